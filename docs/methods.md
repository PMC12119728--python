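# Methods

This note documents the models implemented in `neuropet`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Dynamic acquisitions are carried as a 4-D voxel array plus a frame schedule
(start and duration per frame, seconds from injection; frames contiguous
and non-overlapping).  All kinetic fitting uses frame **mid-times in
minutes** as the abscissa — the standard convention for frame-integrated
PET data — and model predictions are averaged over each frame interval
rather than point-sampled, which matters for the long late frames.
Geometry is voxel-index space only: masks are assumed co-registered with
their companion image, as they are in a simultaneous hybrid acquisition;
registration and resampling are out of scope.  Volumes are NIfTI-1 with a
JSON sidecar (`FrameTimesStart`, `FrameDuration`, `Units`,
`DecayCorrected`) mirroring PET-BIDS vocabulary so real data can be
adapted without code changes.  Decay correction to injection time is
tracked by a flag and is idempotent by construction; the synthetic
generator emits decay-corrected data by default, as reconstructed PET
normally is.

## Population input function

The plasma input is the tri-exponential bolus
`Cp(t) = (A1 t − A2 − A3)e^{−λ1 t} + A2 e^{−λ2 t} + A3 e^{−λ3 t}`,
zero at injection, scaled to an image-derived whole-blood curve from the
superior sagittal sinus by matching trapezoidal AUC over a configurable
window.  Defaults (`A1 = 300, A2 = 20.8, A3 = 21.9` kBq/mL;
`λ = 1.5, 0.6, 0.0104` min⁻¹) are a Feng-type parameterisation chosen
once so that the bolus peaks ≈ 45 s post-injection and clearance is
effectively mono-exponential beyond ~10 min.  The second property is a
modelling requirement, not a tuning knob: Patlak analysis of an
irreversibly trapped tracer assumes the reversible-compartment transient
has equilibrated by `t*`, and an input with a slowly mixing intermediate
decay component violates that assumption well past 20 min.  The true
population shape used clinically is unpublished; these parameters live in
configuration and are explicitly placeholders.  A single configurable
plasma-to-whole-blood ratio (default 1.0) relates `Cp` to the blood curve
`Cb`, since tracer partitioning is not published for this class of agent.

## PET kinetics

The irreversible two-tissue compartment model is fitted with bounds
`K1, k2, k3 ∈ [0, 5]`, `vb ∈ [0, 0.2]` and five documented starting
points, keeping the best-residual solution.  `vb` multiplies **whole
blood**, modelling blood-signal contamination of the tissue region.  The
forward model is evaluated on a 1-s uniform grid with trapezoid-weighted
FFT convolution, then frame-averaged; the same forward model drives the
simulator, so noiseless self-generated curves are recovered exactly (the
suite asserts 0.5%), and an independent ODE integration at 0.1 s agrees
with the closed-form convolution to < 0.05% per frame.

Patlak analysis uses `t* = 20 min` by default (configurable); the window
diagnostics (`R²`, point count) are returned with every fit.  An optional
whole-blood correction `(C_t − vb·Cb)/(1 − vb)` removes the `(1 − vb)`
attenuation of the slope when a blood-volume estimate is available — the
sagittal-sinus segmentation exists precisely to support this correction.
The "modified" variant is the generalized (Patlak–Blasberg) regression
with an efflux regressor `−k_loss ∫C_t/Cp`, solved as a three-parameter
least-squares problem; rank deficiency is flagged, not silently dropped.
This formulation is an explicit design choice — the clinical literature's
"modified Patlak" is not uniquely defined — and it is pluggable behind the
same interface.  Published tables in this field print the two Patlak
variants on scales differing by ~100×, suggesting a normalisation
difference we deliberately do not guess at; our outputs are mL/g/min for
both.  Similarly, K1 is conventionally mL/g/min even where summary tables
print 1/min.

## DCE-MRI

Signal↔concentration conversion inverts the spoiled-gradient-echo
steady-state equation, with `M0` estimated from pre-contrast baseline
frames and the known `R10`.  Non-invertible samples are flagged per-sample,
never raised on.  Defaults: `r1 = 5.0 L/(mmol·s)` (gadobutrol at 3 T),
haematocrit 0.42, TR 5 ms, flip 12° — all configurable, none published for
the target protocol.

Extended Tofts is evaluated directly on the acquisition grid using the
exponential-kernel recursion that is exact for piecewise-linear `Cp`,
avoiding any auxiliary-grid bias.  Bounds `Ktrans ∈ [0,5] min⁻¹`,
`ve ∈ (0,1]`, `vp ∈ [0,0.5]`, `τi ∈ [0,10] min`; multi-start lattice in
the estimator signature.  The surface has a degenerate ridge at `ve → 0`
(`kep → ∞`) where the exchange term mimics a purely vascular one; among
solutions tied at numerical precision the smallest-`Ktrans` solution is
preferred, and a zero-transfer start is included so the exact solution is
always among the candidates.

The shutter-speed model propagates two longitudinal water pools
(intracellular fraction `p_i`, default 0.8; extracellular `p_o = 1 − p_i`)
under the 2×2 exchange-relaxation matrix with rates `1/τi` and
`1/τo = p_i/(τi p_o)` (detailed balance); the observed signal is the sum
of both eigencomponents through the SPGR readout, computed from the
analytic 2×2 eigendecomposition (validated in-suite against `numpy.linalg.eig`).
Extracellular contrast concentration is defined as `C_t / p_o` — contrast
per accessible extracellular water — which makes the `τi → 0` limit equal
the fast-exchange extended-Tofts signal exactly; the suite asserts the
nesting to 0.1%.  `p_i` and `R1i` are held fixed during fitting: they are
not jointly identifiable with `τi` at clinical SNR.  The full two-site
solution is implemented; the fast-exchange-regime limit is its `τi → 0`
special case.

## DSC-MRI

`ΔR2*(t) = −ln(S/S0)/TE` with `S0` the pre-bolus baseline mean and
nonpositive samples flagged.  Leakage correction fits the linear model
`ΔR2*_tissue ≈ K1·ΔR2*_ref − K2·∫ΔR2*_ref` against a non-leaky reference
(the average over a designated non-enhancing region; in phantoms, a
region-averaged curve with correspondingly suppressed noise), and `CBVlc`
integrates the corrected curve.  `K2` is reported signed so both
T1-dominant (post-bolus overshoot) and T2*-dominant leakage are
representable.  CBF uses truncated-SVD deconvolution of
`C_t = CBF·(AIF ⊛ R)` with threshold `λ` as a fraction of the largest
singular value (default 0.2, standard sSVD practice; tests of exact
recovery use a small `λ` on noiseless data); `MTT = CBV/CBF` by the
central volume theorem and TTP is the tissue-peak time relative to bolus
arrival (first sample above baseline + 3 SD), earliest index on ties.
Discrete deconvolution carries an `O(dt)` bias in MTT (≈ dt/2), so
deconvolution validation uses 0.2-s sampling.  Summary tables in this
field sometimes print CBV in a flow unit (mL/100 mL/min); outputs here are
labelled with dimensionally consistent relative units, normalisable by a
configurable constant.

## ASL and DWI

ASL uses the single-compartment QUIPSS-II pulsed-ASL expression
`CBF = 6000·λ·ΔM·e^{TI/T1b}/(2α·M0·TI1)` with consensus 3 T defaults
(`λ = 0.9 mL/g`, `T1b = 1650 ms`, `α = 0.98`); the scanner's actual timing
parameters are configuration.  ADC is fitted log-linearly (deterministic,
no optimizer) with nonpositive samples excluded and flagged, and reported
on the 10⁻⁶ mm²/s scale used clinically.

## Feature table and predictive vectors

The per-lesion table carries the standard variable inventory (SUV/TBR,
Patlak and compartmental constants, DCE/DSC/ASL/DWI parameters) per mask
context (T1, SUV40, SUV30).  The static vector (GpVs) excludes the
dynamic-PET constants; the dynamic vector (GpVd) includes them.
Standardisation (per-column mean/SD) is stored with the model so a vector
trained on one cohort transfers unchanged to unseen lesions.  Missing
values are refused rather than silently imputed.

The classifier is L1-penalised logistic regression over a λ grid spanning
four decades below `λ_max` (the all-zero boundary, from the dual norm of
the gradient at zero), with seeded stratified cross-validation; λ is
chosen at minimum mean CV binomial deviance (a one-SE rule is selectable)
and the full-data sparsity path is retained as a trace diagnostic.
Penalised **logistic** (not linear) regression was chosen because the
endpoints are binary and evaluation is ROC-based.  Fitted vectors
serialise to JSON (features, weights on the standardised scale,
intercept, λ, standardisation, seed) so externally published weight sets
can be loaded verbatim.  ROC evaluation is trapezoidal over the empirical
curve with accuracy at the Youden-optimal threshold; the suite asserts the
trapezoid AUC equals brute-force concordant-pair counting.

## Survival and group statistics

Cohort comparisons use the two-sided Wilcoxon rank-sum test per variable
(exact enumeration available for small samples).  Survival dichotomisation
at `marker ≥ cutoff` reports product-limit medians (median = earliest time
the curve reaches 0.5; undefined flag when it never does), a two-tailed
Mann–Whitney test on the observed times, **and** the log-rank test:
rank-sum on censored times is unusual, and the conventional alternative is
reported alongside rather than substituted silently.  Multiple lesions per
patient are treated as independent rows by default, with patient-level
aggregation available as a switch.

## Metabolomics screen

Abundances (assumed normalised to extracted tissue mass) are
log-transformed; each metabolite and group pair gets Welch's
unequal-variance t, a Benjamini–Hochberg FDR q-value (monotone,
assumption-light; a Storey-type estimator could be substituted),
fold-change as the ratio of geometric means (consistent with log-space
testing), and a shading category (significant at p ≤ 0.05, trend at
0.05 < p < 0.10, by direction).  Metabolites constant in both groups are
flagged with undefined p.  PCA operates on column-centred log abundances
with samples as observations.

## Synthetic-data module

Every simulator is a deterministic function of (parameters, seed), and its
noiseless output is exactly invertible by the corresponding quantifier —
the central recovery property the suite asserts.  Defaults describe a
plausible clinical scale: lesion 2TCM `(K1, k2, k3, vb) =
(0.1, 0.15, 0.02, 0.03)`; white-matter-like background with ~4× lower
trapping (giving TBR in the 3–4 range); DCE `(Ktrans, ve, vp) =
(0.25, 0.3, 0.03)` with `τi` of order 1–2 min; DSC relative CBV ≈ 4% with
arterial ΔR2* peak 25 s⁻¹; ASL-CBF ≈ 40 mL/100 g/min; ADC ≈ 1000×10⁻⁶
mm²/s.  Noise models: frame-weighted Gaussian for PET (SD ∝
√value/√duration, emulating count statistics), Rician for MRI magnitude
(Gaussian available for analytic checks).  The phantom is a sphere in a
box with lesion, background, blood and contrast-enhancing regions; it
emulates region-level contrast, not anatomy, motion or reconstruction
physics — passing tests demonstrate correctness of the estimators under
the stated models, not robustness to everything real data contains (e.g.
partial-volume effects, B1 errors, bolus dispersion are all absent).
The demo pipeline runs 4 lesions per cohort by default; the suite and
acceptance script use small grids (24³–41³ voxels) and 80–400-sample
curves, sizes at which every recovery property above is already
measurable.

## Known limitations

* ROI-level quantification only; no voxelwise parametric maps.
* No k4 > 0 compartment models, IVIM/kurtosis diffusion, or multi-PLD ASL.
* The shutter-speed `τi` is weakly identified at realistic noise; fits
  report residual norms, and fixed `p_i`/`R1i` should be treated as part
  of the model definition.
* Survival modelling is estimator + two-sample tests; no proportional-
  hazards regression.
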