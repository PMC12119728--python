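# neuropet

Quantification pipeline for hybrid dynamic-PET / multiparametric-MRI studies
of brain tumour lesions, built for tracers that are trapped irreversibly in
tissue (monocarboxylate / short-chain fatty-acid radiotracers), with the
downstream statistics such studies report: LASSO-selected imaging-biomarker
vectors, survival dichotomisation, and a tissue metabolomics screen.

It is aimed at imaging scientists who want the full analysis chain —
from 4-D NIfTI volumes and frame-timing sidecars to a summary table of
per-lesion variables — as tested, seedable, reusable code.  Because patient
images from such studies are rarely shareable, the package ships a
first-class synthetic-data module that generates every input with known
ground truth, so the whole pipeline is verifiable end to end by parameter
recovery.

## What it computes

**Static PET** — SUV (`C_tissue / (dose / weight)`), tumour-to-contralateral
white-matter ratios (TBRmax/TBRmean), fractional-SUVmax contour masks
(SUV30/SUV40: the 26-connected region above 30%/40% of SUVmax), Dice overlap
and percent volume difference against contrast-enhancing MRI masks.

**PET kinetics** — with plasma input `Cp` (a population shape scaled to the
sagittal-sinus blood curve):

* standard Patlak: slope of `C_t/Cp` against `∫Cp/Cp` past `t*` estimates
  the net trapping rate `Ki`;
* modified (generalized) Patlak with an efflux term `−k_loss ∫C_t/Cp`;
* irreversible two-tissue compartment model
  `C_t = (1−v_b)(C_free+C_bound) + v_b C_b` with
  `dC_free/dt = K1 Cp − (k2+k3) C_free`, `dC_bound/dt = k3 C_free` (k4 = 0),
  fitted by bounded multi-start nonlinear least squares;
  macro constant `Ki = K1 k3/(k2+k3)`.

**DCE-MRI** — spoiled-gradient-echo signal↔concentration conversion,
extended Tofts (`Ktrans`, `ve`, `vp`, `kep = Ktrans/ve`), and the two-site
water-exchange (shutter-speed) model yielding the mean intracellular water
lifetime `τi`.

**DSC-MRI** — ΔR2* conversion, CBV with linear (Boxerman-style) leakage
correction (`CBVlc`, signed `K2`), truncated-SVD deconvolution for CBF,
MTT by the central volume theorem, and TTP.

**ASL / DWI** — QUIPSS-II pulsed-ASL CBF and mono-exponential ADC.

**Statistics** — per-variable rank-sum cohort comparisons; L1-penalised
logistic "grade-predictive vectors" (static GpVs / dynamic GpVd) over the
standardised feature table with seeded cross-validation, JSON-serialisable
weights and ROC evaluation; Kaplan–Meier dichotomisation at a marker cutoff
(Mann–Whitney and log-rank both reported); Welch-t + BH-q metabolite
screening and a PCA overview.

## Worked example

```python
from neuropet.simulate import make_population_aif, NoiseSpec
from neuropet.simulate.pet import clinical_schedule, TcmTruth, simulate_2tcm_tac
from neuropet.kinetics import fit_2tcm, patlak_standard

schedule = clinical_schedule()          # 10x15s, 3x60s, 5x120s, 9x300s, 1x360s
aif = make_population_aif()
truth = TcmTruth(k1=0.10, k2=0.15, k3=0.02, vb=0.03)
tac = simulate_2tcm_tac(aif, truth, schedule,
                        noise=NoiseSpec("frame-gaussian", 0.05, seed=42))

tcm = fit_2tcm(tac, aif, schedule)
pat = patlak_standard(tac, aif, t_star=20.0)
print(f"scan ends at {schedule.end_time_min} min over {len(schedule)} frames")
print(f"2TCM fit:  K1={tcm.k1:.4f}  k2={tcm.k2:.4f}  k3={tcm.k3:.4f}  vb={tcm.vb:.4f}")
print(f"macro Ki = {tcm.ki_macro:.5f} mL/g/min (truth {truth.ki_macro:.5f})")
print(f"Patlak slope = {pat.ki:.5f} mL/g/min (R2 = {pat.r_squared:.4f})")
```

prints

```
scan ends at 66.5 min over 28 frames
2TCM fit:  K1=0.0992  k2=0.1464  k3=0.0194  vb=0.0241
macro Ki = 0.01160 mL/g/min (truth 0.01176)
Patlak slope = 0.01155 mL/g/min (R2 = 0.9960)
```

i.e. a dynamic lesion curve with 5% frame-weighted noise gives back the
generating rate constants to a few percent, and the graphical and
compartmental estimates of the trapping rate agree.

The end-to-end demo study (simulate two cohorts → quantify every modality →
summary table → GpV fit → survival split → metabolomics screen) runs with

```bash
neuropet run --seed 0 --out pipeline_run
```

and writes `features.csv`, `table2_report.csv` (variables × cohort × mask
context with rank-sum p-values), fitted GpV specs, survival records and the
metabolite screen, plus a provenance log echoing every resolved parameter.

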