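"""DSC-MRI perfusion: ΔR2* conversion, CBV with linear leakage correction,
and truncated-SVD deconvolution for CBF, MTT and TTP.

Contrast-agent extravasation through a broken blood-brain barrier biases
the bolus integral; the standard linear (Boxerman-Weisskoff) model

    ΔR2*_tissue(t) ≈ K1 ΔR2*_ref(t) - K2 ∫_0^t ΔR2*_ref dτ

is fitted against a non-leaky reference curve, and CBVlc is the integral
of the corrected curve ΔR2* + K2 ∫ΔR2*_ref.  K2 is reported signed so both
T1-dominant (signal overshoot) and T2*-dominant leakage are representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DscResult",
    "delta_r2star",
    "leakage_correct",
    "compute_cbv",
    "deconvolve_cbf",
    "quantify_dsc",
]


@dataclass
class DscResult:
    cbv: float
    cbv_lc: float
    cbf: float          # relative units, 1/s scale
    mtt: float          # s
    ttp: float          # s
    k1_leak: float
    k2_leak: float      # 1/s


def delta_r2star(signal, n_baseline: int, te_ms: float):
    """ΔR2*(t) = -ln(S/S0)/TE with S0 the pre-bolus baseline mean.

    Nonpositive samples are flagged and returned as NaN rather than raised.
    """
    if te_ms <= 0:
        raise ValueError("TE must be positive")
    signal = np.asarray(signal, dtype=float)
    if n_baseline < 1 or n_baseline > signal.size:
        raise ValueError("baseline range out of bounds")
    s0 = signal[:n_baseline].mean()
    te_s = te_ms / 1000.0
    invalid = signal <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2 = -np.log(signal / s0) / te_s
    dr2[invalid] = np.nan
    return dr2, invalid


def leakage_correct(tissue_dr2, ref_dr2, t_s):
    """Fit the linear leakage model and return (k1, k2, corrected curve).

    ``ref_dr2`` is the average ΔR2* over a designated non-enhancing region.
    """
    tissue = np.asarray(tissue_dr2, dtype=float)
    ref = np.asarray(ref_dr2, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if np.ptp(ref) <= 1e-12 * max(abs(ref).max(), 1.0):
        raise ValueError("degenerate (flat) reference curve")
    cum_ref = cumulative_trapezoid(ref, t_s, initial=0.0)
    design = np.column_stack([ref, -cum_ref])
    coef, *_ = np.linalg.lstsq(design, tissue, rcond=None)
    k1, k2 = map(float, coef)
    corrected = tissue + k2 * cum_ref
    return k1, k2, corrected


def compute_cbv(tissue_dr2, aif_dr2, t_s) -> float:
    """Relative CBV: ratio of trapezoidal bolus integrals."""
    t_s = np.asarray(t_s, dtype=float)
    denom = np.trapezoid(np.asarray(aif_dr2, float), t_s)
    if denom <= 0:
        raise ValueError("zero AIF integral")
    return float(np.trapezoid(np.asarray(tissue_dr2, float), t_s) / denom)


def deconvolve_cbf(tissue_dr2, aif_dr2, t_s, lam: float = 0.2):
    """Truncated-SVD deconvolution of C_t = CBF (AIF ⊛ R).

    Singular values below ``lam`` times the largest are discarded.  Returns
    ``(cbf, residue, mtt, ttp)`` where CBF is the peak of the deconvolved
    impulse response CBF·R(t), MTT = CBV/CBF (central volume theorem) and
    TTP is the time of the tissue-curve peak relative to bolus arrival
    (earliest index on ties).
    """
    if not 0 < lam < 1:
        raise ValueError("svd threshold must be in (0, 1)")
    tissue = np.asarray(tissue_dr2, dtype=float)
    aif = np.asarray(aif_dr2, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    dt = t_s[1] - t_s[0]
    n = t_s.size
    # lower-triangular discrete convolution matrix
    a = np.zeros((n, n))
    for j in range(n):
        a[j:, j] = aif[: n - j] * dt
    u, s, vt = np.linalg.svd(a)
    keep = s >= lam * s[0]
    s_inv = np.where(keep, 1.0 / np.where(s == 0, 1.0, s), 0.0)
    residue = vt.T @ (s_inv * (u.T @ tissue))
    cbf = float(residue.max())
    cbv = compute_cbv(tissue, aif, t_s)
    mtt = cbv / cbf if cbf > 0 else np.inf
    # bolus arrival: first sample above baseline + 3 SD of the pre-bolus noise
    arrival_idx = _bolus_arrival(tissue)
    ttp = float(t_s[int(np.argmax(tissue))] - t_s[arrival_idx])
    return cbf, residue, float(mtt), ttp


def _bolus_arrival(curve, n_baseline: int = 5) -> int:
    base = curve[:n_baseline]
    thresh = base.mean() + 3.0 * (base.std() if base.std() > 0 else 1e-9)
    above = np.nonzero(curve > thresh)[0]
    return int(above[0]) if above.size else 0


def quantify_dsc(tissue_signal, aif_signal, ref_signal, t_s,
                 te_ms: float = 30.0, n_baseline: int = 5,
                 lam: float = 0.2) -> DscResult:
    """Full DSC pipeline from signal curves to perfusion metrics."""
    tissue, _ = delta_r2star(tissue_signal, n_baseline, te_ms)
    aif, _ = delta_r2star(aif_signal, n_baseline, te_ms)
    ref, _ = delta_r2star(ref_signal, n_baseline, te_ms)
    k1, k2, corrected = leakage_correct(tissue, ref, t_s)
    cbv = compute_cbv(tissue, aif, t_s)
    cbv_lc = compute_cbv(corrected, aif, t_s)
    cbf, _, mtt, ttp = deconvolve_cbf(corrected, aif, t_s, lam=lam)
    return DscResult(cbv, cbv_lc, cbf, mtt, ttp, k1, k2)
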