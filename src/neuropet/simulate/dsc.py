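"""DSC-MRI simulator: gamma-variate bolus, linear first-pass leakage and a
gradient-echo signal readout."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .noise import NoiseSpec

__all__ = ["DscTruth", "gamma_variate", "simulate_dsc_signal"]


def gamma_variate(t_s, t0: float = 10.0, alpha: float = 3.0, beta: float = 1.5,
                  peak: float = 1.0) -> np.ndarray:
    """Gamma-variate bolus, peak-normalised then scaled to ``peak`` (1/s)."""
    t = np.clip(np.asarray(t_s, dtype=float) - t0, 0.0, None)
    shape = t**alpha * np.exp(-t / beta)
    m = shape.max()
    return peak * shape / m if m > 0 else shape


@dataclass
class DscTruth:
    cbv_rel: float = 0.04        # tissue/arterial bolus-integral ratio
    k1_leak: float = 1.0
    k2_leak: float = 0.0         # 1/s; > 0 means T1-dominant leakage
    mtt_s: float | None = None   # if set, tissue = CBF (AIF ⊛ exp(-t/MTT))


def simulate_dsc_signal(
    truth: DscTruth,
    te_ms: float = 30.0,
    dt_s: float = 1.0,
    n_samples: int = 80,
    s0: float = 1000.0,
    aif_peak: float = 25.0,
    noise: NoiseSpec | None = None,
    ref_noise_scale: float = 0.1,
):
    """Return ``(t_s, tissue_signal, aif_signal, ref_signal)``.

    The reference (non-leaky) tissue curve is the arterial bolus scaled by
    ``cbv_rel``; the leaky tissue curve follows the linear leakage model
    ΔR2* = K1·ref − K2·∫ref.  When ``mtt_s`` is set the tissue curve is
    instead a flow-scaled convolution with an exponential residue function
    (for deconvolution testing), CBF = CBV/MTT.
    """
    if te_ms <= 0:
        raise ValueError("TE must be positive")
    t_s = np.arange(n_samples) * dt_s
    aif = gamma_variate(t_s, peak=aif_peak)
    ref = truth.cbv_rel * aif
    if truth.mtt_s is not None:
        cbf = truth.cbv_rel / truth.mtt_s
        residue = np.exp(-t_s / truth.mtt_s)
        tissue = cbf * np.convolve(aif, residue)[:n_samples] * dt_s
    else:
        cum_ref = cumulative_trapezoid(ref, t_s, initial=0.0)
        tissue = truth.k1_leak * ref - truth.k2_leak * cum_ref
    te_s = te_ms / 1000.0
    curves = []
    rng = noise.rng() if noise is not None else None
    # the reference curve is the average over a large non-enhancing region,
    # so its noise is suppressed relative to single-lesion curves
    scales = (1.0, 1.0, ref_noise_scale)
    for dr2, scale in zip((tissue, aif, ref), scales):
        sig = s0 * np.exp(-te_s * dr2)
        if noise is not None and noise.level * scale > 0:
            from dataclasses import replace

            sig = replace(noise, level=noise.level * scale).apply(sig, rng=rng)
        curves.append(sig)
    return t_s, curves[0], curves[1], curves[2]
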