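"""ASL control/label pair and multi-b DWI simulators, exact inverses of the
corresponding quantifiers at zero noise."""

from __future__ import annotations

import numpy as np

from ..asl_dwi import AslAcquisition
from .noise import NoiseSpec

__all__ = ["simulate_asl_pair", "simulate_dwi_series"]


def simulate_asl_pair(
    cbf_ml_100g_min: float,
    acq: AslAcquisition,
    m0: float = 1000.0,
    shape=(8, 8, 8),
    noise: NoiseSpec | None = None,
):
    """Control/label volumes whose difference encodes the given CBF.

    Inverts the QUIPSS-II expression: ΔM = CBF · 2 α M0 TI1 e^(−TI/T1b) / (6000 λ).
    """
    if m0 <= 0:
        raise ValueError("M0 must be positive")
    ti_s = acq.ti_ms / 1000.0
    ti1_s = acq.ti1_ms / 1000.0
    t1b_s = acq.t1_blood_ms / 1000.0
    dm = (cbf_ml_100g_min * 2.0 * acq.labeling_efficiency * m0 * ti1_s
          * np.exp(-ti_s / t1b_s) / (6000.0 * acq.lambda_partition))
    control = np.full(shape, m0 * 0.5 + dm / 2.0)
    label = np.full(shape, m0 * 0.5 - dm / 2.0)
    if noise is not None:
        rng = noise.rng()
        control = noise.apply(control, rng=rng)
        label = noise.apply(label, rng=rng)
    return control, label, np.full(shape, float(m0))


def simulate_dwi_series(
    adc_mm2_per_s: float,
    b_values,
    s0: float = 1000.0,
    noise: NoiseSpec | None = None,
):
    """Mono-exponential decay S(b) = S0 exp(−b · ADC); b in s/mm², ADC in mm²/s."""
    b = np.asarray(b_values, dtype=float)
    if np.unique(b).size != b.size:
        raise ValueError("b-values must be distinct")
    if adc_mm2_per_s < 0:
        raise ValueError("ADC must be nonnegative")
    signal = s0 * np.exp(-b * adc_mm2_per_s)
    if noise is not None:
        signal = noise.apply(signal)
    return signal
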