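"""DCE-MRI signal simulator: extended-Tofts kinetics through an SPGR
readout, optionally with two-site water exchange."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dce import (
    DceAcquisition,
    concentration_to_signal,
    forward_two_site_exchange,
    tofts_concentration,
)
from .noise import NoiseSpec

__all__ = ["DceTruth", "parker_like_cp", "simulate_dce_signal"]


@dataclass
class DceTruth:
    ktrans: float = 0.25    # 1/min
    ve: float = 0.30
    vp: float = 0.03
    taui: float = 0.0       # min; 0 -> fast exchange

    def __post_init__(self):
        if not (0 < self.ve <= 1 and 0 <= self.vp < 1 and self.ve + self.vp <= 1):
            raise ValueError("volume fractions must satisfy ve in (0,1], vp in [0,1), ve+vp<=1")
        if self.ktrans < 0 or self.taui < 0:
            raise ValueError("ktrans and taui must be nonnegative")


def parker_like_cp(t_min: np.ndarray, onset_min: float = 0.5,
                   peak_mm: float = 6.0) -> np.ndarray:
    """Simple bolus + washout plasma concentration curve (mM).

    A gamma-variate first pass plus a slow mono-exponential washout tail —
    adequate as a driving function for simulation; a measured blood curve
    is used on real data.
    """
    t = np.asarray(t_min, dtype=float) - onset_min
    t = np.clip(t, 0.0, None)
    first_pass = (t / 0.25) ** 2 * np.exp(-t / 0.25)
    tail = 0.3 * (1.0 - np.exp(-t / 0.2)) * np.exp(-t / 8.0)
    curve = first_pass / first_pass.max() if first_pass.max() > 0 else first_pass
    return peak_mm * (curve + tail) / (1.0 + 0.3)


def simulate_dce_signal(
    truth: DceTruth,
    acq: DceAcquisition,
    n_frames: int = 90,
    m0: float = 1000.0,
    noise: NoiseSpec | None = None,
    cp: np.ndarray | None = None,
):
    """Return ``(t_min, signal, cp)`` for one tissue region.

    Fast-exchange (``truth.taui == 0``) uses the single-R1 SPGR signal with
    R1(t) = R10 + r1 C_t(t); a positive tau_i routes through the two-site
    exchange forward model.  Baseline frames sit before bolus onset so M0
    can be re-estimated by the quantifier.
    """
    t_min = np.arange(n_frames) * acq.dt_s / 60.0
    if cp is None:
        onset = (acq.baseline_frames + 1) * acq.dt_s / 60.0
        cp = parker_like_cp(t_min, onset_min=onset)
    if truth.taui > 0:
        signal = forward_two_site_exchange(
            t_min, cp, acq, truth.ktrans, truth.ve, truth.vp, truth.taui, m0=m0
        )
    else:
        ct = tofts_concentration(t_min, cp, truth.ktrans, truth.ve, truth.vp)
        signal = concentration_to_signal(ct, acq, m0=m0)
    if noise is not None:
        signal = noise.apply(signal)
    return t_min, signal, cp
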