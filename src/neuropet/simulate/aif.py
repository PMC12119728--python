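"""Population-shaped arterial/blood input function.

The bolus shape is the tri-exponential model

    Cp(t) = (A1 t - A2 - A3) e^(-l1 t) + A2 e^(-l2 t) + A3 e^(-l3 t)

which is zero at t = 0, rises to a peak within the first minute and decays
with fast, intermediate and slow components.  The default parameters are a
Feng-type set chosen so the bolus peaks about 45 s post-injection and the
clearance is effectively mono-exponential beyond ~10 min — the regime in
which Patlak graphical analysis of a trapped tracer is linear past its
equilibration time.  A study-specific population shape (normalised to
sagittal-sinus blood) can be substituted through configuration — the shape
parameters are data, not logic.
"""

from __future__ import annotations

import numpy as np

from ..kinetics import InputFunction

__all__ = ["FENG_DEFAULTS", "make_population_aif"]

#: Feng-model parameters: A1 [kBq/mL/min], A2, A3 [kBq/mL], l1..l3 [1/min].
FENG_DEFAULTS = {
    "a1": 300.0,
    "a2": 20.8,
    "a3": 21.9,
    "l1": 1.5,
    "l2": 0.6,
    "l3": 0.0104,
}


def feng_curve(t_min: np.ndarray, a1, a2, a3, l1, l2, l3) -> np.ndarray:
    t = np.asarray(t_min, dtype=float)
    c = (a1 * t - a2 - a3) * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)
    return np.where(t >= 0, c, 0.0)


def make_population_aif(
    shape_params: dict | None = None,
    end_time_min: float = 70.0,
    dt_min: float = 1.0 / 60.0,
    plasma_to_blood_ratio: float = 1.0,
) -> InputFunction:
    """Sample the population bolus on a fine grid for convolution.

    Raises if the parameters produce a negative early curve (an unphysical
    shape, e.g. A2 + A3 exceeding the rising term for longer than the decay
    permits).
    """
    p = dict(FENG_DEFAULTS)
    if shape_params:
        p.update(shape_params)
    t = np.arange(int(round(end_time_min / dt_min)) + 1) * dt_min
    cb = feng_curve(t, p["a1"], p["a2"], p["a3"], p["l1"], p["l2"], p["l3"])
    if np.any(cb < -1e-9 * max(cb.max(), 1.0)):
        raise ValueError("shape parameters yield a negative early curve")
    cb = np.clip(cb, 0.0, None)
    if np.trapezoid(cb, t) <= 0:
        raise ValueError("input function has zero area")
    return InputFunction(t, cb, plasma_to_blood_ratio, provenance="population-scaled")
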