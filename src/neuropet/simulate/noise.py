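"""Noise models shared by the simulators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec"]


@dataclass
class NoiseSpec:
    """Noise model applied to a simulated curve.

    models
    ------
    ``gaussian``
        zero-mean, SD = ``level * scale`` where ``scale`` is the curve peak.
    ``rician``
        magnitude of (signal + complex Gaussian), the MRI magnitude model.
    ``frame-gaussian``
        zero-mean Gaussian with SD proportional to
        ``sqrt(value) / sqrt(frame duration)``, emulating PET count
        statistics (heavier noise in short early frames).
    """

    model: str = "gaussian"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")
        if self.model not in ("gaussian", "rician", "frame-gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, frame_duration_s=None,
              rng: np.random.Generator | None = None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.level == 0:
            return values.copy()
        rng = rng if rng is not None else self.rng()
        scale = np.max(np.abs(values)) or 1.0
        if self.model == "gaussian":
            return values + rng.normal(0.0, self.level * scale, values.shape)
        if self.model == "rician":
            sd = self.level * scale
            re = values + rng.normal(0.0, sd, values.shape)
            im = rng.normal(0.0, sd, values.shape)
            return np.hypot(re, im)
        # frame-gaussian: SD per frame ~ sqrt(value)/sqrt(duration), scaled
        # so that the curve-peak frame of unit duration has relative SD `level`
        dur = np.asarray(frame_duration_s, dtype=float) if frame_duration_s is not None \
            else np.ones_like(values)
        sd = self.level * np.sqrt(np.clip(values, 0.0, None) * scale) / np.sqrt(dur / 60.0)
        return values + rng.normal(0.0, 1.0, values.shape) * sd
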