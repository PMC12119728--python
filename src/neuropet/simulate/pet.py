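"""Dynamic PET simulators: 2TCM time-activity curves and a lesion phantom.

Lesion, background (contralateral white matter) and blood regions each get
a voxelwise-identical time course; the phantom geometry is a sphere in a
box, with an optional contrast-enhancing mask of different radius to
emulate PET-avid volume extending beyond (or trailing) the CE-MRI volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging import DynamicImage, FrameSchedule, RoiMask, TimeActivityCurve
from ..kinetics import InputFunction, frame_average, two_tissue_curve
from .noise import NoiseSpec

__all__ = ["TcmTruth", "simulate_2tcm_tac", "make_lesion_phantom", "clinical_schedule"]


def clinical_schedule() -> FrameSchedule:
    """The 28-frame dynamic scheme: 10x15 s, 3x60 s, 5x120 s, 9x300 s, 1x360 s."""
    return FrameSchedule.from_blocks([(10, 15), (3, 60), (5, 120), (9, 300), (1, 360)])


@dataclass
class TcmTruth:
    """Ground-truth irreversible 2TCM parameters for one region."""

    k1: float = 0.1
    k2: float = 0.15
    k3: float = 0.02
    vb: float = 0.03

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3) < 0 or not 0 <= self.vb <= 1:
            raise ValueError("rates must be nonnegative and vb a fraction")

    @property
    def ki_macro(self) -> float:
        s = self.k2 + self.k3
        return self.k1 * self.k3 / s if s > 0 else 0.0


def simulate_2tcm_tac(
    aif: InputFunction,
    truth: TcmTruth,
    schedule: FrameSchedule,
    noise: NoiseSpec | None = None,
    label: str = "lesion",
) -> TimeActivityCurve:
    """Frame-averaged irreversible 2TCM curve driven by ``aif``.

    The noiseless curve is the closed-form convolution evaluated on the
    input function's fine grid, then averaged over each frame interval.
    """
    t_fine = aif.time_min
    if t_fine[-1] < schedule.end_time_min - 1e-9:
        raise ValueError("input function grid ends before the last frame")
    curve = two_tissue_curve(t_fine, aif.cp, aif.cb, truth.k1, truth.k2, truth.k3, truth.vb)
    values = frame_average(t_fine, curve, schedule)
    if noise is not None:
        values = noise.apply(values, frame_duration_s=schedule.frame_duration)
    return TimeActivityCurve(schedule.mid_times_min, values, n_voxels=1, label=label)


def _sphere(shape, centre, radius) -> np.ndarray:
    grid = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grid, centre))
    return d2 <= radius**2


@dataclass
class LesionPhantom:
    image: DynamicImage
    lesion_mask: RoiMask
    background_mask: RoiMask
    blood_mask: RoiMask
    ce_mask: RoiMask
    truth: dict


def make_lesion_phantom(
    aif: InputFunction,
    lesion_truth: TcmTruth,
    background_truth: TcmTruth | None = None,
    schedule: FrameSchedule | None = None,
    shape=(32, 32, 32),
    lesion_radius: float = 6.0,
    ce_radius: float | None = 5.0,
    voxel_size_mm=(2.0, 2.0, 2.0),
    noise: NoiseSpec | None = None,
) -> LesionPhantom:
    """Sphere-in-box dynamic phantom with lesion, background and blood regions.

    ``ce_radius`` draws a concentric "contrast-enhancing" mask of different
    size than the PET-avid sphere, for volume/overlap studies; set it equal
    to ``lesion_radius`` for perfectly concordant masks.
    """
    schedule = schedule or clinical_schedule()
    # mild white-matter-like uptake: Ki about a quarter of the default lesion,
    # giving a tumour-to-background ratio in the 3-4 range at 60 min
    background_truth = background_truth or TcmTruth(k1=0.05, k2=0.25, k3=0.015, vb=0.02)
    if lesion_radius <= 0:
        raise ValueError("lesion radius must be positive")
    if lesion_radius >= min(shape) / 2:
        raise ValueError("lesion larger than grid")

    centre = tuple(s // 2 for s in shape)
    lesion = _sphere(shape, centre, lesion_radius)
    ce = _sphere(shape, centre, ce_radius if ce_radius is not None else lesion_radius)
    # blood region: small cylinder in a corner standing in for the sagittal sinus
    blood = np.zeros(shape, dtype=bool)
    blood[2:5, 2:5, 4 : shape[2] - 4] = True
    background = ~(lesion | blood)

    lesion_tac = simulate_2tcm_tac(aif, lesion_truth, schedule, label="lesion")
    bg_tac = simulate_2tcm_tac(aif, background_truth, schedule, label="background")
    blood_vals = frame_average(aif.time_min, aif.cb, schedule)

    voxels = np.empty(shape + (len(schedule),))
    voxels[background] = bg_tac.value
    voxels[lesion] = lesion_tac.value
    voxels[blood] = blood_vals
    if noise is not None:
        rng = noise.rng()
        flat = voxels.reshape(-1, len(schedule))
        flat[:] = noise.apply(flat, frame_duration_s=schedule.frame_duration, rng=rng)

    image = DynamicImage(voxels, voxel_size_mm, schedule, "kBq/mL", True)
    return LesionPhantom(
        image=image,
        lesion_mask=RoiMask(lesion, "lesion"),
        background_mask=RoiMask(background, "contralateral-white-matter"),
        blood_mask=RoiMask(blood, "sagittal-sinus"),
        ce_mask=RoiMask(ce, "ce-mri"),
        truth={"lesion": lesion_truth, "background": background_truth},
    )
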