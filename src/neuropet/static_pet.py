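"""Static PET metrics and segmentation: SUV, tumour-to-background ratio,
fractional-SUVmax contour masks, and mask overlap/volume statistics.

SUV normalises tissue activity concentration by injected activity per body
weight; with concentration in kBq/mL and dose in MBq it is the familiar
g/mL-scale unitless value.  The SUV30/SUV40 contour masks grow a
26-connected region from the SUVmax voxel down to 30% or 40% of SUVmax,
and lesion/CE-MRI concordance is summarised by the Dice coefficient and
percent volume difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import DynamicImage, RoiMask, SubjectMeta

__all__ = [
    "PetStaticResult",
    "OverlapResult",
    "compute_suv",
    "suv_statistics",
    "compute_tbr",
    "threshold_segment",
    "overlap",
]


@dataclass
class PetStaticResult:
    suv_max: float
    suv_mean: float
    mask_label: str
    n_voxels: int
    volume_ml: float
    tbr_max: float | None = None
    tbr_mean: float | None = None


@dataclass
class OverlapResult:
    dice: float
    volume_a_ml: float
    volume_b_ml: float
    percent_volume_difference: float


def compute_suv(concentration_kbq_ml, meta: SubjectMeta):
    """SUV = C_tissue / (injected activity / body weight).

    Concentration in kBq/mL against dose in MBq and weight in kg reduces to
    ``C * weight_g / injected_kBq`` (1 mL tissue taken as 1 g).
    """
    c = np.asarray(concentration_kbq_ml, dtype=float)
    dose_kbq = meta.injected_activity_mbq * 1000.0
    weight_g = meta.body_weight_kg * 1000.0
    return c * weight_g / dose_kbq


def suv_statistics(image: DynamicImage, mask: RoiMask, meta: SubjectMeta) -> PetStaticResult:
    """SUVmax / SUVmean over a mask, using the last reconstructed frame."""
    if mask.voxels.shape != image.voxels.shape[:3]:
        raise ValueError("mask grid does not match image grid")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    suv = compute_suv(image.last_frame()[mask.voxels], meta)
    return PetStaticResult(
        suv_max=float(suv.max()),
        suv_mean=float(suv.mean()),
        mask_label=mask.label,
        n_voxels=mask.n_voxels,
        volume_ml=mask.n_voxels * image.voxel_volume_ml,
    )


def compute_tbr(lesion: PetStaticResult, background: PetStaticResult) -> PetStaticResult:
    """Tumour-to-contralateral-white-matter ratios (max and mean variants)."""
    if background.suv_max <= 0 or background.suv_mean <= 0:
        raise ValueError("background SUV must be positive")
    lesion.tbr_max = lesion.suv_max / background.suv_max
    lesion.tbr_mean = lesion.suv_mean / background.suv_mean
    return lesion


def threshold_segment(
    volume: np.ndarray,
    seed_region: RoiMask,
    fraction: float = 0.4,
    connectivity: int = 3,
) -> RoiMask:
    """Fractional-SUVmax contour mask.

    Finds the hottest voxel inside ``seed_region`` and returns the
    26-connected component (``connectivity=3`` in scipy terms) of
    ``{v >= fraction * max}`` containing it.  Ties at exactly the threshold
    are included; the result is invariant to positive rescaling of the
    image.
    """
    volume = np.asarray(volume, dtype=float)
    if seed_region.n_voxels == 0:
        raise ValueError("empty seed region")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    masked = np.where(seed_region.voxels, volume, -np.inf)
    peak_flat = int(np.argmax(masked))
    peak = np.unravel_index(peak_flat, volume.shape)
    vmax = volume[peak]
    above = volume >= fraction * vmax
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, _ = ndimage.label(above, structure=structure)
    component = labels == labels[peak]
    return RoiMask(component, label=f"suv{int(round(fraction * 100))}")


def overlap(mask_a: RoiMask, mask_b: RoiMask, voxel_volume_ml: float = 0.008) -> OverlapResult:
    """Dice coefficient, volumes and percent volume difference of two masks."""
    if mask_a.voxels.shape != mask_b.voxels.shape:
        raise ValueError("masks are on different grids")
    a, b = mask_a.voxels, mask_b.voxels
    na, nb = int(a.sum()), int(b.sum())
    inter = int(np.logical_and(a, b).sum())
    dice = 2.0 * inter / (na + nb) if (na + nb) > 0 else 1.0
    va, vb = na * voxel_volume_ml, nb * voxel_volume_ml
    pct = 100.0 * (va - vb) / vb if vb > 0 else np.inf
    return OverlapResult(dice, va, vb, pct)
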