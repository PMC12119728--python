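"""Data model and I/O for dynamic volumes, frame schedules, ROI masks and TACs.

A dynamic PET (or dynamic MRI) acquisition is carried here as a
:class:`DynamicImage`: a 4-D voxel array plus a :class:`FrameSchedule` giving
the start and duration of each reconstructed frame, in seconds from tracer
injection.  Region statistics are extracted into
:class:`TimeActivityCurve` objects stamped at frame mid-times in minutes,
which is the abscissa used by every kinetic model in this package.

Volumes are stored as NIfTI-1 with a small JSON sidecar holding the frame
timing (keys mirror PET-BIDS vocabulary: ``FrameTimesStart``,
``FrameDuration``, ``Units``, ``DecayCorrected``) so that real acquisitions
can be adapted without code changes.  All geometry is voxel-index space;
masks are assumed co-registered to their companion image, as in a hybrid
simultaneous acquisition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "RoiMask",
    "TimeActivityCurve",
    "SubjectMeta",
    "SchemaError",
    "load_dynamic_image",
    "save_dynamic_image",
    "load_mask",
    "save_mask",
    "frame_mid_times",
    "extract_tac",
    "decay_correct",
    "FLUORINE_18_HALF_LIFE_MIN",
]

#: Fluorine-18 physical half-life in minutes.
FLUORINE_18_HALF_LIFE_MIN = 109.77


class SchemaError(ValueError):
    """Raised when an image, sidecar or mask violates the declared layout."""


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition, seconds from injection.

    Frames must be contiguous and non-overlapping:
    ``start[i+1] == start[i] + duration[i]``.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise SchemaError("frame_start and frame_duration must be equal-length 1-D")
        if start.size == 0:
            raise SchemaError("schedule needs at least one frame")
        if np.any(dur <= 0):
            raise SchemaError("frame durations must be positive")
        if start[0] < 0:
            raise SchemaError("first frame must start at or after injection")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise SchemaError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_blocks(cls, blocks) -> "FrameSchedule":
        """Build a schedule from ``(count, duration_s)`` blocks.

        The 28-frame clinical scheme ``[(10, 15), (3, 60), (5, 120),
        (9, 300), (1, 360)]`` ends at 66.5 min.
        """
        durations = np.concatenate([np.full(int(n), float(d)) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    def __len__(self) -> int:
        return self.frame_start.size

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes: ``(start + duration / 2) / 60``."""
        return (self.frame_start + self.frame_duration / 2.0) / 60.0

    @property
    def end_time_min(self) -> float:
        """End of the last frame, in minutes from injection."""
        return float(self.frame_start[-1] + self.frame_duration[-1]) / 60.0


def frame_mid_times(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times in minutes for a validated schedule."""
    return schedule.mid_times_min


@dataclass
class DynamicImage:
    """A 3-D static or 4-D dynamic volume on a regular voxel grid.

    ``value_unit`` is one of ``kBq/mL`` (PET activity concentration),
    ``arbitrary-signal`` (MRI magnitude) or ``unitless``.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    schedule: FrameSchedule | None = None
    value_unit: str = "kBq/mL"
    decay_corrected: bool = True

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim not in (3, 4):
            raise SchemaError("voxels must be a 3-D or 4-D array")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise SchemaError("voxel sizes must be positive")
        if self.voxels.ndim == 4:
            if self.schedule is None:
                raise SchemaError("4-D image requires a frame schedule")
            if self.voxels.shape[3] != len(self.schedule):
                raise SchemaError(
                    f"frame count mismatch: image has {self.voxels.shape[3]} frames, "
                    f"schedule declares {len(self.schedule)}"
                )

    @property
    def n_frames(self) -> int:
        return 1 if self.voxels.ndim == 3 else self.voxels.shape[3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def last_frame(self) -> np.ndarray:
        """The last reconstructed frame (used for static uptake metrics)."""
        return self.voxels if self.voxels.ndim == 3 else self.voxels[..., -1]


@dataclass
class RoiMask:
    """Binary region-of-interest mask on the same grid as its image."""

    voxels: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise SchemaError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class TimeActivityCurve:
    """Mean region concentration per frame, stamped at frame mid-times (min)."""

    time_min: np.ndarray
    value: np.ndarray
    n_voxels: int = 0
    label: str = ""
    decay_corrected: bool = True

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_min.shape != self.value.shape:
            raise SchemaError("time and value must have equal length")
        if self.time_min.size > 1 and np.any(np.diff(self.time_min) <= 0):
            raise SchemaError("time must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_min": self.time_min, "value": self.value, "n_voxels": self.n_voxels}
        )


@dataclass
class SubjectMeta:
    """Per-subject injection data needed for SUV and decay handling."""

    injected_activity_mbq: float
    body_weight_kg: float
    isotope_half_life_min: float = FLUORINE_18_HALF_LIFE_MIN

    def __post_init__(self):
        for name in ("injected_activity_mbq", "body_weight_kg", "isotope_half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# I/O


def save_dynamic_image(image: DynamicImage, image_path, sidecar_path=None) -> None:
    """Write a volume as NIfTI-1 plus a JSON timing sidecar (if dynamic)."""
    affine = np.diag(list(image.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), affine), str(image_path))
    if image.schedule is not None:
        if sidecar_path is None:
            sidecar_path = _default_sidecar(image_path)
        payload = {
            "FrameTimesStart": image.schedule.frame_start.tolist(),
            "FrameDuration": image.schedule.frame_duration.tolist(),
            "Units": image.value_unit,
            "DecayCorrected": bool(image.decay_corrected),
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def _default_sidecar(image_path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def load_dynamic_image(image_path, sidecar_path=None) -> DynamicImage:
    """Load a NIfTI volume; a 4-D volume requires its timing sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if sidecar_path is None:
        candidate = _default_sidecar(image_path)
        sidecar_path = candidate if candidate.exists() else None
    if data.ndim == 3:
        unit, corrected = "kBq/mL", True
        if sidecar_path is not None:
            meta = json.loads(Path(sidecar_path).read_text())
            unit = meta.get("Units", unit)
            corrected = bool(meta.get("DecayCorrected", corrected))
        return DynamicImage(data, voxel_size, None, unit, corrected)
    if data.ndim != 4:
        raise SchemaError(f"expected 3-D or 4-D image, got {data.ndim}-D")
    if sidecar_path is None:
        raise SchemaError("4-D image requires a frame-timing sidecar")
    meta = json.loads(Path(sidecar_path).read_text())
    try:
        schedule = FrameSchedule(
            np.asarray(meta["FrameTimesStart"], dtype=float),
            np.asarray(meta["FrameDuration"], dtype=float),
        )
    except KeyError as exc:
        raise SchemaError(f"sidecar missing key {exc}") from exc
    return DynamicImage(
        data,
        voxel_size,
        schedule,
        meta.get("Units", "kBq/mL"),
        bool(meta.get("DecayCorrected", True)),
    )


def save_mask(mask: RoiMask, path, voxel_size_mm=(2.0, 2.0, 2.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def load_mask(path, label="roi") -> RoiMask:
    data = np.asarray(nib.load(str(path)).dataobj)
    return RoiMask(data > 0, label=label)


# ---------------------------------------------------------------------------
# Region extraction and decay handling


def extract_tac(image: DynamicImage, mask: RoiMask) -> TimeActivityCurve:
    """Per-frame arithmetic mean of the image over the mask voxels."""
    if mask.voxels.shape != image.voxels.shape[:3]:
        raise SchemaError(
            f"mask grid {mask.voxels.shape} does not match image grid "
            f"{image.voxels.shape[:3]}"
        )
    if mask.n_voxels == 0:
        raise ValueError("cannot extract a TAC from an empty mask")
    if image.voxels.ndim == 3:
        time = np.array([0.0])
        values = np.array([image.voxels[mask.voxels].mean()])
    else:
        time = image.schedule.mid_times_min
        values = image.voxels[mask.voxels, :].mean(axis=0)
    return TimeActivityCurve(
        time, values, n_voxels=mask.n_voxels, label=mask.label,
        decay_corrected=image.decay_corrected,
    )


def decay_correct(
    tac: TimeActivityCurve, meta: SubjectMeta, target: str = "injection_time"
) -> TimeActivityCurve:
    """Decay-correct a TAC to injection time, or undo that correction.

    Correction multiplies each frame by ``exp(ln2 * t_mid / T_half)``.  The
    ``decay_corrected`` flag tracks state so a curve cannot be corrected
    twice; ``target='none'`` removes an existing correction.
    """
    if target not in ("injection_time", "none"):
        raise ValueError("target must be 'injection_time' or 'none'")
    factor = np.exp(np.log(2.0) * tac.time_min / meta.isotope_half_life_min)
    if target == "injection_time":
        if tac.decay_corrected:
            raise ValueError("curve is already decay-corrected to injection time")
        return dataclasses.replace(tac, value=tac.value * factor, decay_corrected=True)
    if not tac.decay_corrected:
        raise ValueError("curve is already uncorrected")
    return dataclasses.replace(tac, value=tac.value / factor, decay_corrected=False)
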