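"""Reading and writing dynamic PET series, frame schedules, masks and TACs.

Contract notes
--------------
* Activity values are assumed to be decay-corrected to injection time by the
  scanner reconstruction; this package performs no decay correction.
* Frame timing travels in a CSV sidecar (``frame_start_s,frame_duration_s``)
  because NIfTI-1 has no reliable per-frame duration convention.
* Spatial coordinates are 0-based voxel indices; physical spacing is used
  only for documentation of erosion depth and for phantom geometry.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

SCHEDULE_COLUMNS = ("frame_start_s", "frame_duration_s")
TAC_COLUMNS = ("frame_mid_s", "activity_Bq_per_mL")

#: Printed framing schemes as (frame count, frame duration in s) spans.
FRAMING_PRESETS: dict[str, tuple[tuple[int, float], ...]] = {
    # 29 frames, 27 min
    "acetate_27min": ((1, 10), (12, 5), (5, 10), (2, 30), (3, 60), (3, 120), (3, 300)),
    # 22 frames, 400 s
    "water_6min": ((1, 10), (8, 5), (4, 20), (2, 15), (3, 20), (2, 30), (2, 60)),
}

_OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Start time and duration (seconds) of each dynamic frame."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise ValueError("frame_start and frame_duration must be 1D and equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[:-1] + dur[:-1] > start[1:] + _OVERLAP_TOL):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_time(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_duration(self) -> float:
        """Sum of frame durations in seconds."""
        return float(self.frame_duration.sum())

    @classmethod
    def from_spans(
        cls, spans: Sequence[Tuple[int, float]], origin: float = 0.0
    ) -> "FrameSchedule":
        """Build a contiguous schedule from (count, duration) spans."""
        durations = np.concatenate([np.full(int(n), float(d)) for n, d in spans])
        starts = origin + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @classmethod
    def from_preset(cls, name: str) -> "FrameSchedule":
        try:
            spans = FRAMING_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown framing preset {name!r}; choose from {sorted(FRAMING_PRESETS)}"
            ) from None
        return cls.from_spans(spans)


@dataclass(frozen=True)
class DynamicSeries:
    """4D activity-concentration volume (Bq/mL) with its frame schedule."""

    voxels: np.ndarray  # (x, y, z, t)
    spacing: Tuple[float, float, float]  # mm
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if vox.ndim != 4:
            raise ValueError(f"dynamic series must be 4D, got {vox.ndim}D")
        if vox.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"time axis has {vox.shape[3]} points but schedule has "
                f"{self.schedule.n_frames} frames"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean activity (Bq/mL) of a region."""

    mid_time: np.ndarray  # s
    value: np.ndarray  # Bq/mL
    schedule: Optional[FrameSchedule] = None

    def __post_init__(self) -> None:
        mid = np.asarray(self.mid_time, dtype=float)
        val = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "mid_time", mid)
        object.__setattr__(self, "value", val)
        if mid.ndim != 1 or val.ndim != 1 or mid.size != val.size:
            raise ValueError("mid_time and value must be 1D and equal length")
        if mid.size == 0:
            raise ValueError("TAC must contain at least one frame")
        if np.any(np.diff(mid) <= 0):
            raise ValueError("mid-times must be strictly increasing")
        if self.schedule is not None:
            if self.schedule.n_frames != mid.size:
                raise ValueError("TAC length does not match schedule")
            if not np.allclose(mid, self.schedule.mid_time, rtol=0, atol=1e-6):
                raise ValueError("mid-times inconsistent with schedule")

    @property
    def n_frames(self) -> int:
        return int(self.mid_time.size)

    @classmethod
    def from_schedule(cls, schedule: FrameSchedule, values: np.ndarray) -> "TimeActivityCurve":
        return cls(schedule.mid_time, values, schedule)


@dataclass(frozen=True)
class AcquisitionContext:
    """Per-study scalars entered by the operator."""

    injected_dose_bq: float  # decay-corrected to injection time
    heart_rate_per_min: float
    injection_time_s: float = 0.0  # scan starts simultaneously with injection

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0:
            raise ValueError("injected dose must be positive")
        if self.heart_rate_per_min <= 0:
            raise ValueError("heart rate must be positive")

    @classmethod
    def from_mbq(
        cls, dose_mbq: float, heart_rate_per_min: float, injection_time_s: float = 0.0
    ) -> "AcquisitionContext":
        return cls(dose_mbq * 1e6, heart_rate_per_min, injection_time_s)

    @property
    def injected_dose_mbq(self) -> float:
        return self.injected_dose_bq / 1e6


# ---------------------------------------------------------------------------
# schedule CSV
# ---------------------------------------------------------------------------

def read_schedule(path: str | os.PathLike) -> FrameSchedule:
    """Read a frame schedule from its CSV sidecar."""
    df = _read_csv(path)
    _require_columns(df, SCHEDULE_COLUMNS, path)
    return FrameSchedule(
        _numeric_column(df, "frame_start_s", path),
        _numeric_column(df, "frame_duration_s", path),
    )


def write_schedule(schedule: FrameSchedule, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "frame_start_s": schedule.frame_start,
            "frame_duration_s": schedule.frame_duration,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dynamic series NIfTI
# ---------------------------------------------------------------------------

def read_dynamic_series(
    image_path: str | os.PathLike, schedule_path: str | os.PathLike
) -> DynamicSeries:
    """Load a 4D NIfTI series plus its frame-schedule sidecar.

    Raises ``ValueError`` if the image is not 4D or the schedule row count
    does not match the image time axis.
    """
    img = nib.load(str(image_path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4D dynamic series, got {img.ndim}D image")
    schedule = read_schedule(schedule_path)
    voxels = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicSeries(voxels, spacing, schedule)


def write_dynamic_series(series: DynamicSeries, path: str | os.PathLike) -> None:
    affine = np.diag(list(series.spacing) + [1.0])
    nib.save(nib.Nifti1Image(series.voxels, affine), str(path))


# ---------------------------------------------------------------------------
# masks / label volumes
# ---------------------------------------------------------------------------

def write_mask(
    labels: np.ndarray, reference: DynamicSeries, path: str | os.PathLike
) -> None:
    """Write an integer label volume on the reference geometry."""
    labels = np.asarray(labels)
    if labels.shape != reference.spatial_shape:
        raise ValueError(
            f"label shape {labels.shape} does not match series grid "
            f"{reference.spatial_shape}"
        )
    if labels.min() < 0:
        raise ValueError("labels must be non-negative integers")
    dtype = np.uint8 if labels.max() < 256 else np.uint16
    affine = np.diag(list(reference.spacing) + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(dtype), affine), str(path))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got {img.ndim}D image")
    return np.asarray(img.dataobj).astype(np.int64)


# ---------------------------------------------------------------------------
# TAC CSV
# ---------------------------------------------------------------------------

def write_tac(tac: TimeActivityCurve, path: str | os.PathLike) -> None:
    """Write a TAC as CSV; negative values pass through unclamped."""
    data = {"frame_mid_s": tac.mid_time, "activity_Bq_per_mL": tac.value}
    if tac.schedule is not None:
        data["frame_start_s"] = tac.schedule.frame_start
        data["frame_duration_s"] = tac.schedule.frame_duration
    pd.DataFrame(data).to_csv(path, index=False)


def read_tac(path: str | os.PathLike) -> TimeActivityCurve:
    df = _read_csv(path)
    _require_columns(df, TAC_COLUMNS, path)
    schedule = None
    if all(c in df.columns for c in SCHEDULE_COLUMNS):
        schedule = FrameSchedule(
            _numeric_column(df, "frame_start_s", path),
            _numeric_column(df, "frame_duration_s", path),
        )
    return TimeActivityCurve(
        _numeric_column(df, "frame_mid_s", path),
        _numeric_column(df, "activity_Bq_per_mL", path),
        schedule,
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_csv(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric_column(df: pd.DataFrame, name: str, path) -> np.ndarray:
    col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    if np.isnan(col).any() and not df[name].isna().any():
        raise ValueError(f"{path}: non-numeric values in column {name!r}")
    if np.isnan(col).any():
        raise ValueError(f"{path}: missing values in column {name!r}")
    return col
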