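"""Grid-aware volume/time-series containers and file I/O.

Conventions used throughout the package:

* voxel indices are 0-based; the world coordinate of voxel ``(i, j, k)`` is
  ``origin + (i*dx, j*dy, k*dz)`` and refers to the voxel *center*;
* grids are axis-aligned (spacing + origin, no rotation); the third axis is
  the axial/slice direction;
* activity concentrations are kBq/mL, times are seconds, lengths mm.

Volumes are stored/loaded as NIfTI-1 (.nii/.nii.gz), tabular data (frame
schedules, blood samples, time-activity curves) as single-header TSV.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "FrameSchedule",
    "DynamicSeries",
    "TimeActivityCurve",
    "BloodSampleSeries",
    "load_volume",
    "save_volume",
    "load_dynamic_series",
    "save_dynamic_series",
    "load_blood_samples",
    "load_tac",
    "write_tac",
    "default_frame_schedule",
]


@dataclass
class Volume3D:
    """Scalar field on a regular, axis-aligned 3-D voxel grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"Volume3D requires a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if min(self.values.shape) < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=np.float64)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_grid(self, other: "Volume3D", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "Volume3D":
        """New volume with the same grid metadata but different values."""
        return Volume3D(values, self.spacing, self.origin)


@dataclass
class FrameSchedule:
    """Contiguous, non-overlapping dynamic-frame timing (seconds)."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.float64)
        self.durations = np.asarray(self.durations, dtype=np.float64)
        if self.starts.ndim != 1 or self.starts.shape != self.durations.shape:
            raise ValueError("starts and durations must be 1-D with equal length")
        if np.any(self.durations <= 0):
            raise ValueError("frame durations must be positive")
        if len(self.starts) > 1:
            expected = self.starts[:-1] + self.durations[:-1]
            if not np.allclose(self.starts[1:], expected, atol=1e-9):
                raise ValueError("frames must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FrameSchedule":
        df = pd.read_csv(path, sep="\t")
        for col in ("frame_start_s", "frame_duration_s"):
            if col not in df.columns:
                raise ValueError(f"frame table {path} lacks required column '{col}'")
        return cls(df["frame_start_s"].to_numpy(float), df["frame_duration_s"].to_numpy(float))

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"frame_start_s": self.starts, "frame_duration_s": self.durations}
        ).to_csv(path, sep="\t", index=False)


def default_frame_schedule() -> FrameSchedule:
    """The 46-frame, 300-s dynamic schedule: 20x3, 12x5, 12x10, 2x30 s."""
    durations = np.concatenate([np.full(20, 3.0), np.full(12, 5.0), np.full(12, 10.0), np.full(2, 30.0)])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass
class DynamicSeries:
    """Ordered dynamic frames on a shared grid, stored as a 4-D array (x,y,z,t)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    schedule: FrameSchedule
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("DynamicSeries requires a 4-D array (x, y, z, t)")
        if self.values.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame count mismatch: image has {self.values.shape[3]} frames, "
                f"schedule has {len(self.schedule)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def frame(self, i: int) -> Volume3D:
        return Volume3D(self.values[..., i], self.spacing, self.origin)

    @property
    def frames(self) -> list[Volume3D]:
        return [self.frame(i) for i in range(self.n_frames)]

    def max_over_time(self) -> Volume3D:
        """Voxel-wise maximum over all frames (the PET bolus reference image)."""
        return Volume3D(self.values.max(axis=3), self.spacing, self.origin)

    def mean_over_time(self) -> Volume3D:
        return Volume3D(self.values.mean(axis=3), self.spacing, self.origin)


@dataclass
class TimeActivityCurve:
    """Activity concentration (kBq/mL) versus time (s)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D with equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BloodSampleSeries:
    """Manually/automatically drawn arterial blood samples."""

    times: np.ndarray
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D with equal length")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("blood sample times/values must be finite")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("blood sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def as_tac(self) -> TimeActivityCurve:
        return TimeActivityCurve(self.times, self.values)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _grid_from_header(img) -> tuple[tuple, tuple]:
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def load_volume(path: str | os.PathLike) -> Volume3D:
    """Load a 3-D NIfTI image; spacing comes from the header pixel dimensions."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        raise ValueError(
            f"{path} is a 4-D image; use load_dynamic_series() for dynamic data"
        )
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got ndim={data.ndim}")
    spacing, origin = _grid_from_header(img)
    return Volume3D(data, spacing, origin)


def save_volume(volume: Volume3D, path: str | os.PathLike, dtype=np.float64) -> None:
    img = nib.Nifti1Image(volume.values.astype(dtype), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_dynamic_series(path: str | os.PathLike, frames: str | os.PathLike) -> DynamicSeries:
    """Load a 4-D NIfTI series together with its frame-timing TSV."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got ndim={data.ndim}")
    schedule = FrameSchedule.from_tsv(frames)
    spacing, origin = _grid_from_header(img)
    return DynamicSeries(data, spacing, schedule, origin)


def save_dynamic_series(series: DynamicSeries, path: str | os.PathLike,
                        frames: str | os.PathLike | None = None) -> None:
    img = nib.Nifti1Image(series.values, _affine(series.spacing, series.origin))
    img.header.set_zooms(series.spacing + (1.0,))
    nib.save(img, str(path))
    if frames is not None:
        series.schedule.to_tsv(frames)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_blood_samples(path: str | os.PathLike, subject_id: str = "") -> BloodSampleSeries:
    """Read a blood-sample TSV (time_s, activity_kBq_per_mL), sorted by time."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("time_s", "activity_kBq_per_mL"):
        if col not in df.columns:
            raise ValueError(f"blood sample table {path} lacks required column '{col}'")
    times = pd.to_numeric(df["time_s"], errors="raise").to_numpy(float)
    values = pd.to_numeric(df["activity_kBq_per_mL"], errors="raise").to_numpy(float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    if len(times) > 1 and np.any(np.diff(times) == 0):
        raise ValueError(f"duplicate sample times in {path}")
    return BloodSampleSeries(times, values, subject_id=subject_id)


def write_tac(tac: TimeActivityCurve, path: str | os.PathLike) -> None:
    """Write a TAC as TSV with full float precision (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("time_s\tactivity_kBq_per_mL\n")
        for t, v in zip(tac.times, tac.values):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def load_tac(path: str | os.PathLike) -> TimeActivityCurve:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return TimeActivityCurve(df["time_s"].to_numpy(float),
                             df["activity_kBq_per_mL"].to_numpy(float))


def write_json(obj: dict, path: str | os.PathLike) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return super().default(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Encoder)
        fh.write("\n")
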