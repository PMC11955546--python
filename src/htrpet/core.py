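"""Domain types, unit conventions and file I/O.

Conventions used throughout the package:

* time is in **seconds** internally; t = 0 is tracer injection / scan start;
* rate constants (CBF, K1 in ml/min/cm^3 of voxel, k2 in 1/min) are expressed
  per **minute** at every public interface and converted at the API boundary;
* activity concentrations are kBq/ml and assumed decay-corrected on input;
* frame values are treated as frame averages on input while model curves are
  evaluated at frame mid-times t_m = start + duration/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeSeriesCurve",
    "InputFunction",
    "AATHParams",
    "S1TCParams",
    "DerivedParams",
    "DynamicImage",
    "read_tac_table",
    "write_tac_table",
    "per_minute_to_per_second",
    "per_second_to_per_minute",
    "ScheduleError",
    "CoverageError",
]


class ScheduleError(ValueError):
    """Raised for non-contiguous, overlapping or otherwise invalid framing."""


class CoverageError(ValueError):
    """Raised when an input function does not cover the requested schedule."""


def per_minute_to_per_second(value: float | np.ndarray) -> float | np.ndarray:
    """Convert a per-minute rate (e.g. ml/min/cm^3 or 1/min) to per-second."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("rates must be finite and non-negative")
    out = arr / 60.0
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def per_second_to_per_minute(value: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`per_minute_to_per_second` (exact round trip)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("rates must be finite and non-negative")
    out = arr * 60.0
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-PET framing (seconds).

    The default high-temporal-resolution (HTR) protocol is 60 frames of 1 s
    followed by 30 frames of 2 s: a 2-minute acquisition with M = 90 frames.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape or start.size == 0:
            raise ScheduleError("frame_start and frame_duration must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(start)) and np.all(np.isfinite(dur))):
            raise ScheduleError("non-finite frame times")
        if np.any(dur <= 0):
            raise ScheduleError("frame durations must be positive")
        ends = start + dur
        if not np.allclose(start[1:], ends[:-1], rtol=0, atol=1e-9):
            raise ScheduleError("frames must be contiguous and non-overlapping")

    @classmethod
    def default_htr(cls) -> "FrameSchedule":
        """60 x 1 s then 30 x 2 s frames (120 s total, M = 90)."""
        dur = np.concatenate([np.ones(60), np.full(30, 2.0)])
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-point times t_m = start + duration/2 (strictly increasing)."""
        return self.frame_start + self.frame_duration / 2.0

    @property
    def end_time(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.frame_start.shape == other.frame_start.shape
            and np.array_equal(self.frame_start, other.frame_start)
            and np.array_equal(self.frame_duration, other.frame_duration)
        )


@dataclass
class TimeSeriesCurve:
    """A time-activity curve (TAC): one activity concentration per frame, kBq/ml."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""
    noisy: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.schedule.n_frames:
            raise ValueError("values length must equal the number of frames")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TAC values must be finite")
        if not self.noisy and np.any(vals < -1e-12):
            raise ValueError("negative TAC values are only permitted when flagged noisy")
        self.values = vals

    def with_values(self, values: np.ndarray, label: str | None = None, noisy: bool | None = None) -> "TimeSeriesCurve":
        return TimeSeriesCurve(
            self.schedule,
            values,
            self.label if label is None else label,
            self.noisy if noisy is None else noisy,
        )


@dataclass
class InputFunction:
    """Arterial input: whole-blood and plasma curves plus a parent fraction.

    With the early-scan assumption that whole-blood activity equals plasma
    activity (valid over the first two minutes for tracers without significant
    metabolites), ``whole_blood`` and ``plasma`` hold identical values.  The
    plasma *parent* concentration used by the extravascular term of the tissue
    models is ``plasma * parent_fraction`` elementwise.

    A densely sampled representation (``fine_times`` / ``fine_whole_blood`` /
    ``fine_plasma``) may be attached by generators; when absent, fine-grid
    evaluation linearly interpolates the frame-sampled curves, taking the
    input as zero before t = 0.
    """

    whole_blood: TimeSeriesCurve
    plasma: TimeSeriesCurve
    parent_fraction: np.ndarray | None = None
    fine_times: np.ndarray | None = None
    fine_whole_blood: np.ndarray | None = None
    fine_plasma: np.ndarray | None = None
    fine_parent_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.whole_blood.schedule != self.plasma.schedule:
            raise ValueError("whole-blood and plasma curves must share a schedule")
        m = self.whole_blood.schedule.n_frames
        if self.parent_fraction is None:
            self.parent_fraction = np.ones(m)
        pf = np.asarray(self.parent_fraction, dtype=float)
        if pf.shape != (m,):
            raise ValueError("parent_fraction must have one value per frame")
        if np.any(pf < 0) or np.any(pf > 1):
            raise ValueError("parent_fraction values must lie in [0, 1]")
        self.parent_fraction = pf
        fine = [self.fine_times, self.fine_whole_blood, self.fine_plasma]
        if any(f is not None for f in fine) and any(f is None for f in fine):
            raise ValueError("fine_times, fine_whole_blood and fine_plasma must be given together")

    @property
    def schedule(self) -> FrameSchedule:
        return self.whole_blood.schedule

    def plasma_parent(self) -> TimeSeriesCurve:
        """Metabolite-corrected plasma curve: plasma * parent_fraction."""
        return self.plasma.with_values(self.plasma.values * self.parent_fraction, label="plasma_parent")

    def sample_fine(self, fine_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Whole-blood and parent-plasma concentrations on a fine time grid.

        Returns ``(c_wb, c_p_parent)`` sampled at ``fine_times`` (seconds, all
        >= 0).  Values beyond the last available sample hold the last value;
        the input is zero before t = 0 by construction.
        """
        t = np.asarray(fine_times, dtype=float)
        if np.any(t < 0):
            raise ValueError("fine sample times must be non-negative")
        if self.fine_times is not None:
            src_t = self.fine_times
            wb = np.interp(t, src_t, self.fine_whole_blood)
            cp = np.interp(t, src_t, self.fine_plasma)
            if self.fine_parent_fraction is not None:
                pf = np.interp(t, src_t, self.fine_parent_fraction)
            else:
                pf = np.interp(t, self.schedule.mid_times, self.parent_fraction)
            return wb, cp * pf
        tm = self.schedule.mid_times
        # anchor at (0, 0): no tracer in blood before injection
        src_t = np.concatenate([[0.0], tm]) if tm[0] > 0 else tm
        wb_v = self.whole_blood.values
        cp_v = self.plasma.values * self.parent_fraction
        wb_src = np.concatenate([[0.0], wb_v]) if tm[0] > 0 else wb_v
        cp_src = np.concatenate([[0.0], cp_v]) if tm[0] > 0 else cp_v
        return np.interp(t, src_t, wb_src), np.interp(t, src_t, cp_src)

    def coverage_end(self) -> float:
        return float(self.fine_times[-1]) if self.fine_times is not None else self.schedule.end_time


def _check_rate(name: str, value: float) -> float:
    v = float(value)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return v


@dataclass(frozen=True)
class AATHParams:
    """AATH model parameters.

    cbf, k1 : ml/min/cm^3 voxel; k2 : 1/min; tc (mean vascular transit time)
    and td (aorta-to-tissue delay) : seconds.  The extraction fraction
    E = k1/cbf must not exceed 1.
    """

    cbf: float
    k1: float
    k2: float
    tc: float
    td: float

    def __post_init__(self) -> None:
        for name in ("cbf", "k1", "k2", "tc", "td"):
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))
        if self.k1 > self.cbf * (1 + 1e-9) + 1e-15:
            raise ValueError(f"K1 ({self.k1}) must not exceed CBF ({self.cbf}); E <= 1 required")

    @property
    def extraction(self) -> float:
        return self.k1 / self.cbf if self.cbf > 0 else 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.cbf, self.k1, self.k2, self.tc, self.td])


@dataclass(frozen=True)
class S1TCParams:
    """Standard one-tissue-compartment parameters (instantaneous vascular mixing).

    vb : ml/cm^3 voxel (blood volume fraction, <= 1); k1 : ml/min/cm^3;
    k2 : 1/min; td : seconds.
    """

    vb: float
    k1: float
    k2: float
    td: float

    def __post_init__(self) -> None:
        for name in ("vb", "k1", "k2", "td"):
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))
        if self.vb > 1 + 1e-9:
            raise ValueError(f"vb ({self.vb}) must not exceed 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.vb, self.k1, self.k2, self.td])


@dataclass(frozen=True)
class DerivedParams:
    """Quantities derived from an AATH fit.

    e : extraction fraction K1/CBF; ps : permeability-surface-area product
    (ml/min/cm^3), indeterminate when E == 1; vb = CBF*Tc (ml/cm^3);
    ve = K1/k2 (ml/cm^3, None when k2 == 0).
    """

    e: float
    ps: float
    vb: float
    ve: float | None = None
    ps_indeterminate: bool = False


@dataclass
class DynamicImage:
    """A 4-D dynamic image: voxel array (x, y, z, frame) in kBq/ml."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 4 or arr.shape[3] != self.schedule.n_frames:
            raise ValueError("data must be 4-D with frame axis length M")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        self.data = arr

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine()), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, schedule: FrameSchedule) -> "DynamicImage":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.dataobj, dtype=float), tuple(float(z) for z in zooms), schedule)


# ---------------------------------------------------------------------------
# TAC tables


def read_tac_table(path: str | Path) -> tuple[FrameSchedule, list[TimeSeriesCurve]]:
    """Read a TAC table (CSV or TSV, auto-detected; header row mandatory).

    The first two columns must be ``frame_start_s`` and ``frame_duration_s``;
    every further column is one curve (kBq/ml), named by its header.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"could not parse TAC table {path}: {exc}") from exc
    required = {"frame_start_s", "frame_duration_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"TAC table must contain columns {sorted(required)}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(float), df["frame_duration_s"].to_numpy(float))
    curves = [
        TimeSeriesCurve(schedule, df[col].to_numpy(float), label=str(col), noisy=True)
        for col in df.columns
        if col not in required
    ]
    return schedule, curves


def write_tac_table(path: str | Path, schedule: FrameSchedule, curves: Sequence[TimeSeriesCurve]) -> None:
    """Write curves sharing one schedule to CSV (TSV if the suffix is .tsv)."""
    for c in curves:
        if c.schedule != schedule:
            raise ValueError(f"curve {c.label!r} does not share the table schedule")
    data = {"frame_start_s": schedule.frame_start, "frame_duration_s": schedule.frame_duration}
    for i, c in enumerate(curves):
        data[c.label or f"curve_{i}"] = c.values
    sep = "\t" if str(path).endswith(".tsv") else ","
    # %.17g keeps the text round trip bit-exact for float64
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
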