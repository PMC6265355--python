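"""Core domain types for dynamic-PET quantification.

Conventions used throughout the package: time is in minutes, activity in
kBq/mL, and frame indices are 1-based in error messages. Blood curves are
shifted *later* in time by a positive ``delay``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TAC",
    "BloodInput",
    "VoxelDataset",
    "StudyTable",
    "default_schedule",
    "interpolate_input",
    "frame_midpoints",
    "frame_durations",
]

#: decay constant of carbon-11 (half-life 20.4 min), 1/min
C11_LAMBDA = np.log(2.0) / 20.4


class ScheduleError(ValueError):
    """Raised for overlapping, inverted or otherwise invalid frame timing."""


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic scan: per-frame start and end, minutes.

    Frames must be strictly increasing and non-overlapping; gaps between
    consecutive frames are allowed but reported via :attr:`has_gaps`.
    """

    start_times: np.ndarray
    end_times: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_times, dtype=float)
        end = np.asarray(self.end_times, dtype=float)
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "end_times", end)
        if start.shape != end.shape or start.ndim != 1:
            raise ScheduleError("start_times and end_times must be 1-D and equal length")
        if np.any(end <= start):
            bad = int(np.argmax(end <= start)) + 1
            raise ScheduleError(f"frame {bad}: end must exceed start")
        if start.size > 1:
            if np.any(np.diff(start) <= 0):
                raise ScheduleError("frame start times must be strictly increasing")
            if np.any(start[1:] < end[:-1] - 1e-9):
                bad = int(np.argmax(start[1:] < end[:-1] - 1e-9)) + 1
                raise ScheduleError(f"frames {bad} and {bad + 1} overlap")

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    def __len__(self) -> int:
        return self.n_frames

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.start_times + self.end_times)

    @property
    def durations(self) -> np.ndarray:
        return self.end_times - self.start_times

    @property
    def total_duration(self) -> float:
        """Sum of frame durations, minutes (excludes gaps)."""
        return float(self.durations.sum())

    @property
    def scan_end(self) -> float:
        return float(self.end_times[-1]) if self.n_frames else 0.0

    @property
    def has_gaps(self) -> bool:
        if self.n_frames < 2:
            return False
        return bool(np.any(self.start_times[1:] > self.end_times[:-1] + 1e-9))

    @property
    def is_short_scan(self) -> bool:
        """True when the scan ends before 60 min (e.g. the 50-min session)."""
        return self.scan_end < 60.0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and self.n_frames == other.n_frames
            and np.array_equal(self.start_times, other.start_times)
            and np.array_equal(self.end_times, other.end_times)
        )

    def __hash__(self):
        return hash((self.start_times.tobytes(), self.end_times.tobytes()))


def default_schedule(total_min: float = 63.0) -> FrameSchedule:
    """Default 24-frame schedule: 4x0.25, 4x0.5, 4x1, 4x2, 4x4, 4x8 min.

    For ``total_min`` < 63 the schedule is truncated at the first frame end
    that reaches ``total_min`` (used for the 50-min session; 50 min is hit
    mid-block, so the last frame is shortened).
    """
    durs = np.repeat([0.25, 0.5, 1.0, 2.0, 4.0, 8.0], 4)
    end = np.cumsum(durs)
    start = end - durs
    if total_min < end[-1]:
        keep = start < total_min
        start, end = start[keep], end[keep]
        end[-1] = min(end[-1], total_min)
    return FrameSchedule(start, end)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    return schedule.midpoints


def frame_durations(schedule: FrameSchedule) -> np.ndarray:
    return schedule.durations


def default_weights(schedule: FrameSchedule, decay_lambda: float = C11_LAMBDA) -> np.ndarray:
    """Count-proportional fit weights: duration * exp(-lambda * midpoint)."""
    return schedule.durations * np.exp(-decay_lambda * schedule.midpoints)


@dataclass
class TAC:
    """A single region's time-activity curve on a frame schedule.

    values are decay-corrected activity concentrations, kBq/mL; weights are
    nonnegative fit weights (defaulting to count-proportional ones when a
    fitter needs them and none are set).
    """

    schedule: FrameSchedule
    values: np.ndarray
    weights: np.ndarray | None = None
    region_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"TAC '{self.region_label}': {self.values.size} values for "
                f"{self.schedule.n_frames} frames"
            )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights length must equal frame count")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")

    @property
    def is_short_scan(self) -> bool:
        return self.schedule.is_short_scan

    def effective_weights(self) -> np.ndarray:
        if self.weights is not None:
            return self.weights
        return default_weights(self.schedule)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TAC":
        return TAC(self.schedule, np.asarray(values, float), self.weights,
                   self.region_label if label is None else label)


@dataclass
class BloodInput:
    """Metabolite-corrected plasma and whole-blood curves with a delay.

    ``delay`` (minutes) shifts both blood curves later in time relative to
    the tissue data when positive. Interpolation is piecewise linear, zero
    before the first (shifted) sample and last-value extrapolated beyond the
    last sample.
    """

    sample_times: np.ndarray
    plasma_parent: np.ndarray
    whole_blood: np.ndarray
    delay: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least two blood samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing and start >= 0")
        self.sample_times = t
        self.plasma_parent = np.asarray(self.plasma_parent, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        for name in ("plasma_parent", "whole_blood"):
            arr = getattr(self, name)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match sample_times in length")

    def with_delay(self, delay: float) -> "BloodInput":
        return replace(self, delay=float(delay))

    def interp(self, t, component: str = "plasma", warn_extrapolate: bool = True):
        return interpolate_input(self, t, component, warn_extrapolate=warn_extrapolate)


def interpolate_input(
    blood: BloodInput,
    t,
    component: str = "plasma",
    *,
    warn_extrapolate: bool = True,
) -> np.ndarray:
    """Evaluate a blood curve at times ``t`` (minutes), honouring the delay.

    The curve is zero before the first shifted sample; beyond the last
    sample the final value is held with a warning.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("interpolation times must be >= 0")
    if component in ("plasma", "plasma_parent"):
        y = blood.plasma_parent
    elif component == "whole_blood":
        y = blood.whole_blood
    else:
        raise ValueError(f"unknown blood component {component!r}")
    ts = blood.sample_times + blood.delay
    out = np.interp(t, ts, y, left=0.0, right=y[-1])
    # the shift can push the first sample past t=0; everything earlier is 0
    if warn_extrapolate and np.any(t > ts[-1] + 1e-12):
        warnings.warn(
            "blood curve extrapolated (last value held) beyond "
            f"{ts[-1]:.2f} min",
            stacklevel=2,
        )
    return out


@dataclass
class VoxelDataset:
    """Voxel-level dynamic data: a voxels x frames matrix plus geometry.

    ``grid_shape`` is set for image-backed data (rows are the C-order ravel
    of the grid); purely tabular voxel lists leave it None, which disables
    spatial smoothing.
    """

    voxel_tacs: np.ndarray
    schedule: FrameSchedule
    brain_mask: np.ndarray | None = None
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.voxel_tacs = np.asarray(self.voxel_tacs, dtype=float)
        if self.voxel_tacs.ndim != 2:
            raise ValueError("voxel_tacs must be 2-D (voxels x frames)")
        if self.voxel_tacs.shape[1] != self.schedule.n_frames:
            raise ValueError("voxel_tacs frame count does not match schedule")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.voxel_tacs.shape[0], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != (self.voxel_tacs.shape[0],):
                raise ValueError("brain_mask length must equal voxel count")
        if self.grid_shape is not None:
            self.grid_shape = tuple(int(s) for s in self.grid_shape)
            if int(np.prod(self.grid_shape)) != self.voxel_tacs.shape[0]:
                raise ValueError("grid_shape does not match voxel count")

    @property
    def n_voxels(self) -> int:
        return self.voxel_tacs.shape[0]


STUDY_COLUMNS = [
    "subject_id", "session", "region", "outcome", "value",
    "injected_dose_MBq", "body_weight_kg",
]


@dataclass
class StudyTable:
    """Long-format subject x session x region x outcome table.

    The canonical input of every reliability / validity statistic. At most
    one value per (subject, session, region, outcome); sessions are 1 or 2.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=STUDY_COLUMNS))

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        for col in STUDY_COLUMNS:
            if col not in df.columns:
                if col in ("injected_dose_MBq", "body_weight_kg"):
                    df[col] = np.nan
                else:
                    raise ValueError(f"StudyTable missing column {col!r}")
        if len(df):
            if not df["session"].isin([1, 2]).all():
                raise ValueError("sessions must be 1 or 2")
            key = ["subject_id", "session", "region", "outcome"]
            if df.duplicated(subset=key).any():
                dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
                raise ValueError(
                    "duplicate study record for "
                    f"{tuple(dup[k] for k in key)}"
                )
        self.data = df[STUDY_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcomes(self) -> list[str]:
        return sorted(self.data["outcome"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.data["region"].unique())

    def add(self, subject_id, session, region, outcome, value,
            injected_dose_MBq=np.nan, body_weight_kg=np.nan) -> None:
        row = pd.DataFrame([{
            "subject_id": subject_id, "session": int(session), "region": region,
            "outcome": outcome, "value": float(value),
            "injected_dose_MBq": injected_dose_MBq, "body_weight_kg": body_weight_kg,
        }])
        self.data = StudyTable(pd.concat([self.data, row], ignore_index=True)).data

    def pairs(self, outcome: str, region: str) -> pd.DataFrame:
        """Wide (test, retest) frame indexed by subject; complete pairs only."""
        sub = self.data[(self.data["outcome"] == outcome) & (self.data["region"] == region)]
        wide = sub.pivot(index="subject_id", columns="session", values="value")
        return wide.dropna().rename(columns={1: "test", 2: "retest"})
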