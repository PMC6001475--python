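"""Gaze sample and trial-event I/O, drift correction, and trial segmentation.

The on-disk dialects mirror a 250 Hz remote eye-tracker text export:

* gaze TSV — headered, one row per sample: ``participant_id, trial_id,
  t_ms (int), x (px), y (px), valid (0/1)``; monocular (right-eye) stream.
* events CSV — ``trial_id, duration_ms, speech_onset_ms, speech_offset_ms``.
* corrections CSV — ``participant_id, trial_id, dx, dy``; each correction
  re-anchors the calibration from the named trial onward (cumulatively),
  emulating the between-trial drift-correction fixations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NOMINAL_PERIOD_MS",
    "ScreenGeometry",
    "GazeSample",
    "GazeTrial",
    "TrialEvents",
    "SegmentWindows",
    "DriftCorrection",
    "SchemaError",
    "OrderingError",
    "UnknownTrialError",
    "EventConsistencyError",
    "read_gaze_table",
    "write_gaze_table",
    "read_events",
    "write_events",
    "read_corrections",
    "write_corrections",
    "apply_drift_corrections",
    "segment_windows",
    "sample_durations",
    "clipped_durations",
]

logger = logging.getLogger(__name__)

#: Nominal inter-sample period of the 250 Hz tracker, in ms.
NOMINAL_PERIOD_MS = 4.0


class SchemaError(ValueError):
    """An input table is missing required columns or is otherwise unreadable."""


class OrderingError(ValueError):
    """Timestamps within a trial are not strictly increasing."""


class UnknownTrialError(KeyError):
    """A drift correction references a participant/trial absent from the data."""


class EventConsistencyError(ValueError):
    """Trial event times violate 0 <= onset < offset <= duration."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Stimulus screen rectangle in pixels; origin top-left, y downward."""

    width_px: float = 1280.0
    height_px: float = 1024.0

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width_px) & (y >= 0) & (y <= self.height_px)


@dataclass(frozen=True)
class GazeSample:
    t: float
    x: float
    y: float
    valid: bool


@dataclass
class GazeTrial:
    """One participant x trial stream of timestamped monocular gaze samples."""

    participant_id: str
    trial_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if n and np.any(self.t < 0):
            raise ValueError("sample timestamps must be >= 0")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise OrderingError(
                f"participant {self.participant_id} trial {self.trial_id}: "
                "timestamps not strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def samples(self) -> Iterable[GazeSample]:
        for i in range(self.n_samples):
            yield GazeSample(float(self.t[i]), float(self.x[i]),
                             float(self.y[i]), bool(self.valid[i]))

    def shifted(self, dx: float, dy: float) -> "GazeTrial":
        return replace(self, x=self.x + dx, y=self.y + dy)


@dataclass(frozen=True)
class TrialEvents:
    """Hand-coded visual-speech onset/offset times for one stimulus video."""

    trial_id: int
    duration_ms: float
    speech_onset_ms: float
    speech_offset_ms: float

    def __post_init__(self) -> None:
        ok = (0 <= self.speech_onset_ms < self.speech_offset_ms <= self.duration_ms)
        if not ok:
            raise EventConsistencyError(
                f"trial {self.trial_id}: need 0 <= onset < offset <= duration, got "
                f"onset={self.speech_onset_ms}, offset={self.speech_offset_ms}, "
                f"duration={self.duration_ms}")


@dataclass(frozen=True)
class SegmentWindows:
    """Half-open pre-speech / speech / post-speech partition of a trial."""

    pre: tuple[float, float]
    speech: tuple[float, float]
    post: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"pre": self.pre, "speech": self.speech, "post": self.post}


@dataclass(frozen=True)
class DriftCorrection:
    """Calibration offset applying to the named trial and all later trials."""

    participant_id: str
    trial_id: int
    dx: float
    dy: float


def segment_windows(events: TrialEvents) -> SegmentWindows:
    """Partition [0, duration) into the three analysis segments."""
    return SegmentWindows(
        pre=(0.0, events.speech_onset_ms),
        speech=(events.speech_onset_ms, events.speech_offset_ms),
        post=(events.speech_offset_ms, events.duration_ms),
    )


def sample_durations(trial: GazeTrial,
                     nominal_period_ms: float = NOMINAL_PERIOD_MS) -> np.ndarray:
    """Duration credited to each sample: gap to the next sample, the nominal
    period for the last one.  Dropped frames are absorbed by the preceding
    sample."""
    if trial.n_samples == 0:
        return np.empty(0)
    d = np.diff(trial.t)
    return np.append(d, nominal_period_ms)


def clipped_durations(t: np.ndarray, durations: np.ndarray,
                      window: tuple[float, float]) -> np.ndarray:
    """Overlap of each sample's interval [t, t + duration) with a half-open window."""
    t = np.asarray(t, dtype=float)
    lo = np.maximum(t, window[0])
    hi = np.minimum(t + durations, window[1])
    return np.maximum(hi - lo, 0.0)


_GAZE_COLUMNS = ["participant_id", "trial_id", "t_ms", "x", "y", "valid"]
_EVENT_COLUMNS = ["trial_id", "duration_ms", "speech_onset_ms", "speech_offset_ms"]
_CORR_COLUMNS = ["participant_id", "trial_id", "dx", "dy"]


def read_gaze_table(source: str | Path,
                    screen: ScreenGeometry | None = None) -> list[GazeTrial]:
    """Read a gaze TSV into per-(participant, trial) streams.

    Rows with non-numeric fields are rejected individually and reported with
    their file row numbers through the module logger; structural problems
    (missing columns, non-monotone timestamps) raise.
    """
    screen = screen or ScreenGeometry()
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{source}: empty gaze file without header") from exc
    missing = set(_GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{source}: gaze table missing columns {sorted(missing)}")
    if df.empty:
        return []

    numeric = df[["t_ms", "x", "y", "valid"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | df["participant_id"].isna()
    if bad.any():
        for row in df.index[bad]:
            # +2: header line plus 1-based file numbering
            logger.warning("%s: rejecting malformed row %d: %s",
                           source, row + 2, df.loc[row].to_dict())
        df = df.loc[~bad]
        numeric = numeric.loc[~bad]
    df = df.assign(**{c: numeric[c] for c in numeric.columns})

    trials = []
    for (pid, tid), g in df.groupby(["participant_id", "trial_id"], sort=True):
        trials.append(GazeTrial(
            participant_id=str(pid),
            trial_id=int(float(tid)),
            t=g["t_ms"].to_numpy(dtype=float),
            x=g["x"].to_numpy(dtype=float),
            y=g["y"].to_numpy(dtype=float),
            valid=g["valid"].to_numpy(dtype=float) > 0.5,
            screen=screen,
        ))
    trials.sort(key=lambda tr: (tr.participant_id, tr.trial_id))
    return trials


def write_gaze_table(trials: Sequence[GazeTrial], dest: str | Path) -> None:
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "trial_id": tr.trial_id,
            "t_ms": tr.t.astype(np.int64),
            "x": tr.x,
            "y": tr.y,
            "valid": tr.valid.astype(int),
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=_GAZE_COLUMNS)
    out.to_csv(dest, sep="\t", index=False, float_format="%.6f")


def read_events(source: str | Path) -> dict[int, TrialEvents]:
    df = pd.read_csv(source)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{source}: events table missing columns {sorted(missing)}")
    return {
        int(r.trial_id): TrialEvents(int(r.trial_id), float(r.duration_ms),
                                     float(r.speech_onset_ms), float(r.speech_offset_ms))
        for r in df.itertuples()
    }


def write_events(events: Mapping[int, TrialEvents] | Sequence[TrialEvents],
                 dest: str | Path) -> None:
    if isinstance(events, Mapping):
        events = [events[k] for k in sorted(events)]
    pd.DataFrame([{
        "trial_id": e.trial_id, "duration_ms": e.duration_ms,
        "speech_onset_ms": e.speech_onset_ms, "speech_offset_ms": e.speech_offset_ms,
    } for e in events]).to_csv(dest, index=False, float_format="%.6g")


def read_corrections(source: str | Path) -> list[DriftCorrection]:
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        return []
    missing = set(_CORR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{source}: corrections table missing columns {sorted(missing)}")
    out = [DriftCorrection(str(r.participant_id), int(r.trial_id),
                           float(r.dx), float(r.dy)) for r in df.itertuples()]
    out.sort(key=lambda c: (c.participant_id, c.trial_id))
    return out


def write_corrections(corrections: Sequence[DriftCorrection], dest: str | Path) -> None:
    pd.DataFrame([{
        "participant_id": c.participant_id, "trial_id": c.trial_id,
        "dx": c.dx, "dy": c.dy,
    } for c in corrections], columns=_CORR_COLUMNS).to_csv(
        dest, index=False, float_format="%.6g")


def apply_drift_corrections(trials: Sequence[GazeTrial],
                            corrections: Sequence[DriftCorrection]) -> list[GazeTrial]:
    """Shift each trial by the cumulative offset of all corrections at or
    before it (per participant); validity flags are untouched."""
    known = {(tr.participant_id, tr.trial_id) for tr in trials}
    for c in corrections:
        if not any(pid == c.participant_id and tid >= c.trial_id
                   for pid, tid in known):
            raise UnknownTrialError(
                f"drift correction references unknown participant/trial "
                f"({c.participant_id}, {c.trial_id})")
    out = []
    for tr in trials:
        dx = sum(c.dx for c in corrections
                 if c.participant_id == tr.participant_id and c.trial_id <= tr.trial_id)
        dy = sum(c.dy for c in corrections
                 if c.participant_id == tr.participant_id and c.trial_id <= tr.trial_id)
        out.append(tr.shifted(dx, dy) if (dx or dy) else tr)
    return out
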