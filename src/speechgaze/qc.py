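"""Trial- and participant-level quality control.

A trial is retained only if the child was looking at the screen (a valid
sample whose position falls inside the screen rectangle) for strictly more
than half of the visual-speech window, and was not flagged off-task by the
experimenter.  Participants keep their data only if at least eight of the
twelve trials survive.  A fraction of exactly 0.5 is removed, which
satisfies both the "less than 50% removed" and "more than 50% retained"
readings of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_io import (GazeTrial, SegmentWindows, TrialEvents, clipped_durations,
                      sample_durations, segment_windows)

__all__ = [
    "DEFAULT_ONSCREEN_THRESHOLD",
    "DEFAULT_MIN_TRIALS",
    "TrialQC",
    "ParticipantQC",
    "UndefinedFractionError",
    "onscreen_fraction",
    "filter_trials",
    "filter_participants",
    "trial_qc_frame",
    "participant_qc_frame",
    "write_qc_report",
]

DEFAULT_ONSCREEN_THRESHOLD = 0.5
DEFAULT_MIN_TRIALS = 8


class UndefinedFractionError(ValueError):
    """The speech window is empty, so no on-screen fraction is defined."""


@dataclass(frozen=True)
class TrialQC:
    participant_id: str
    trial_id: int
    onscreen_fraction_speech: float
    excluded_off_task: bool
    retained: bool


@dataclass(frozen=True)
class ParticipantQC:
    participant_id: str
    n_trials_retained: int
    included: bool


def onscreen_fraction(trial: GazeTrial, windows: SegmentWindows) -> float:
    """Fraction of the speech window covered by valid, on-screen gaze.

    Sample intervals are clipped to the speech window; tracking loss and
    off-screen positions both count against the fraction (denominator is
    the full window length).
    """
    start, end = windows.speech
    length = end - start
    if length <= 0:
        raise UndefinedFractionError("empty speech window")
    if trial.n_samples == 0:
        return 0.0
    durs = clipped_durations(trial.t, sample_durations(trial), (start, end))
    onscreen = trial.valid & trial.screen.contains(trial.x, trial.y)
    covered = float(durs[onscreen].sum())
    return min(covered / length, 1.0)


def filter_trials(
    trials: Sequence[GazeTrial],
    events: Mapping[int, TrialEvents],
    off_task: Iterable[tuple[str, int]] = (),
    threshold: float = DEFAULT_ONSCREEN_THRESHOLD,
) -> tuple[list[GazeTrial], list[TrialQC]]:
    """Apply the off-task and strict >threshold on-screen rules per trial."""
    off_task = set(off_task)
    retained_trials: list[GazeTrial] = []
    report: list[TrialQC] = []
    for tr in trials:
        frac = onscreen_fraction(tr, segment_windows(events[tr.trial_id]))
        off = (tr.participant_id, tr.trial_id) in off_task
        keep = (not off) and frac > threshold
        report.append(TrialQC(tr.participant_id, tr.trial_id, frac, off, keep))
        if keep:
            retained_trials.append(tr)
    return retained_trials, report


def filter_participants(
    trial_qc: Sequence[TrialQC],
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> list[ParticipantQC]:
    """Participants with fewer than ``min_trials`` retained trials are excluded."""
    counts: dict[str, int] = {}
    for tq in trial_qc:
        counts.setdefault(tq.participant_id, 0)
        if tq.retained:
            counts[tq.participant_id] += 1
    return [ParticipantQC(pid, n, n >= min_trials)
            for pid, n in sorted(counts.items())]


def trial_qc_frame(report: Sequence[TrialQC]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": tq.participant_id,
        "trial_id": tq.trial_id,
        "onscreen_fraction_speech": tq.onscreen_fraction_speech,
        "excluded_off_task": int(tq.excluded_off_task),
        "retained": int(tq.retained),
    } for tq in report])


def participant_qc_frame(report: Sequence[ParticipantQC]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": pq.participant_id,
        "n_trials_retained": pq.n_trials_retained,
        "included": int(pq.included),
    } for pq in report])


def write_qc_report(trial_qc: Sequence[TrialQC], participant_qc: Sequence[ParticipantQC],
                    trial_path: str | Path, participant_path: str | Path) -> None:
    trial_qc_frame(trial_qc).to_csv(trial_path, index=False, float_format="%.6f")
    participant_qc_frame(participant_qc).to_csv(participant_path, index=False)
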