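"""Percentage Net Dwell Time (%NDT) per AOI per segment and derived scores.

%NDT is sample-based: each gaze sample is credited with the time until the
next sample (the nominal 4 ms period for the last), clipped to the segment
window, and classified against the AOI pair evaluated at the sample's own
timestamp.  The percentage denominator is the full segment length, so
tracking loss lowers %NDT rather than renormalising it; videos of
different lengths therefore average on a common percentage scale.

The social-tuning ratio condenses the eyes-before-speech, mouth-during-
speech, eyes-after-speech viewing pattern into one number: the share of a
participant's total eyes+mouth dwell mass that sits in the three
pattern-concordant cells,

    STR = (E_pre + M_speech + E_post) /
          (E_pre + M_pre + E_speech + M_speech + E_post + M_post),

bounded in [0, 1] with 0.5 as the indifference point.  The exact published
rendering of the score is available only as an image in the source
article, so this operationalisation is a declared stand-in and every
output row carries ``formula_version = "pattern-mass-v1"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_io import (GazeTrial, TrialEvents, clipped_durations, sample_durations,
                      segment_windows)
from .geometry import CODE_EYES, CODE_MOUTH, LandmarkTrack, classify_points

__all__ = [
    "FORMULA_VERSION",
    "Segment",
    "DwellProfile",
    "ParticipantMetrics",
    "NoDataError",
    "UndefinedRatioError",
    "trial_dwell_profile",
    "participant_average",
    "social_tuning_ratio",
    "cohort_metrics",
    "metrics_frame",
    "write_metrics",
    "read_metrics",
]

FORMULA_VERSION = "pattern-mass-v1"


class Segment(IntEnum):
    PRE = 0
    SPEECH = 1
    POST = 2


class NoDataError(ValueError):
    """No dwell profiles were supplied."""


class UndefinedRatioError(ValueError):
    """No eyes/mouth dwell mass at all; the social-tuning ratio is undefined."""


@dataclass
class DwellProfile:
    """%NDT on eyes / mouth / whole screen for the three segments.

    Each field is a length-3 array indexed by :class:`Segment`; NaN marks a
    segment of zero length (missing, never zero).
    """

    pct_eyes: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    pct_mouth: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    pct_screen: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))

    def __post_init__(self) -> None:
        self.pct_eyes = np.asarray(self.pct_eyes, dtype=float)
        self.pct_mouth = np.asarray(self.pct_mouth, dtype=float)
        self.pct_screen = np.asarray(self.pct_screen, dtype=float)
        for arr in (self.pct_eyes, self.pct_mouth, self.pct_screen):
            if arr.shape != (3,):
                raise ValueError("profile fields must be length-3 arrays")

    def cell(self, aoi: str, segment: Segment) -> float:
        return float(getattr(self, f"pct_{aoi}")[segment])


@dataclass(frozen=True)
class ParticipantMetrics:
    participant_id: str
    profile: DwellProfile
    mouth_ndt_speech: float
    social_tuning_ratio: float
    n_trials: int
    formula_version: str = FORMULA_VERSION


def trial_dwell_profile(
    trial: GazeTrial,
    events: TrialEvents,
    landmark_track: LandmarkTrack,
    radius_factor: float = 2.0,
) -> DwellProfile:
    """Per-trial %NDT for eyes, mouth and whole screen in each segment."""
    windows = segment_windows(events)
    profile = DwellProfile()
    if trial.n_samples == 0:
        for seg, (start, end) in zip(Segment, windows.as_dict().values()):
            if end > start:
                profile.pct_eyes[seg] = 0.0
                profile.pct_mouth[seg] = 0.0
                profile.pct_screen[seg] = 0.0
        return profile

    durs = sample_durations(trial)
    eyes_xy, mouth_xy = landmark_track.interpolate(trial.t)
    pts = np.column_stack([trial.x, trial.y])
    codes = classify_points(eyes_xy, mouth_xy, pts, radius_factor)
    onscreen = trial.valid & trial.screen.contains(trial.x, trial.y)
    in_eyes = trial.valid & (codes == CODE_EYES)
    in_mouth = trial.valid & (codes == CODE_MOUTH)

    for seg, (start, end) in zip(Segment, windows.as_dict().values()):
        length = end - start
        if length <= 0:
            continue  # empty segment stays NaN (missing, not zero)
        clipped = clipped_durations(trial.t, durs, (start, end))
        profile.pct_eyes[seg] = 100.0 * float(clipped[in_eyes].sum()) / length
        profile.pct_mouth[seg] = 100.0 * float(clipped[in_mouth].sum()) / length
        profile.pct_screen[seg] = 100.0 * float(clipped[onscreen].sum()) / length
    return profile


def participant_average(profiles: Sequence[DwellProfile]) -> DwellProfile:
    """Unweighted per-cell mean over trials, skipping missing cells."""
    if not profiles:
        raise NoDataError("no dwell profiles to average")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cell -> NaN
        return DwellProfile(
            pct_eyes=np.nanmean([p.pct_eyes for p in profiles], axis=0),
            pct_mouth=np.nanmean([p.pct_mouth for p in profiles], axis=0),
            pct_screen=np.nanmean([p.pct_screen for p in profiles], axis=0),
        )


def social_tuning_ratio(profile: DwellProfile,
                        formula_version: str = FORMULA_VERSION) -> float:
    """Pattern-concordant share of total eyes+mouth dwell mass, in [0, 1].

    Concordant cells are eyes in PRE and POST and mouth in SPEECH.  Cells
    of missing segments are left out of both numerator and denominator, so
    the ratio is computed over the segments the trial set actually covers.
    """
    if formula_version != FORMULA_VERSION:
        raise ValueError(f"unknown social-tuning formula version {formula_version!r}")
    concordant = {Segment.PRE: "eyes", Segment.SPEECH: "mouth", Segment.POST: "eyes"}
    num = 0.0
    den = 0.0
    for seg, conc in concordant.items():
        e, m = profile.pct_eyes[seg], profile.pct_mouth[seg]
        if math.isnan(e) or math.isnan(m):
            continue
        num += e if conc == "eyes" else m
        den += e + m
    if den <= 0.0:
        raise UndefinedRatioError("participant never dwelt in either AOI")
    return num / den


def cohort_metrics(
    retained_trials: Sequence[GazeTrial],
    events: Mapping[int, TrialEvents],
    tracks: Mapping[int, LandmarkTrack],
    included_participants: Sequence[str],
    radius_factor: float = 2.0,
) -> list[ParticipantMetrics]:
    """Trial-averaged metrics for every QC-included participant.

    ``retained_trials`` must already have passed trial-level QC; a
    participant with no retained trials simply does not appear.
    """
    included = set(included_participants)
    by_participant: dict[str, list[GazeTrial]] = {}
    for tr in retained_trials:
        if tr.participant_id in included:
            by_participant.setdefault(tr.participant_id, []).append(tr)

    out = []
    for pid in sorted(by_participant):
        trials = by_participant[pid]
        profiles = [trial_dwell_profile(tr, events[tr.trial_id], tracks[tr.trial_id],
                                        radius_factor) for tr in trials]
        mean_profile = participant_average(profiles)
        out.append(ParticipantMetrics(
            participant_id=pid,
            profile=mean_profile,
            mouth_ndt_speech=mean_profile.cell("mouth", Segment.SPEECH),
            social_tuning_ratio=social_tuning_ratio(mean_profile),
            n_trials=len(trials),
        ))
    return out


_METRIC_COLUMNS = [
    "participant_id", "n_trials",
    "E_pre", "M_pre", "E_speech", "M_speech", "E_post", "M_post",
    "screen_pre", "screen_speech", "screen_post",
    "mouth_ndt_speech", "social_tuning_ratio", "formula_version",
]


def metrics_frame(metrics: Sequence[ParticipantMetrics]) -> pd.DataFrame:
    rows = []
    for pm in metrics:
        p = pm.profile
        rows.append({
            "participant_id": pm.participant_id,
            "n_trials": pm.n_trials,
            "E_pre": p.pct_eyes[Segment.PRE], "M_pre": p.pct_mouth[Segment.PRE],
            "E_speech": p.pct_eyes[Segment.SPEECH], "M_speech": p.pct_mouth[Segment.SPEECH],
            "E_post": p.pct_eyes[Segment.POST], "M_post": p.pct_mouth[Segment.POST],
            "screen_pre": p.pct_screen[Segment.PRE],
            "screen_speech": p.pct_screen[Segment.SPEECH],
            "screen_post": p.pct_screen[Segment.POST],
            "mouth_ndt_speech": pm.mouth_ndt_speech,
            "social_tuning_ratio": pm.social_tuning_ratio,
            "formula_version": pm.formula_version,
        })
    return pd.DataFrame(rows, columns=_METRIC_COLUMNS)


def write_metrics(metrics: Sequence[ParticipantMetrics], dest: str | Path) -> None:
    metrics_frame(metrics).to_csv(dest, index=False, float_format="%.6f")


def read_metrics(source: str | Path) -> pd.DataFrame:
    df = pd.read_csv(source)
    missing = set(_METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    return df
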