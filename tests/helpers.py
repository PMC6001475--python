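"""Shared test fixtures-as-functions and independent oracles.

The rasterization oracle recomputes dwell percentages by brute force: it
walks the trial millisecond by millisecond, assigns each millisecond to
the sample covering it, and counts labelled milliseconds per segment —
an integration path independent of the interval-clipping arithmetic used
by the implementation.
"""

from __future__ import annotations

import numpy as np

from speechgaze.gaze_io import (NOMINAL_PERIOD_MS, GazeTrial, ScreenGeometry,
                                TrialEvents)
from speechgaze.geometry import (CODE_EYES, CODE_MOUTH, LandmarkTrack,
                                 classify_points)

SCREEN = ScreenGeometry(1280.0, 1024.0)
EYES = (640.0, 400.0)
MOUTH = (640.0, 560.0)
OFFSCREEN = (640.0, 1500.0)


def static_track(duration_ms: float = 10_000.0) -> LandmarkTrack:
    return LandmarkTrack([0.0, duration_ms],
                         np.array([EYES, EYES]), np.array([MOUTH, MOUTH]))


def piecewise_trial(pieces, participant="p1", trial_id=1, period=4.0,
                    screen=SCREEN) -> GazeTrial:
    """Build a gaze stream from (start_ms, end_ms, (x, y), valid) pieces.

    Samples sit on the regular period grid; times not covered by any piece
    get no sample at all (a recording gap).
    """
    t, xs, ys, vs = [], [], [], []
    for start, end, pos, valid in pieces:
        grid = np.arange(start, end, period)
        t.extend(grid)
        xs.extend([pos[0]] * len(grid))
        ys.extend([pos[1]] * len(grid))
        vs.extend([valid] * len(grid))
    order = np.argsort(t)
    return GazeTrial(participant, trial_id, np.asarray(t)[order],
                     np.asarray(xs)[order], np.asarray(ys)[order],
                     np.asarray(vs)[order], screen=screen)


def rasterized_profile(trial: GazeTrial, events: TrialEvents,
                       track: LandmarkTrack, radius_factor: float = 2.0):
    """1 ms brute-force dwell percentages: dict of (aoi, segment) -> pct.

    Segments are 'pre'/'speech'/'post'; AOIs 'eyes'/'mouth'/'screen'.
    Empty segments are absent from the dict.
    """
    duration = int(round(events.duration_ms))
    ms = np.arange(duration, dtype=float)
    # which sample covers each millisecond
    idx = np.searchsorted(trial.t, ms, side="right") - 1
    covered = idx >= 0
    durs = np.append(np.diff(trial.t), NOMINAL_PERIOD_MS)
    covered &= ms < trial.t[np.clip(idx, 0, None)] + durs[np.clip(idx, 0, None)]

    eyes_xy, mouth_xy = track.interpolate(trial.t)
    pts = np.column_stack([trial.x, trial.y])
    codes = classify_points(eyes_xy, mouth_xy, pts, radius_factor)
    onscreen = trial.valid & trial.screen.contains(trial.x, trial.y)

    ms_eyes = np.zeros(duration, dtype=bool)
    ms_mouth = np.zeros(duration, dtype=bool)
    ms_screen = np.zeros(duration, dtype=bool)
    ci = idx[covered]
    ms_eyes[covered] = trial.valid[ci] & (codes[ci] == CODE_EYES)
    ms_mouth[covered] = trial.valid[ci] & (codes[ci] == CODE_MOUTH)
    ms_screen[covered] = onscreen[ci]

    bounds = {"pre": (0, int(events.speech_onset_ms)),
              "speech": (int(events.speech_onset_ms), int(events.speech_offset_ms)),
              "post": (int(events.speech_offset_ms), duration)}
    out = {}
    for seg, (lo, hi) in bounds.items():
        if hi <= lo:
            continue
        n = hi - lo
        out[("eyes", seg)] = 100.0 * ms_eyes[lo:hi].sum() / n
        out[("mouth", seg)] = 100.0 * ms_mouth[lo:hi].sum() / n
        out[("screen", seg)] = 100.0 * ms_screen[lo:hi].sum() / n
    return out


def rasterized_onscreen_fraction(trial: GazeTrial, events: TrialEvents) -> float:
    """1 ms brute-force on-screen fraction of the speech window."""
    prof = rasterized_profile(trial, events, static_track(events.duration_ms))
    return prof[("screen", "speech")] / 100.0
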