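"""One small diagnostic plot: a trial's gaze trace over the moving AOIs."""

from __future__ import annotations

import numpy as np

from .gaze_io import GazeTrial, TrialEvents
from .geometry import LandmarkTrack


def plot_trial(trial: GazeTrial, events: TrialEvents, track: LandmarkTrack,
               radius_factor: float = 2.0, ax=None):
    """Scatter the gaze samples coloured by segment, with the AOI disk drawn
    at the trial midpoint.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    seg = np.where(trial.t < events.speech_onset_ms, 0,
                   np.where(trial.t < events.speech_offset_ms, 1, 2))
    colors = np.array(["tab:blue", "tab:red", "tab:green"])[seg]
    ok = trial.valid
    ax.scatter(trial.x[ok], trial.y[ok], s=3, c=colors[ok], alpha=0.5)
    ax.scatter(trial.x[~ok], trial.y[~ok], s=3, c="grey", alpha=0.3, marker="x")

    mid = events.duration_ms / 2.0
    eyes, mouth = track.interpolate(np.array([mid]))
    centre = (eyes[0] + mouth[0]) / 2.0
    d = np.linalg.norm(eyes[0] - mouth[0])
    r = radius_factor * d / 2.0
    circ = __import__("matplotlib.patches", fromlist=["Circle"]).Circle(
        centre, r, fill=False, color="k", lw=1)
    ax.add_patch(circ)
    axis = (eyes[0] - mouth[0]) / d
    perp = np.array([-axis[1], axis[0]])
    line = np.array([centre - r * perp, centre + r * perp])
    ax.plot(line[:, 0], line[:, 1], "k--", lw=1)

    ax.set_xlim(0, trial.screen.width_px)
    ax.set_ylim(trial.screen.height_px, 0)  # screen coords: y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{trial.participant_id} trial {trial.trial_id} "
                 "(blue pre / red speech / green post)")
    return ax
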