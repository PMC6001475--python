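"""Synthetic gaze cohorts with known ground truth.

The generator emulates a 250 Hz monocular remote-tracker recording of
children watching twelve silent talking-head videos.  Each trial follows
one of four latent behaviours:

``social``
    the eyes -> mouth -> eyes communicative pattern: gaze starts on the
    eyes, shifts to the mouth a truncated-normal latency after visual
    speech onset, and returns to the eyes a latency after offset;
``mouth`` / ``eyes``
    single-AOI watching for the whole trial;
``roam``
    unconstrained looking, a sequence of 200-600 ms fixations uniform over
    the screen.

``p_social`` is the per-trial probability of the pattern; the remaining
mass is split between the three non-pattern behaviours by per-participant
weights.  The non-pattern mixture is deliberately mouth-heavy by default:
group mean social-tuning ratios sit *below* the 0.5 indifference point in
the population this emulates, which is only possible when the discordant
dwell mass (mouth before/after speech) outweighs eyes-at-rest looking, so
a symmetric mixture cannot reproduce the observed group means.

Fixation jitter is isotropic Gaussian; tracking loss arrives as runs of
invalid samples (geometric run lengths); occasional half-second off-screen
excursions leave samples valid but outside the screen rectangle.  Outcome
scores are linear in the participant's realized mouth %NDT and
social-tuning ratio with a group-dependent slope, clipped to the 0-62
speechreading score range.

Two resolutions are offered: ``"samples"`` writes full gaze streams and
realizes metrics through the actual AOI pipeline; ``"metrics"`` draws the
same latent behaviours and latencies but computes each trial's dwell cells
analytically, for large parameter-recovery studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_io import (NOMINAL_PERIOD_MS, GazeTrial, ScreenGeometry, TrialEvents,
                      write_corrections, write_events, write_gaze_table)
from .geometry import LandmarkTrack, write_landmark_tracks
from .metrics import (DwellProfile, Segment, participant_average,
                      social_tuning_ratio, trial_dwell_profile)

__all__ = [
    "StrategyParams",
    "StrategyDistribution",
    "CellConfig",
    "OutcomeModel",
    "CohortConfig",
    "CohortData",
    "BEHAVIOURS",
    "DEFAULT_EVENTS",
    "DEFAULT_SCREEN",
    "default_tracks",
    "default_cohort_config",
    "simulate_trial",
    "simulate_cohort",
    "expected_metrics",
    "expected_valid_fraction",
]

BEHAVIOURS = ("social", "mouth", "eyes", "roam")

DEFAULT_SCREEN = ScreenGeometry(1280.0, 1024.0)

#: Fixed stimulus set: twelve videos of different lengths, visual-speech
#: onset 400-800 ms in, post-speech tail 500-700 ms.
DEFAULT_EVENTS: dict[int, TrialEvents] = {
    e.trial_id: e for e in [
        TrialEvents(1, 2600, 450, 2100),
        TrialEvents(2, 3000, 500, 2450),
        TrialEvents(3, 3400, 600, 2800),
        TrialEvents(4, 2800, 400, 2300),
        TrialEvents(5, 3800, 700, 3200),
        TrialEvents(6, 4200, 650, 3500),
        TrialEvents(7, 2500, 500, 2000),
        TrialEvents(8, 3200, 550, 2700),
        TrialEvents(9, 4600, 800, 3900),
        TrialEvents(10, 3600, 500, 3100),
        TrialEvents(11, 5000, 750, 4300),
        TrialEvents(12, 4000, 600, 3400),
    ]
}

# Talking-head geometry: face centred on screen, eyes 160 px above mouth.
_FACE_EYES = np.array([640.0, 400.0])
_FACE_MOUTH = np.array([640.0, 560.0])
_HEAD_SWAY_PX = 8.0
_HEAD_SWAY_PERIOD_MS = 2200.0
_EXCURSION_MS = 500.0
_ROAM_FIX_MS = (200.0, 600.0)


def default_tracks(events: Mapping[int, TrialEvents] = DEFAULT_EVENTS,
                   keyframe_ms: float = 250.0) -> dict[int, LandmarkTrack]:
    """Deterministic landmark tracks: gentle rigid head sway per video."""
    tracks = {}
    for trial_id, ev in sorted(events.items()):
        t = np.arange(0.0, ev.duration_ms + keyframe_ms, keyframe_ms)
        phase = trial_id * 0.7
        sway_x = _HEAD_SWAY_PX * np.sin(2 * np.pi * t / _HEAD_SWAY_PERIOD_MS + phase)
        sway_y = 0.5 * _HEAD_SWAY_PX * np.sin(2 * np.pi * t / (1.7 * _HEAD_SWAY_PERIOD_MS))
        eyes = np.column_stack([_FACE_EYES[0] + sway_x, _FACE_EYES[1] + sway_y])
        mouth = np.column_stack([_FACE_MOUTH[0] + sway_x, _FACE_MOUTH[1] + sway_y])
        tracks[trial_id] = LandmarkTrack(t, eyes, mouth)
    return tracks


@dataclass(frozen=True)
class StrategyParams:
    """Latent gaze-behaviour parameters of one participant.

    ``w_mouth + w_eyes + w_roam`` is the conditional split of non-pattern
    trials; latencies are ms, truncated-normal at zero; ``loss_rate`` is
    the per-sample probability of starting an invalid run with geometric
    mean length ``loss_run_mean`` (samples); ``offscreen_rate`` is the
    per-trial probability of one ~500 ms off-screen excursion.
    """

    p_social: float
    w_mouth: float = 1.0 / 3
    w_eyes: float = 1.0 / 3
    w_roam: float = 1.0 / 3
    shift_latency_mean_ms: float = 400.0
    shift_latency_sd_ms: float = 150.0
    jitter_sd_px: float = 18.0
    loss_rate: float = 0.001
    loss_run_mean: float = 50.0
    offscreen_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_social", "w_mouth", "w_eyes", "w_roam",
                     "loss_rate", "offscreen_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not math.isclose(self.w_mouth + self.w_eyes + self.w_roam, 1.0,
                            abs_tol=1e-9):
            raise ValueError("non-pattern weights must sum to 1")
        for name in ("shift_latency_sd_ms", "jitter_sd_px", "loss_run_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def nonpattern_weights(self) -> np.ndarray:
        return np.array([self.w_mouth, self.w_eyes, self.w_roam])


@dataclass(frozen=True)
class StrategyDistribution:
    """Between-participant distribution of :class:`StrategyParams` in a cell.

    ``p_social`` and the mouth share of the non-pattern mass are Beta with
    the given means and common concentration ``kappa``; the remaining
    non-pattern mass is split ``eyes : roam`` at a fixed ratio; the
    latency mean varies Normally between participants (truncated at 50 ms).
    """

    p_social_mean: float
    w_mouth_mean: float
    kappa: float = 8.0
    eyes_share_of_rest: float = 0.35
    latency_mean_ms: float = 400.0
    latency_between_sd_ms: float = 80.0
    latency_within_sd_ms: float = 150.0
    jitter_sd_px: float = 18.0
    loss_rate: float = 0.001
    loss_run_mean: float = 50.0
    offscreen_rate: float = 0.05

    def _beta(self, rng: np.random.Generator, mean: float, size=None):
        a = mean * self.kappa
        b = (1.0 - mean) * self.kappa
        return rng.beta(a, b, size=size)

    def draw(self, rng: np.random.Generator) -> StrategyParams:
        p = float(self._beta(rng, self.p_social_mean))
        wm = float(self._beta(rng, self.w_mouth_mean))
        we = (1.0 - wm) * self.eyes_share_of_rest
        wr = (1.0 - wm) * (1.0 - self.eyes_share_of_rest)
        lat = max(float(rng.normal(self.latency_mean_ms, self.latency_between_sd_ms)),
                  50.0)
        return StrategyParams(
            p_social=p, w_mouth=wm, w_eyes=we, w_roam=wr,
            shift_latency_mean_ms=lat,
            shift_latency_sd_ms=self.latency_within_sd_ms,
            jitter_sd_px=self.jitter_sd_px,
            loss_rate=self.loss_rate,
            loss_run_mean=self.loss_run_mean,
            offscreen_rate=self.offscreen_rate,
        )

    def draw_arrays(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        p = self._beta(rng, self.p_social_mean, size=n)
        wm = self._beta(rng, self.w_mouth_mean, size=n)
        lat = np.maximum(rng.normal(self.latency_mean_ms,
                                    self.latency_between_sd_ms, size=n), 50.0)
        return {"p_social": p, "w_mouth": wm,
                "w_eyes": (1 - wm) * self.eyes_share_of_rest,
                "w_roam": (1 - wm) * (1 - self.eyes_share_of_rest),
                "latency_mean": lat}


@dataclass(frozen=True)
class CellConfig:
    group: str             # "deaf" | "hearing"
    intervention: str      # "speechreading" | "maths" | "none"
    n: int
    strategy: StrategyDistribution


@dataclass(frozen=True)
class OutcomeModel:
    """Linear outcome structure tying scores to realized gaze metrics.

    speechreading score = b0 + b_mouth * mouthNDT + b_str * STR
                          + b_str_deaf * STR * deaf + N(0, resid_sd),
    rounded and clipped to 0-62.  The two reading measures share the same
    form with their own coefficients and stay continuous.
    """

    beta0: float = -10.0
    beta_mouth: float = 0.25
    beta_str: float = 20.0
    beta_str_deaf: float = 40.0
    resid_sd: float = 8.0
    reading1: tuple[float, float, float, float] = (10.0, 8.0, 10.0, 4.0)
    reading2: tuple[float, float, float, float] = (15.0, 10.0, 12.0, 5.0)

    def speechreading(self, mouth: np.ndarray, s: np.ndarray, deaf: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        raw = (self.beta0 + self.beta_mouth * mouth + self.beta_str * s
               + self.beta_str_deaf * s * deaf
               + rng.normal(0.0, self.resid_sd, size=len(s)))
        clipped = (raw < 0) | (raw > 62)
        return np.clip(np.round(raw), 0, 62), clipped

    def reading(self, which: tuple[float, float, float, float], s: np.ndarray,
                deaf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        g0, g_str, g_str_deaf, sd = which
        return np.round(g0 + g_str * s + g_str_deaf * s * deaf
                        + rng.normal(0.0, sd, size=len(s)), 1)


# ---------------------------------------------------------------------------
# Default cell calibration.
#
# The non-pattern mixture is mouth-heavy (see module docstring); per-cell
# means are calibrated once, on the analytic expectations below, so that a
# default cohort reproduces the group structure this generator emulates:
# mouth %NDT during speech near 70 (hearing) / 64 (deaf overall, with the
# speechreading-trained subgroup near 71 and the maths-trained near 57)
# and social-tuning ratios near .48 (hearing) / .37 (deaf).
# ---------------------------------------------------------------------------

DEFAULT_CELLS: dict[tuple[str, str], StrategyDistribution] = {
    ("hearing", "none"): StrategyDistribution(
        p_social_mean=0.24, w_mouth_mean=0.68, kappa=6.0,
        latency_mean_ms=380.0, loss_rate=0.0003, loss_run_mean=50.0,
        offscreen_rate=0.04),
    ("deaf", "speechreading"): StrategyDistribution(
        p_social_mean=0.04, w_mouth_mean=0.82, kappa=5.0,
        latency_mean_ms=550.0, loss_rate=0.0019, loss_run_mean=150.0,
        offscreen_rate=0.08),
    ("deaf", "maths"): StrategyDistribution(
        p_social_mean=0.04, w_mouth_mean=0.68, kappa=5.0,
        latency_mean_ms=550.0, loss_rate=0.0019, loss_run_mean=150.0,
        offscreen_rate=0.08),
}


@dataclass
class CohortConfig:
    cells: list[CellConfig]
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    events: dict[int, TrialEvents] = field(default_factory=lambda: dict(DEFAULT_EVENTS))
    screen: ScreenGeometry = DEFAULT_SCREEN
    radius_factor: float = 2.0
    seed: int = 0


def default_cohort_config(n_deaf_speechreading: int = 15, n_deaf_maths: int = 14,
                          n_hearing: int = 29, seed: int = 0,
                          outcome: OutcomeModel | None = None) -> CohortConfig:
    """Study-sized cohort by default; scale the ``n`` arguments as needed."""
    cells = [
        CellConfig("deaf", "speechreading", n_deaf_speechreading,
                   DEFAULT_CELLS[("deaf", "speechreading")]),
        CellConfig("deaf", "maths", n_deaf_maths, DEFAULT_CELLS[("deaf", "maths")]),
        CellConfig("hearing", "none", n_hearing, DEFAULT_CELLS[("hearing", "none")]),
    ]
    return CohortConfig(cells=cells, outcome=outcome or OutcomeModel(), seed=seed)


# ---------------------------------------------------------------------------
# Trial-level simulation (sample resolution)
# ---------------------------------------------------------------------------

def _truncnorm_rvs(mean, sd, rng: np.random.Generator, size=None) -> np.ndarray:
    """Non-negative truncated normal latencies."""
    mean = np.asarray(mean, dtype=float)
    if np.all(sd == 0):
        return np.broadcast_to(mean, size if size else mean.shape).copy()
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _loss_mask(n: int, loss_rate: float, run_mean: float,
               rng: np.random.Generator) -> np.ndarray:
    """Invalid-sample mask from a run process: runs start at rate
    ``loss_rate`` per valid sample and last Geometric(1/run_mean) samples."""
    lost = np.zeros(n, dtype=bool)
    if loss_rate <= 0 or n == 0:
        return lost
    starts = np.flatnonzero(rng.random(n) < loss_rate)
    p_geom = min(1.0 / max(run_mean, 1.0), 1.0)
    for s in starts:
        if lost[s]:
            continue
        run = rng.geometric(p_geom)
        lost[s:s + run] = True
    return lost


def simulate_trial(
    strategy: StrategyParams,
    events: TrialEvents,
    track: LandmarkTrack,
    rng: np.random.Generator,
    screen: ScreenGeometry = DEFAULT_SCREEN,
    participant_id: str = "sim",
    behaviour: str | None = None,
    rate_hz: float = 250.0,
) -> tuple[GazeTrial, dict]:
    """One synthetic gaze stream plus its latent ground truth.

    Returns the trial and a dict with the realized behaviour label and
    sampled onset/offset latencies (NaN for non-pattern trials).
    """
    period = 1000.0 / rate_hz
    t = np.arange(0.0, events.duration_ms, period)
    n = len(t)

    if behaviour is None:
        if rng.random() < strategy.p_social:
            behaviour = "social"
        else:
            behaviour = str(rng.choice(["mouth", "eyes", "roam"],
                                       p=strategy.nonpattern_weights()))
    elif behaviour not in BEHAVIOURS:
        raise ValueError(f"unknown behaviour {behaviour!r}")

    eyes_xy, mouth_xy = track.interpolate(t)
    lat1 = lat2 = math.nan
    if behaviour == "social":
        lat1 = float(_truncnorm_rvs(strategy.shift_latency_mean_ms,
                                    strategy.shift_latency_sd_ms, rng))
        lat2 = float(_truncnorm_rvs(strategy.shift_latency_mean_ms,
                                    strategy.shift_latency_sd_ms, rng))
        shift_to_mouth = events.speech_onset_ms + lat1
        shift_back = max(events.speech_offset_ms + lat2, shift_to_mouth)
        on_mouth = (t >= shift_to_mouth) & (t < shift_back)
        pos = np.where(on_mouth[:, None], mouth_xy, eyes_xy)
    elif behaviour == "mouth":
        pos = mouth_xy.copy()
    elif behaviour == "eyes":
        pos = eyes_xy.copy()
    else:  # roam: sequence of uniform fixations over the screen
        pos = np.empty((n, 2))
        t_fix = 0.0
        while t_fix < events.duration_ms:
            dur = rng.uniform(*_ROAM_FIX_MS)
            target = rng.uniform([0.0, 0.0], [screen.width_px, screen.height_px])
            sel = (t >= t_fix) & (t < t_fix + dur)
            pos[sel] = target
            t_fix += dur

    if strategy.jitter_sd_px > 0:
        pos = pos + rng.normal(0.0, strategy.jitter_sd_px, size=(n, 2))

    if rng.random() < strategy.offscreen_rate and events.duration_ms > _EXCURSION_MS:
        start = rng.uniform(0.0, events.duration_ms - _EXCURSION_MS)
        sel = (t >= start) & (t < start + _EXCURSION_MS)
        pos[sel, 0] = rng.uniform(0.0, screen.width_px)
        pos[sel, 1] = screen.height_px + 60.0

    lost = _loss_mask(n, strategy.loss_rate, strategy.loss_run_mean, rng)

    trial = GazeTrial(
        participant_id=participant_id,
        trial_id=events.trial_id,
        t=np.round(t).astype(float),
        x=pos[:, 0],
        y=pos[:, 1],
        valid=~lost,
        screen=screen,
    )
    return trial, {"behaviour": behaviour, "latency_onset_ms": lat1,
                   "latency_offset_ms": lat2}


# ---------------------------------------------------------------------------
# Analytic expectations (oracle for recovery tests; metric-level generator)
# ---------------------------------------------------------------------------

def expected_valid_fraction(strategy: StrategyParams) -> float:
    """Stationary fraction of valid samples under the loss-run process."""
    lam_m = strategy.loss_rate * strategy.loss_run_mean
    return 1.0 / (1.0 + lam_m)


def _expected_capped_latency(mean: float, sd: float, window: float) -> float:
    """E[min(L, W)] for L truncated-normal(mean, sd) on [0, inf)."""
    if window <= 0:
        return 0.0
    if sd == 0:
        return min(mean, window)
    a = (0.0 - mean) / sd
    grid = np.linspace(0.0, window, 513)
    surv = stats.truncnorm.sf(grid, a, np.inf, loc=mean, scale=sd)
    return float(np.trapezoid(surv, grid))


def _aoi_screen_fraction(screen: ScreenGeometry = DEFAULT_SCREEN,
                         radius_factor: float = 2.0) -> float:
    """Fraction of the screen covered by one half-disk AOI."""
    dist = float(np.linalg.norm(_FACE_EYES - _FACE_MOUTH))
    radius = radius_factor * dist / 2.0
    return (math.pi * radius ** 2 / 2.0) / (screen.width_px * screen.height_px)


def _jitter_fidelity(strategy: StrategyParams, radius_factor: float = 2.0) -> float:
    """Probability a jittered on-landmark sample stays in its own half-disk.

    First-order: the landmark sits half the eyes--mouth distance from the
    dividing line and (radius_factor - 1) half-distances from the disk rim;
    treat the two escapes as independent Gaussian crossings.  Accurate for
    jitter small relative to the AOI radius.
    """
    if strategy.jitter_sd_px == 0:
        return 1.0
    half = float(np.linalg.norm(_FACE_EYES - _FACE_MOUTH)) / 2.0
    rim = (radius_factor - 1.0) * half
    p_line = stats.norm.cdf(half / strategy.jitter_sd_px)
    p_rim = stats.norm.cdf(rim / strategy.jitter_sd_px)
    return float(p_line * p_rim)


def _expected_cells_one_trial(strategy: StrategyParams, ev: TrialEvents,
                              radius_factor: float = 2.0,
                              screen: ScreenGeometry = DEFAULT_SCREEN) -> np.ndarray:
    """Expected (E_pre, M_pre, E_speech, M_speech, E_post, M_post) in %."""
    w_speech = ev.speech_offset_ms - ev.speech_onset_ms
    w_post = ev.duration_ms - ev.speech_offset_ms
    l1 = (_expected_capped_latency(strategy.shift_latency_mean_ms,
                                   strategy.shift_latency_sd_ms, w_speech) / w_speech
          if w_speech > 0 else 0.0)
    l2 = (_expected_capped_latency(strategy.shift_latency_mean_ms,
                                   strategy.shift_latency_sd_ms, w_post) / w_post
          if w_post > 0 else 0.0)
    p = strategy.p_social
    wm = (1 - p) * strategy.w_mouth
    we = (1 - p) * strategy.w_eyes
    wr = (1 - p) * strategy.w_roam
    eps = _aoi_screen_fraction(screen, radius_factor)
    f = _jitter_fidelity(strategy, radius_factor)
    v = expected_valid_fraction(strategy)
    o = 1.0 - strategy.offscreen_rate * _EXCURSION_MS / ev.duration_ms
    scale = 100.0 * f * v * o
    cells = np.array([
        p * 1.0 + we + wr * eps,            # E_pre
        wm + wr * eps,                      # M_pre
        p * l1 + we + wr * eps,             # E_speech
        p * (1.0 - l1) + wm + wr * eps,     # M_speech
        p * (1.0 - l2) + we + wr * eps,     # E_post
        p * l2 + wm + wr * eps,             # M_post
    ])
    return scale * cells


def expected_metrics(strategy: StrategyParams,
                     events: Mapping[int, TrialEvents] = DEFAULT_EVENTS,
                     radius_factor: float = 2.0,
                     screen: ScreenGeometry = DEFAULT_SCREEN) -> DwellProfile:
    """Closed-form expected trial-averaged dwell profile for a strategy.

    Valid when jitter is small relative to the AOI radius (the fidelity
    factor is a first-order crossing approximation).
    """
    cells = np.mean([_expected_cells_one_trial(strategy, ev, radius_factor, screen)
                     for ev in events.values()], axis=0)
    v = expected_valid_fraction(strategy)
    o = float(np.mean([1.0 - strategy.offscreen_rate * _EXCURSION_MS / ev.duration_ms
                       for ev in events.values()]))
    profile = DwellProfile(
        pct_eyes=np.array([cells[0], cells[2], cells[4]]),
        pct_mouth=np.array([cells[1], cells[3], cells[5]]),
        pct_screen=np.full(3, 100.0 * v * o),
    )
    return profile


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Everything one simulated cohort produced."""

    trials: list[GazeTrial]
    events: dict[int, TrialEvents]
    tracks: dict[int, LandmarkTrack]
    participants: pd.DataFrame
    ground_truth: dict
    screen: ScreenGeometry

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gaze": out / "gaze.tsv",
            "events": out / "events.csv",
            "landmarks": out / "landmarks.csv",
            "participants": out / "participants.csv",
            "ground_truth": out / "ground_truth.json",
            "corrections": out / "corrections.csv",
        }
        write_gaze_table(self.trials, paths["gaze"])
        write_events(self.events, paths["events"])
        write_landmark_tracks(self.tracks, paths["landmarks"])
        self.participants.to_csv(paths["participants"], index=False,
                                 float_format="%.6f")
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=float)
        write_corrections([], paths["corrections"])
        return paths


def _metrics_from_trials(trials, events, tracks, radius_factor):
    profiles = [trial_dwell_profile(tr, events[tr.trial_id], tracks[tr.trial_id],
                                    radius_factor) for tr in trials]
    mean_profile = participant_average(profiles)
    try:
        ratio = social_tuning_ratio(mean_profile)
    except Exception:
        ratio = math.nan
    return mean_profile, ratio


def _simulate_cell_samples(cell: CellConfig, config: CohortConfig, pid_start: int,
                           tracks, rng: np.random.Generator):
    rows, truths, all_trials = [], {}, []
    for i in range(cell.n):
        pid = f"p{pid_start + i:04d}"
        params = cell.strategy.draw(rng)
        trial_truths = []
        trials = []
        for trial_id in sorted(config.events):
            tr, truth = simulate_trial(params, config.events[trial_id],
                                       tracks[trial_id], rng, config.screen,
                                       participant_id=pid)
            trials.append(tr)
            trial_truths.append(truth)
        mean_profile, ratio = _metrics_from_trials(trials, config.events, tracks,
                                                   config.radius_factor)
        rows.append({
            "participant_id": pid, "group": cell.group,
            "intervention": cell.intervention,
            "mouth_ndt": mean_profile.cell("mouth", Segment.SPEECH),
            "str": ratio,
        })
        truths[pid] = {"params": asdict(params), "trials": trial_truths,
                       "realized_mouth_ndt": rows[-1]["mouth_ndt"],
                       "realized_str": ratio}
        all_trials.extend(trials)
    return rows, truths, all_trials


def _simulate_cell_metrics(cell: CellConfig, config: CohortConfig, pid_start: int,
                           rng: np.random.Generator):
    """Vectorised metric-resolution cell: analytic per-trial dwell cells from
    the same latent behaviour/latency draws, no rasterized samples."""
    n = cell.n
    dist = cell.strategy
    draws = dist.draw_arrays(rng, n)
    trial_ids = sorted(config.events)
    n_tr = len(trial_ids)
    w_speech = np.array([config.events[k].speech_offset_ms
                         - config.events[k].speech_onset_ms for k in trial_ids])
    w_post = np.array([config.events[k].duration_ms
                       - config.events[k].speech_offset_ms for k in trial_ids])
    dur = np.array([config.events[k].duration_ms for k in trial_ids])

    u = rng.random((n, n_tr))
    social = u < draws["p_social"][:, None]
    # conditional non-pattern category
    c = rng.random((n, n_tr))
    wm = draws["w_mouth"][:, None]
    we = draws["w_eyes"][:, None]
    mouth = (~social) & (c < wm)
    eyes = (~social) & (c >= wm) & (c < wm + we)
    roam = (~social) & ~mouth & ~eyes

    base = StrategyParams(p_social=float(np.mean(draws["p_social"])),
                          jitter_sd_px=dist.jitter_sd_px,
                          loss_rate=dist.loss_rate,
                          loss_run_mean=dist.loss_run_mean,
                          offscreen_rate=dist.offscreen_rate)
    f = _jitter_fidelity(base, config.radius_factor)
    v = expected_valid_fraction(base)
    eps = _aoi_screen_fraction(config.screen, config.radius_factor)

    lat_mu = draws["latency_mean"][:, None]
    sd = dist.latency_within_sd_ms
    l1 = np.minimum(_truncnorm_rvs(np.broadcast_to(lat_mu, (n, n_tr)), sd, rng,
                                   size=(n, n_tr)), w_speech) / w_speech
    l2 = np.minimum(_truncnorm_rvs(np.broadcast_to(lat_mu, (n, n_tr)), sd, rng,
                                   size=(n, n_tr)), w_post) / w_post
    exc = rng.random((n, n_tr)) < dist.offscreen_rate
    o = 1.0 - exc * (_EXCURSION_MS / dur)
    scale = 100.0 * f * v * o

    cells = np.empty((6, n, n_tr))
    cells[0] = social * 1.0 + eyes * 1.0 + roam * eps            # E_pre
    cells[1] = mouth * 1.0 + roam * eps                          # M_pre
    cells[2] = social * l1 + eyes * 1.0 + roam * eps             # E_speech
    cells[3] = social * (1 - l1) + mouth * 1.0 + roam * eps      # M_speech
    cells[4] = social * (1 - l2) + eyes * 1.0 + roam * eps       # E_post
    cells[5] = social * l2 + mouth * 1.0 + roam * eps            # M_post
    cells *= scale

    mean_cells = cells.mean(axis=2)                              # (6, n)
    num = mean_cells[0] + mean_cells[3] + mean_cells[4]
    den = mean_cells.sum(axis=0)
    ratio = np.where(den > 0, num / den, np.nan)
    rows = [{
        "participant_id": f"p{pid_start + i:04d}", "group": cell.group,
        "intervention": cell.intervention,
        "mouth_ndt": mean_cells[3, i], "str": ratio[i],
    } for i in range(n)]
    truths = {rows[i]["participant_id"]: {
        "params": {"p_social": float(draws["p_social"][i]),
                   "w_mouth": float(draws["w_mouth"][i]),
                   "latency_mean_ms": float(draws["latency_mean"][i])},
        "realized_mouth_ndt": float(mean_cells[3, i]),
        "realized_str": float(ratio[i]),
    } for i in range(n)}
    return rows, truths, []


def simulate_cohort(config: CohortConfig, out_dir: str | Path | None = None,
                    resolution: str = "samples") -> CohortData:
    """Generate a full cohort: gaze streams (or analytic metrics), trial
    events, landmark tracks, outcome scores and serialized ground truth.

    Outcome scores are driven by metrics realized over *all* simulated
    trials (the latent behaviour drives the child's score); the analysis
    pipeline then sees only what survives its own QC.
    """
    if resolution not in ("samples", "metrics"):
        raise ValueError(f"unknown resolution {resolution!r}")
    rng = np.random.default_rng(config.seed)
    tracks = default_tracks(config.events)

    rows: list[dict] = []
    truths: dict = {}
    all_trials: list[GazeTrial] = []
    pid_start = 1
    for cell in config.cells:
        if cell.n <= 0:
            continue
        sim = (_simulate_cell_samples if resolution == "samples"
               else _simulate_cell_metrics)
        if resolution == "samples":
            cell_rows, cell_truths, cell_trials = sim(cell, config, pid_start,
                                                      tracks, rng)
        else:
            cell_rows, cell_truths, cell_trials = sim(cell, config, pid_start, rng)
        rows.extend(cell_rows)
        truths.update(cell_truths)
        all_trials.extend(cell_trials)
        pid_start += cell.n

    df = pd.DataFrame(rows)
    deaf = (df["group"] == "deaf").to_numpy(dtype=float)
    mouth = df["mouth_ndt"].to_numpy()
    s = df["str"].to_numpy()
    tocs, clipped = config.outcome.speechreading(mouth, s, deaf, rng)
    reading1 = config.outcome.reading(config.outcome.reading1, s, deaf, rng)
    reading2 = config.outcome.reading(config.outcome.reading2, s, deaf, rng)
    participants = pd.DataFrame({
        "participant_id": df["participant_id"],
        "group": df["group"],
        "intervention": df["intervention"],
        "tocs_questions_score": tocs.astype(int),
        "reading1": reading1,
        "reading2": reading2,
    })

    ground_truth = {
        "seed": config.seed,
        "resolution": resolution,
        "outcome_model": {
            "beta0": config.outcome.beta0,
            "beta_mouth": config.outcome.beta_mouth,
            "beta_str": config.outcome.beta_str,
            "beta_str_deaf": config.outcome.beta_str_deaf,
            "resid_sd": config.outcome.resid_sd,
        },
        "clipped_fraction": float(np.mean(clipped)),
        "participants": truths,
        "realized": {
            pid: {"mouth_ndt": float(m), "str": float(r)}
            for pid, m, r in zip(df["participant_id"], mouth, s)
        },
    }

    data = CohortData(trials=all_trials, events=dict(config.events), tracks=tracks,
                      participants=participants, ground_truth=ground_truth,
                      screen=config.screen)
    if out_dir is not None:
        data.write(out_dir)
    return data
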