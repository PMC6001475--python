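"""Reproducible simulate -> QC -> metrics -> analyze pipeline.

Each stage reads/writes the plain-text dialects defined in
:mod:`speechgaze.gaze_io`; a resolved copy of the configuration is
serialized next to every run's outputs so a run can be reproduced from its
output directory alone.  The analysis report mirrors the structure of a
group study: group contrasts of the gaze metrics, per-group
metric--outcome correlations, and dummy-coded moderated regressions with
the drop-the-interaction reduction rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gaze_io, inference, metrics, qc, simulate

__all__ = ["PipelineConfig", "run_simulate", "run_qc", "run_metrics",
           "run_analyze", "QCEmptyError"]

logger = logging.getLogger(__name__)


class QCEmptyError(RuntimeError):
    """Quality control removed too much data for any analysis to run."""


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; serialized beside each run's outputs."""

    data_dir: str = "data"
    out_dir: str = "out"
    seed: int | None = None
    radius_factor: float = 2.0
    qc_threshold: float = qc.DEFAULT_ONSCREEN_THRESHOLD
    min_trials: int = qc.DEFAULT_MIN_TRIALS
    n_boot: int = 1000
    alpha_reduce: float = 0.05
    formula_version: str = metrics.FORMULA_VERSION
    # simulation cell sizes (study-sized by default)
    n_deaf_speechreading: int = 15
    n_deaf_maths: int = 14
    n_hearing: int = 29
    screen_width_px: float = 1280.0
    screen_height_px: float = 1024.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    # -- derived paths -----------------------------------------------------
    def _data(self, name: str) -> Path:
        return Path(self.data_dir) / name

    @property
    def screen(self) -> gaze_io.ScreenGeometry:
        return gaze_io.ScreenGeometry(self.screen_width_px, self.screen_height_px)


def _write_resolved(config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic cohort dataset under ``config.data_dir``."""
    if config.seed is None:
        raise ValueError("simulation requires an explicit seed "
                         "(set `seed` in the config or pass --seed)")
    cohort_cfg = simulate.default_cohort_config(
        n_deaf_speechreading=config.n_deaf_speechreading,
        n_deaf_maths=config.n_deaf_maths,
        n_hearing=config.n_hearing,
        seed=config.seed,
    )
    cohort_cfg.radius_factor = config.radius_factor
    data = simulate.simulate_cohort(cohort_cfg, out_dir=config.data_dir)
    _write_resolved(config, Path(config.data_dir))
    logger.info("simulated cohort: %d participants, %d trials, seed %d",
                len(data.participants), len(data.trials), config.seed)
    return {"data_dir": Path(config.data_dir)}


def _load_dataset(config: PipelineConfig):
    trials = gaze_io.read_gaze_table(config._data("gaze.tsv"), screen=config.screen)
    events = gaze_io.read_events(config._data("events.csv"))
    from .geometry import read_landmark_tracks
    tracks = read_landmark_tracks(config._data("landmarks.csv"))
    corr_path = config._data("corrections.csv")
    if corr_path.exists():
        corrections = gaze_io.read_corrections(corr_path)
        if corrections:
            trials = gaze_io.apply_drift_corrections(trials, corrections)
    return trials, events, tracks


def run_qc(config: PipelineConfig):
    """Trial/participant exclusion rules; writes the QC report CSVs."""
    trials, events, tracks = _load_dataset(config)
    retained, trial_report = qc.filter_trials(trials, events,
                                              threshold=config.qc_threshold)
    participant_report = qc.filter_participants(trial_report,
                                                min_trials=config.min_trials)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc.write_qc_report(trial_report, participant_report,
                       out / "qc_trials.csv", out / "qc_participants.csv")
    for tq in trial_report:
        if not tq.retained:
            rule = ("off-task" if tq.excluded_off_task
                    else f"on-screen fraction {tq.onscreen_fraction_speech:.3f} "
                         f"<= {config.qc_threshold}")
            logger.warning("dropped trial %s/%d: %s", tq.participant_id,
                           tq.trial_id, rule)
    for pq in participant_report:
        if not pq.included:
            logger.warning("excluded participant %s: %d retained trials < %d",
                           pq.participant_id, pq.n_trials_retained,
                           config.min_trials)
    _write_resolved(config, out)
    return retained, trial_report, participant_report, events, tracks


def run_metrics(config: PipelineConfig) -> pd.DataFrame:
    """QC plus per-participant dwell metrics; writes metrics.csv."""
    retained, _, participant_report, events, tracks = run_qc(config)
    included = [p.participant_id for p in participant_report if p.included]
    pm = metrics.cohort_metrics(retained, events, tracks, included,
                                radius_factor=config.radius_factor)
    df = metrics.metrics_frame(pm)
    df.to_csv(Path(config.out_dir) / "metrics.csv", index=False,
              float_format="%.6f")
    return df


def _seed_for(config: PipelineConfig, tag: str) -> int | None:
    if config.seed is None:
        return None
    # crc32 is stable across processes, unlike str.__hash__
    import zlib
    h = np.random.SeedSequence([config.seed, zlib.crc32(tag.encode())])
    return int(h.generate_state(1)[0] % (2 ** 31))


def _contrast_row(name, variable, a_name, a, b_name, b):
    res = inference.choose_t(a, b)
    return {
        "contrast": name, "variable": variable,
        "group_a": a_name, "n_a": a.n, "mean_a": a.mean, "sd_a": a.sd,
        "group_b": b_name, "n_b": b.n, "mean_b": b.mean, "sd_b": b.sd,
        "t": res.t, "df": res.df, "p": res.p, "d": res.d, "variant": res.variant,
    }


def _regression_rows(tag, result, y_name, x_name):
    rows = []
    for which, fit in (("full", result.full), ("reduced", result.reduced)):
        if fit is None:
            continue
        for term in fit.terms:
            ci = fit.bootstrap_ci.get(term, (np.nan, np.nan))
            rows.append({
                "regression": tag, "outcome": y_name, "predictor": x_name,
                "model": which, "reported": int((which == "reduced")
                                                == result.reduced_reported),
                "term": term, "coef": fit.params[term], "p": fit.pvalues[term],
                "ci_low": ci[0], "ci_high": ci[1], "nobs": fit.nobs,
                "n_boot": result.n_boot, "seed": result.seed,
            })
    return rows


def run_analyze(config: PipelineConfig) -> dict[str, Any]:
    """Full analysis: QC, metrics, contrasts, correlations, regressions.

    Groups too small to analyse produce skipped-block notices, never a
    crash; the report dict is also written as JSON + CSV tables and a
    plain-text summary.
    """
    mdf = run_metrics(config)
    participants = pd.read_csv(config._data("participants.csv"))
    df = mdf.merge(participants, on="participant_id", how="inner")
    out = Path(config.out_dir)

    notices: list[str] = []
    contrasts: list[dict] = []
    correlations: list[dict] = []
    regressions: list[dict] = []

    deaf = df[df.group == "deaf"]
    hearing = df[df.group == "hearing"]
    sr = deaf[deaf.intervention == "speechreading"]
    maths = deaf[deaf.intervention == "maths"]

    def summary(sub, col):
        return inference.GroupSummary.from_sample(sub[col].to_numpy())

    # --- block 1: group contrasts of gaze metrics -------------------------
    if len(deaf) >= 2 and len(hearing) >= 2:
        for col, label in (("mouth_ndt_speech", "mouth %NDT during speech"),
                           ("social_tuning_ratio", "social-tuning ratio")):
            contrasts.append(_contrast_row("deaf vs hearing", label,
                                           "deaf", summary(deaf, col),
                                           "hearing", summary(hearing, col)))
    else:
        notices.append("between-group contrasts skipped: fewer than 2 "
                       "participants in a hearing-status group")
    if len(sr) >= 2 and len(maths) >= 2:
        for col, label in (("mouth_ndt_speech", "mouth %NDT during speech"),
                           ("social_tuning_ratio", "social-tuning ratio")):
            contrasts.append(_contrast_row("speechreading vs maths training", label,
                                           "speechreading", summary(sr, col),
                                           "maths", summary(maths, col)))
    else:
        notices.append("within-deaf training contrasts skipped: fewer than 2 "
                       "participants in a training arm")

    # --- composite reading ------------------------------------------------
    composite = None
    try:
        composite = inference.composite_reading(df)
        df = df.assign(reading_composite=composite)
    except (inference.InsufficientDataError,
            inference.UndefinedCorrelationError) as exc:
        notices.append(f"composite reading skipped: {exc}")

    # --- block 2: metric-outcome correlations per group -------------------
    pairs = [("mouth_ndt_speech", "tocs_questions_score"),
             ("social_tuning_ratio", "tocs_questions_score")]
    if composite is not None:
        pairs.append(("social_tuning_ratio", "reading_composite"))
    for gname, sub in (("deaf", deaf), ("hearing", hearing)):
        sub = df[df.group == gname]
        for xcol, ycol in pairs:
            if ycol not in sub.columns:
                continue
            if len(sub) < 3:
                notices.append(f"correlation {xcol}~{ycol} skipped for {gname}: n < 3")
                continue
            try:
                res = inference.pearson_r(sub[xcol], sub[ycol],
                                          n_boot=config.n_boot,
                                          seed=_seed_for(config, f"r:{gname}:{xcol}:{ycol}"))
            except inference.UndefinedCorrelationError as exc:
                notices.append(f"correlation {xcol}~{ycol} for {gname}: {exc}")
                continue
            correlations.append({
                "group": gname, "x": xcol, "y": ycol, "n": len(sub),
                "r": res.r, "df": res.df, "p": res.p,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "n_boot": res.n_boot, "seed": res.seed,
            })

    # --- block 3+4: moderated regressions with reduction ------------------
    specs = []
    if len(sr) >= 2 and len(maths) >= 2:
        dummy = (deaf.intervention == "speechreading").astype(int)
        specs.append(("deaf: tocs ~ mouth x intervention", deaf,
                      "tocs_questions_score", "mouth_ndt_speech", dummy,
                      {"maths": 0, "speechreading": 1}))
        specs.append(("deaf: tocs ~ str x intervention", deaf,
                      "tocs_questions_score", "social_tuning_ratio", dummy,
                      {"maths": 0, "speechreading": 1}))
    else:
        notices.append("within-deaf moderated regressions skipped: fewer than "
                       "2 participants in a training arm")
    if len(deaf) >= 2 and len(hearing) >= 2:
        dummy = (df.group == "hearing").astype(int)
        specs.append(("all: tocs ~ str x hearing", df,
                      "tocs_questions_score", "social_tuning_ratio", dummy,
                      {"deaf": 0, "hearing": 1}))
        if composite is not None:
            specs.append(("all: reading ~ str x hearing", df,
                          "reading_composite", "social_tuning_ratio", dummy,
                          {"deaf": 0, "hearing": 1}))
    else:
        notices.append("between-group moderated regressions skipped: fewer "
                       "than 2 participants in a hearing-status group")

    reg_results = {}
    for tag, sub, ycol, xcol, dummy, coding in specs:
        try:
            res = inference.fit_moderated_regression(
                sub[ycol].to_numpy(dtype=float), sub[xcol].to_numpy(),
                dummy.to_numpy(), alpha_reduce=config.alpha_reduce,
                n_boot=config.n_boot, seed=_seed_for(config, f"reg:{tag}"),
                dummy_coding=coding)
        except inference.RankDeficiencyError as exc:
            notices.append(f"regression '{tag}' skipped: {exc}")
            continue
        reg_results[tag] = res
        regressions.extend(_regression_rows(tag, res, ycol, xcol))

    report = {
        "n_analysed": int(len(df)),
        "contrasts": contrasts,
        "correlations": correlations,
        "regressions": regressions,
        "notices": notices,
        "formula_version": config.formula_version,
        "seed": config.seed,
        "n_boot": config.n_boot,
    }
    pd.DataFrame(contrasts).to_csv(out / "contrasts.csv", index=False,
                                   float_format="%.6f")
    pd.DataFrame(correlations).to_csv(out / "correlations.csv", index=False,
                                      float_format="%.6f")
    pd.DataFrame(regressions).to_csv(out / "regressions.csv", index=False,
                                     float_format="%.6f")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    (out / "summary.txt").write_text(_render_summary(report, reg_results))
    return report


def _render_summary(report: dict, reg_results: dict) -> str:
    lines = [f"speechgaze analysis summary "
             f"(n = {report['n_analysed']}, "
             f"social-tuning formula {report['formula_version']})", ""]
    if report["contrasts"]:
        lines.append("Group contrasts")
        for c in report["contrasts"]:
            lines.append(
                f"  {c['contrast']}, {c['variable']}: "
                f"{c['group_a']} M={c['mean_a']:.2f} SD={c['sd_a']:.2f} vs "
                f"{c['group_b']} M={c['mean_b']:.2f} SD={c['sd_b']:.2f}; "
                f"t({c['df']:.1f}) = {c['t']:.2f}, p = {c['p']:.3f}, "
                f"d = {c['d']:.2f} [{c['variant']}]")
        lines.append("")
    if report["correlations"]:
        lines.append("Metric-outcome correlations (percentile bootstrap 95% CI)")
        for r in report["correlations"]:
            lines.append(
                f"  {r['group']}: {r['x']} ~ {r['y']}: r({r['df']}) = "
                f"{r['r']:.3f}, p = {r['p']:.3f}, CI [{r['ci_low']:.3f}, "
                f"{r['ci_high']:.3f}]")
        lines.append("")
    if reg_results:
        lines.append("Moderated regressions (interaction dropped when p >= alpha)")
        for tag, res in reg_results.items():
            which = "reduced" if res.reduced_reported else "full"
            fit = res.reported
            terms = ", ".join(f"{t} = {fit.params[t]:.2f} (p = {fit.pvalues[t]:.3f})"
                              for t in fit.terms)
            lines.append(f"  {tag} [{which} model reported]: {terms}")
        lines.append("")
    for n in report["notices"]:
        lines.append(f"  notice: {n}")
    return "\n".join(lines) + "\n"
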