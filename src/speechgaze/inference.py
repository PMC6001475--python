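"""Group-level statistics: t tests from summaries, bootstrapped correlations,
dummy-coded moderated regressions with an interaction-reduction rule, and
composite reading z-scores.

Conventions
-----------
* Cohen's d always uses the pooled standard deviation, for the Welch
  variant too, so effect sizes stay comparable across test variants.
* p-values come from the classical reference distributions; percentile
  bootstrap confidence intervals (seeded, 1000 replicates by default) are
  reported alongside, since resampling inference is used throughout the
  analysis this package reimplements without a stated method.
* Test-variant choice, when not forced: pooled by default, switching to
  Welch when a two-sided F screen on the variance ratio rejects equality
  at alpha = .05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "CorrelationResult",
    "RegressionFit",
    "ModeratedRegressionResult",
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "RankDeficiencyError",
    "pooled_t",
    "welch_t",
    "choose_t",
    "pearson_r",
    "fit_moderated_regression",
    "composite_reading",
]


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


class UndefinedCorrelationError(ValueError):
    """One of the variables has zero variance."""


class RankDeficiencyError(ValueError):
    """The regression design matrix is rank deficient (e.g. constant dummy)."""


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group on one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"group needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    variant: str  # "pooled" | "welch"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    return math.sqrt(((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2)
                     / (a.n + b.n - 2))


def pooled_t(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Independent-samples t test assuming equal variances, with Cohen's d."""
    sp = _pooled_sd(a, b)
    df = a.n + b.n - 2
    se = sp * math.sqrt(1.0 / a.n + 1.0 / b.n)
    diff = a.mean - b.mean
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / sp if sp > 0 else 0.0
    return TTestResult(t=t, df=float(df), p=float(p), d=d, variant="pooled")


def welch_t(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Unequal-variance t test with Welch–Satterthwaite df; d still pooled."""
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    diff = a.mean - b.mean
    se = math.sqrt(va + vb)
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        df = float(a.n + b.n - 2)
    else:
        t = diff / se
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    sp = _pooled_sd(a, b)
    d = diff / sp if sp > 0 else 0.0
    return TTestResult(t=t, df=float(df), p=float(p), d=d, variant="welch")


def choose_t(a: GroupSummary, b: GroupSummary, alpha_var: float = 0.05) -> TTestResult:
    """Pooled t unless a two-sided F screen rejects equal variances."""
    if a.sd == 0.0 or b.sd == 0.0:
        return pooled_t(a, b)
    f = a.sd ** 2 / b.sd ** 2
    p_hi = stats.f.sf(f, a.n - 1, b.n - 1)
    p_f = 2.0 * min(p_hi, 1.0 - p_hi)
    return welch_t(a, b) if p_f < alpha_var else pooled_t(a, b)


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> CorrelationResult:
    """Pearson correlation with classical p and percentile-bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    ci_low = ci_high = math.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        bx, by = x[idx], y[idx]
        bxc = bx - bx.mean(axis=1, keepdims=True)
        byc = by - by.mean(axis=1, keepdims=True)
        denom = np.sqrt((bxc ** 2).sum(axis=1) * (byc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rb = (bxc * byc).sum(axis=1) / denom
        rb = rb[np.isfinite(rb)]  # degenerate resamples carry no information
        alpha = 1.0 - ci_level
        ci_low, ci_high = np.quantile(rb, [alpha / 2.0, 1.0 - alpha / 2.0])
    return CorrelationResult(r=float(res.statistic), df=n - 2, p=float(res.pvalue),
                             ci_low=float(ci_low), ci_high=float(ci_high),
                             n_boot=n_boot, seed=seed)


@dataclass(frozen=True)
class RegressionFit:
    """One fitted OLS model with named coefficients and bootstrap CIs."""

    params: Mapping[str, float]
    pvalues: Mapping[str, float]
    bootstrap_ci: Mapping[str, tuple[float, float]]
    nobs: int
    terms: tuple[str, ...]

    def predict_terms(self) -> str:
        return " + ".join(self.terms)


@dataclass(frozen=True)
class ModeratedRegressionResult:
    """Full interaction model plus, when the interaction fails the screen,
    the reduced main-effects refit (mirroring the drop-the-interaction rule)."""

    full: RegressionFit
    reduced: RegressionFit | None
    reduced_reported: bool
    dummy_coding: Mapping[str, int]
    alpha_reduce: float
    seed: int | None
    n_boot: int

    @property
    def reported(self) -> RegressionFit:
        return self.reduced if self.reduced_reported else self.full


def _ols_fit(y: np.ndarray, X: np.ndarray, names: Sequence[str],
             n_boot: int, rng: np.random.Generator | None) -> RegressionFit:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank deficient for terms {list(names)}")
    fit = sm.OLS(y, X).fit()
    cis: dict[str, tuple[float, float]] = {}
    if n_boot > 0 and rng is not None:
        n = len(y)
        boot = np.full((n_boot, X.shape[1]), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
                continue
            boot[b] = np.linalg.lstsq(Xb, y[idx], rcond=None)[0]
        ok = ~np.isnan(boot[:, 0])
        lo, hi = np.quantile(boot[ok], [0.025, 0.975], axis=0)
        cis = {nm: (float(lo[j]), float(hi[j])) for j, nm in enumerate(names)}
    return RegressionFit(
        params={nm: float(v) for nm, v in zip(names, fit.params)},
        pvalues={nm: float(v) for nm, v in zip(names, fit.pvalues)},
        bootstrap_ci=cis,
        nobs=int(fit.nobs),
        terms=tuple(names),
    )


def fit_moderated_regression(
    y: Sequence[float],
    x: Sequence[float],
    group_dummy: Sequence[int],
    alpha_reduce: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
    covariates: Mapping[str, Sequence[float]] | None = None,
    dummy_coding: Mapping[str, int] | None = None,
) -> ModeratedRegressionResult:
    """OLS of ``y ~ x + g + x:g`` (plus optional covariates) with reduction.

    If the interaction's classical p-value is at or above ``alpha_reduce``
    the model is refit without it and the reduced fit is flagged as the one
    to report; both fits are returned either way the rule goes.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(group_dummy, dtype=float)
    if not np.all(np.isin(g, (0.0, 1.0))):
        raise ValueError("group_dummy must be coded 0/1")
    if len({0.0, 1.0} & set(g)) < 2:
        raise RankDeficiencyError("group dummy is constant")
    cov_names = list(covariates) if covariates else []
    cov_cols = [np.asarray(covariates[nm], dtype=float) for nm in cov_names]

    names_full = ["intercept", *cov_names, "x", "group", "x:group"]
    X_full = np.column_stack([np.ones_like(y), *cov_cols, x, g, x * g])
    rng = np.random.default_rng(seed) if n_boot > 0 else None
    full = _ols_fit(y, X_full, names_full, n_boot, rng)

    reduced = None
    reduce_it = full.pvalues["x:group"] >= alpha_reduce
    names_red = ["intercept", *cov_names, "x", "group"]
    X_red = X_full[:, :-1]
    reduced = _ols_fit(y, X_red, names_red, n_boot, rng)
    return ModeratedRegressionResult(
        full=full,
        reduced=reduced,
        reduced_reported=bool(reduce_it),
        dummy_coding=dict(dummy_coding or {"reference": 0, "comparison": 1}),
        alpha_reduce=alpha_reduce,
        seed=seed,
        n_boot=n_boot,
    )


def composite_reading(reading: pd.DataFrame,
                      columns: Sequence[str] = ("reading1", "reading2")) -> pd.Series:
    """Sum of per-measure z-scores over the combined analysed sample.

    Rows missing either measure are dropped (with an index-preserving
    result); a measure with zero variance leaves z undefined and raises.
    """
    cols = list(columns)
    complete = reading.dropna(subset=cols)
    if len(complete) < len(reading):
        import warnings
        warnings.warn(f"dropped {len(reading) - len(complete)} participants "
                      "missing a reading measure", stacklevel=2)
    if len(complete) < 2:
        raise InsufficientDataError("composite needs >= 2 complete participants")
    z = pd.Series(0.0, index=complete.index)
    for c in cols:
        sd = complete[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise UndefinedCorrelationError(f"zero variance in reading measure {c!r}")
        z = z + (complete[c] - complete[c].mean()) / sd
    return z
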