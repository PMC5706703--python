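"""Per-subject analysis: estimation slopes and task performance.

The estimation slope quantifies a subject's reliance on the likelihood.
With positions centered at the prior mean mu, it is the through-origin
least-squares coefficient of responses on splash centroids,

    slope = sum((c_i - mu)(s_hat_i - mu)) / sum((c_i - mu)^2),

so 1 means pure reliance on the splash and 0 pure reliance on the prior.
Centering at the true mu encodes the assumption that subjects learned the
prior mean accurately; a free-intercept fit is available as an option.
Confidence intervals come from a trial-level percentile bootstrap.

Task performance is p(correct), the proportion of trials on which the net
caught the target; trials without a response (timeouts) count as misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import Condition, TaskDesign, DEFAULT_DESIGN, optimal_slope
from .cohort import SubjectDataset

__all__ = [
    "SlopeEstimate",
    "PerformanceSummary",
    "estimation_slope",
    "fit_estimation_slope",
    "bootstrap_slope_ci",
    "p_correct",
    "fit_cohort_slopes",
    "cohort_performance",
]


@dataclass
class SlopeEstimate:
    subject_id: str
    condition: Condition
    slope: float
    ci_low: float
    ci_high: float
    n_trials_used: int
    optimal: float


@dataclass
class PerformanceSummary:
    subject_id: str
    p_correct: float
    n_trials: int


def _clean_xy(
    centroids: Sequence[float], responses: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(centroids, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("centroids and responses must have equal length")
    keep = ~np.isnan(y)
    return c[keep], y[keep]


def estimation_slope(
    centroids: Sequence[float],
    responses: Sequence[float],
    prior_mean: float,
    fit_intercept: bool = False,
) -> float:
    """Estimation slope from paired (centroid, response) arrays.

    Missing responses (NaN) are dropped.  Raises when fewer than two usable
    trials remain or when all centroids coincide with the prior mean (the
    regressor is degenerate).
    """
    c, y = _clean_xy(centroids, responses)
    if c.size < 2:
        raise ValueError(
            f"need >= 2 non-missing trials to fit a slope, got {c.size}"
        )
    cc = c - prior_mean
    yy = y - prior_mean
    den = float(np.dot(cc, cc))
    if den <= 0 or np.isclose(den, 0.0):
        raise ValueError(
            "degenerate condition: centroids carry no variance about the prior mean"
        )
    if fit_intercept:
        X = np.column_stack([np.ones_like(cc), cc])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        return float(beta[1])
    return float(np.dot(cc, yy) / den)


def bootstrap_slope_ci(
    centroids: Sequence[float],
    responses: Sequence[float],
    prior_mean: float,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the estimation slope.

    Resamples trials with replacement ``n_boot`` times; resamples whose
    centered centroids are all zero (probability ~0 for continuous data) are
    dropped.  Deterministic given the seed.
    """
    c, y = _clean_xy(centroids, responses)
    if c.size < 2:
        raise ValueError("need >= 2 non-missing trials to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, c.size, size=(n_boot, c.size))
    cc = c[idx] - prior_mean
    yy = y[idx] - prior_mean
    num = np.einsum("ij,ij->i", cc, yy)
    den = np.einsum("ij,ij->i", cc, cc)
    ok = den > 0
    slopes = num[ok] / den[ok]
    lo, hi = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _centroids(trials: pd.DataFrame) -> np.ndarray:
    splash_cols = [c for c in trials.columns if c.startswith("splash_")]
    if not splash_cols:
        raise ValueError("trial table has no splash_* columns")
    return trials[splash_cols].to_numpy(dtype=float).mean(axis=1)


def fit_estimation_slope(
    trials: pd.DataFrame,
    prior_mean: float,
    condition: Condition,
    n_samples: int,
    fit_intercept: bool = False,
) -> SlopeEstimate:
    """Fit the estimation slope for one subject x condition trial table."""
    c = _centroids(trials)
    y = trials["response"].to_numpy(dtype=float)
    slope = estimation_slope(c, y, prior_mean, fit_intercept=fit_intercept)
    n_used = int(np.sum(~np.isnan(y)))
    return SlopeEstimate(
        subject_id=str(trials["subject_id"].iloc[0]),
        condition=condition,
        slope=slope,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_trials_used=n_used,
        optimal=optimal_slope(condition.prior_sd, condition.likelihood_sd, n_samples),
    )


def p_correct(
    trials: pd.DataFrame,
    net_halfwidth: float = DEFAULT_DESIGN.net_halfwidth,
) -> PerformanceSummary:
    """Proportion of trials caught; timeouts (missing responses) are misses."""
    if len(trials) == 0:
        raise ValueError("p_correct requires at least one trial")
    resp = trials["response"].to_numpy(dtype=float)
    target = trials["target"].to_numpy(dtype=float)
    hit = np.abs(resp - target) <= net_halfwidth
    hit[np.isnan(resp)] = False
    return PerformanceSummary(
        subject_id=str(trials["subject_id"].iloc[0]),
        p_correct=float(hit.mean()),
        n_trials=int(len(trials)),
    )


def fit_cohort_slopes(
    datasets: Iterable[SubjectDataset],
    design: TaskDesign = DEFAULT_DESIGN,
    n_boot: int = 1000,
    seed: int = 0,
    fit_intercept: bool = False,
) -> pd.DataFrame:
    """Tidy table of slopes: one row per subject x condition.

    Trials are pooled across the blocks sharing a prior condition.  Columns:
    subject_id, group, prior_sd, likelihood_sd, prior_label, likelihood_label,
    slope, ci_low, ci_high, optimal, n_trials_used.  ``n_boot=0`` skips the
    bootstrap (CIs become NaN), which is useful in large simulation studies.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    for i, ds in enumerate(datasets):
        trials = ds.trials
        for j, cond in enumerate(design.conditions()):
            sub = trials[
                np.isclose(trials["prior_sd"], cond.prior_sd)
                & np.isclose(trials["likelihood_sd"], cond.likelihood_sd)
            ]
            est = fit_estimation_slope(
                sub, design.prior_mean, cond, design.n_samples,
                fit_intercept=fit_intercept,
            )
            if n_boot > 0:
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(i, j))
                )
                est.ci_low, est.ci_high = bootstrap_slope_ci(
                    _centroids(sub),
                    sub["response"].to_numpy(dtype=float),
                    design.prior_mean,
                    n_boot=n_boot,
                    seed=rng,
                )
            rows.append(
                {
                    "subject_id": est.subject_id,
                    "group": ds.observer.group,
                    "prior_sd": cond.prior_sd,
                    "likelihood_sd": cond.likelihood_sd,
                    "prior_label": cond.prior_label,
                    "likelihood_label": cond.likelihood_label,
                    "slope": est.slope,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "optimal": est.optimal,
                    "n_trials_used": est.n_trials_used,
                }
            )
    return pd.DataFrame(rows)


def cohort_performance(
    datasets: Iterable[SubjectDataset],
    design: TaskDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Per-subject p(correct) table: subject_id, group, age, p_correct, n_trials."""
    rows = []
    for ds in datasets:
        perf = p_correct(ds.trials, design.net_halfwidth)
        rows.append(
            {
                "subject_id": perf.subject_id,
                "group": ds.observer.group,
                "age": ds.observer.age,
                "p_correct": perf.p_correct,
                "n_trials": perf.n_trials,
            }
        )
    return pd.DataFrame(rows)
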