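"""Group-level nonparametric inference.

Two rank-based procedures drive the group analysis:

* Wilcoxon signed-rank tests — per-group comparisons of p(correct) against
  chance and a paired between-group comparison — with an *exact* small-sample
  null distribution.  Ranks of |differences| use average ranks for ties; the
  exact tail probability of the signed-rank sum is obtained by convolving the
  rank generating function (equivalent to enumerating all 2^m sign
  assignments, conditional on the observed ranks).  A normal approximation
  with tie-adjusted variance and continuity correction covers larger samples.

* The Scheirer-Ray-Hare (SRH) test — a Kruskal-Wallis-style extension to
  factorial layouts.  All N observations are ranked jointly (average ranks
  for ties); the crossed-ANOVA sum of squares is computed on the ranks; each
  effect's statistic H = SS_effect / (SS_total / (N - 1)) is referred to a
  chi-squared distribution with the effect's degrees of freedom.  Because the
  divisor is the realized variance of the ranks, ties need no separate
  correction, and the one-factor case reduces exactly to the tie-corrected
  Kruskal-Wallis statistic.  The classical test is two-way; the same
  rank-then-ANOVA recipe extends it to the three-factor layout used here
  (group x prior x likelihood on per-subject-per-condition slopes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "bonferroni",
    "scheirer_ray_hare",
    "slopes_factorial_test",
    "performance_vs_chance",
    "group_performance_test",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: Optional[int]
    p_value: float
    p_adjusted: Optional[float] = None
    method_notes: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "method_notes": self.method_notes,
        }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_tail_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments producing each possible doubled rank sum.

    Average ranks are at worst half-integers, so doubling makes them integers
    and the null distribution of the (doubled) negative-rank sum is the
    convolution of m two-point distributions {0, 2r_i}.  counts[s] is the
    number of the 2^m assignments with doubled sum s; m <= 20 keeps every
    count exactly representable.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        if r == 0:
            counts *= 2.0
        else:
            counts[r:] = counts[r:] + counts[: total + 1 - r]
    return counts


def wilcoxon_signed_rank(
    differences: Sequence[float],
    alternative: str = "two-sided",
    mode: str = "auto",
    name: str = "wilcoxon_signed_rank",
) -> TestResult:
    """Wilcoxon signed-rank test on a sample of paired differences.

    Zero differences are dropped before ranking.  ``alternative`` refers to
    the location of the differences: "greater" tests a positive shift
    (evidence = small negative-rank sum), "less" a negative shift.  The
    reported statistic is the negative-rank sum for "greater", the
    positive-rank sum for "less", and min(T+, T-) for "two-sided".

    ``mode``: "exact" enumerates the conditional null distribution (m <= 20
    in "auto"); "approx" uses the tie-adjusted normal approximation with a
    0.5 continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference sample")
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero; the test is undefined")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    ranks = sps.rankdata(np.abs(d))
    t_minus = float(ranks[d < 0].sum())
    t_plus = float(ranks[d > 0].sum())
    total = t_plus + t_minus

    use_exact = mode == "exact" or (mode == "auto" and m <= 20)
    if use_exact and m > 25:
        raise ValueError(f"exact mode is limited to m <= 25 differences, got {m}")

    if use_exact:
        counts = _signed_rank_tail_counts(np.round(2 * ranks).astype(int))
        denom = 2.0**m
        w2 = int(round(2 * t_minus))
        p_le = counts[: w2 + 1].sum() / denom  # P(T- <= observed)
        p_ge = counts[w2:].sum() / denom       # P(T- >= observed)
        how = f"exact (conditional enumeration of 2^{m} sign assignments)"
    else:
        mean = total / 2.0
        sd = float(np.sqrt(np.sum(ranks**2) / 4.0))
        p_le = float(sps.norm.cdf((t_minus + 0.5 - mean) / sd))
        p_ge = float(sps.norm.sf((t_minus - 0.5 - mean) / sd))
        how = "normal approximation, tie-adjusted variance, continuity correction"

    if alternative == "greater":
        stat, p = t_minus, p_le
    elif alternative == "less":
        stat, p = t_plus, p_ge
    else:
        stat = min(t_plus, t_minus)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(
        name=name,
        statistic=stat,
        df=None,
        p_value=float(min(p, 1.0)),
        method_notes=f"m={m} nonzero differences; {how}; alternative={alternative}",
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError(f"p-values must lie in [0, 1], got {p_values!r}")
    return [float(v) for v in np.minimum(1.0, p * p.size)]


# ---------------------------------------------------------------------------
# Scheirer-Ray-Hare
# ---------------------------------------------------------------------------

def scheirer_ray_hare(
    data: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    effects: Optional[Sequence[str]] = None,
) -> list[TestResult]:
    """Rank-based factorial test on ``data[dv]`` with crossed ``factors``.

    Every cell of the crossed layout must be non-empty.  Returns one
    TestResult per effect (all main effects and interactions by default;
    ``effects`` selects a subset by name, e.g. "group" or "group:prior").
    The sum-of-squares decomposition on the joint ranks is an ordinary
    crossed ANOVA (type II, identical to type I/III on balanced layouts).
    """
    if dv not in data.columns:
        raise ValueError(f"column {dv!r} not in data")
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"factor column {f!r} not in data")
    if len(factors) == 0:
        raise ValueError("at least one factor is required")
    obs = data[dv].to_numpy(dtype=float)
    if np.any(np.isnan(obs)):
        raise ValueError(f"{dv} contains missing values")

    levels = [sorted(data[f].astype(str).unique()) for f in factors]
    present = set(map(tuple, data[list(factors)].astype(str).itertuples(index=False)))
    for cell in itertools.product(*levels):
        if cell not in present:
            named = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            raise ValueError(f"empty design cell: {named}")

    work = data[list(factors)].astype(str).copy()
    work["_rank_"] = sps.rankdata(obs)
    n = len(work)
    ss_total = float(np.sum((work["_rank_"] - work["_rank_"].mean()) ** 2))
    if ss_total == 0:
        raise ValueError("all observations tie; ranks carry no variance")
    ms_total = ss_total / (n - 1)

    formula = "_rank_ ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=work).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    results: list[TestResult] = []
    for row_name, row in table.iterrows():
        if row_name == "Residual":
            continue
        effect = row_name.replace("C(", "").replace(")", "")
        h = float(row["sum_sq"]) / ms_total
        df = int(row["df"])
        results.append(
            TestResult(
                name=f"SRH {effect}",
                statistic=h,
                df=df,
                p_value=float(sps.chi2.sf(h, df)),
                method_notes=(
                    f"Scheirer-Ray-Hare: H = SS_ranks / (SS_total/(N-1)), "
                    f"N={n}, chi2({df}) reference"
                ),
            )
        )
    if effects is not None:
        wanted = set(effects)
        by_name = {r.name.removeprefix("SRH "): r for r in results}
        missing = wanted - set(by_name)
        if missing:
            raise ValueError(f"unknown effects requested: {sorted(missing)}")
        results = [by_name[e] for e in effects]
    return results


# ---------------------------------------------------------------------------
# Study-level wrappers
# ---------------------------------------------------------------------------

def slopes_factorial_test(
    slopes: pd.DataFrame,
    effects: Optional[Sequence[str]] = None,
) -> list[TestResult]:
    """SRH on the tidy slope table: factors group x prior x likelihood."""
    return scheirer_ray_hare(
        slopes,
        dv="slope",
        factors=["group", "prior_label", "likelihood_label"],
        effects=effects,
    )


def performance_vs_chance(
    performance: pd.DataFrame,
    chance: float = 0.02,
    alternative: str = "two-sided",
    mode: str = "auto",
) -> list[TestResult]:
    """Per-group signed-rank tests of p(correct) against chance level,
    Bonferroni-corrected across groups."""
    results = []
    for group, sub in performance.groupby("group", sort=True):
        res = wilcoxon_signed_rank(
            sub["p_correct"].to_numpy() - chance,
            alternative=alternative,
            mode=mode,
            name=f"p_correct vs chance ({group})",
        )
        results.append(res)
    adjusted = bonferroni([r.p_value for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    return results


def group_performance_test(
    performance: pd.DataFrame,
    paired: bool = True,
    alternative: str = "two-sided",
    mode: str = "auto",
) -> TestResult:
    """Between-group comparison of p(correct).

    ``paired=True`` (default) forms age-matched pairs by sorting each group
    by age and runs a signed-rank test on the within-pair differences
    (first group minus second, in sorted group-name order).  ``paired=False``
    runs an unpaired Mann-Whitney U test instead.
    """
    groups = sorted(performance["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    a = performance[performance["group"] == groups[0]].sort_values("age")
    b = performance[performance["group"] == groups[1]].sort_values("age")
    if paired:
        if len(a) != len(b):
            raise ValueError(
                f"paired test needs equal group sizes, got {len(a)} vs {len(b)}"
            )
        diffs = a["p_correct"].to_numpy() - b["p_correct"].to_numpy()
        res = wilcoxon_signed_rank(
            diffs,
            alternative=alternative,
            mode=mode,
            name=f"p_correct {groups[0]} vs {groups[1]} (paired signed-rank)",
        )
        res.method_notes += "; pairs formed by within-group age rank"
        return res
    u = sps.mannwhitneyu(
        a["p_correct"], b["p_correct"], alternative=alternative
    )
    return TestResult(
        name=f"p_correct {groups[0]} vs {groups[1]} (Mann-Whitney U)",
        statistic=float(u.statistic),
        df=None,
        p_value=float(u.pvalue),
        method_notes=f"unpaired rank-sum; alternative={alternative}",
    )
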