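"""Cohort-level behavioral summaries and group tests.

Level-stratified investment trajectories, total-earnings comparisons across
depth-of-thought levels (one-way ANOVA with Tukey HSD pairwise contrasts),
Fisher's exact test on level distributions between trustee groups (full
enumeration on the 2 x k table), and the chi-square test of association on
the joint investor/trustee level table.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, exp

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .game import ExchangeHistory, total_earnings
from .fitting import FitResult

__all__ = [
    "TrajectoryTable",
    "trajectory_summary",
    "earnings_comparison",
    "level_distribution_test",
    "joint_classification_test",
]


@dataclass
class TrajectoryTable:
    """Per level x round mean investment fraction with SE and n."""

    table: pd.DataFrame  # columns: level, round, mean, se, n


def trajectory_summary(
    cohort: list[ExchangeHistory], fits: list[FitResult]
) -> TrajectoryTable:
    """Level-stratified per-round mean investment fractions."""
    if len(cohort) != len(fits):
        raise ValueError("each history needs a FitResult")
    rows = []
    for h, f in zip(cohort, fits):
        if f.best_level is None:
            continue
        for t, rnd in enumerate(h.rounds, start=1):
            rows.append((f.best_level, t, rnd.investment_fraction))
    df = pd.DataFrame(rows, columns=["level", "round", "investment"])
    g = df.groupby(["level", "round"])["investment"]
    out = g.agg(mean="mean", n="count", sd=lambda x: x.std(ddof=1)).reset_index()
    out["se"] = (out.pop("sd") / np.sqrt(out["n"])).fillna(0.0)
    return TrajectoryTable(out[["level", "round", "mean", "se", "n"]])


def earnings_comparison(
    cohort: list[ExchangeHistory], fits: list[FitResult]
) -> dict:
    """One-way ANOVA on total investor earnings by level plus Tukey HSD.

    Returns the omnibus F and p plus a table of pairwise adjusted p-values.
    """
    groups: dict[int, list[float]] = {}
    for h, f in zip(cohort, fits):
        if f.best_level is None:
            continue
        groups.setdefault(f.best_level, []).append(total_earnings(h)[0])
    levels = sorted(k for k, v in groups.items() if len(v) >= 2)
    if len(levels) < 2:
        raise ValueError("need at least two levels with two or more members")
    samples = [groups[k] for k in levels]
    F, p = sps.f_oneway(*samples)
    endog = np.concatenate(samples)
    labels = np.concatenate([[k] * len(groups[k]) for k in levels])
    tk = pairwise_tukeyhsd(endog, labels)
    from itertools import combinations

    pair_rows = []
    for (g1, g2), padj, diff in zip(
        combinations(tk.groupsunique, 2), tk.pvalues, tk.meandiffs
    ):
        pair_rows.append((int(g1), int(g2), float(diff), float(padj)))
    pairs = pd.DataFrame(pair_rows, columns=["level_a", "level_b", "mean_diff", "p_adj"])
    return {"F": float(F), "p": float(p), "tukey": pairs}


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _table_logprob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table with fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    lp -= lgamma(n + 1) + sum(lgamma(x + 1) for x in table.ravel())
    return lp


def level_distribution_test(counts_a, counts_b) -> float:
    """Generalized Fisher's exact test (two-sided) on a 2 x k count table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one.
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts must be two equal-length vectors")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both groups need at least one observation")
    obs = np.vstack([a, b])
    cols = obs.sum(axis=0)
    r1 = int(a.sum())
    lp_obs = _table_logprob(obs)
    k = len(cols)

    total = 0.0
    row = np.zeros(k, dtype=int)

    def rec(j: int, remaining: int):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                row[j] = remaining
                t = np.vstack([row, cols - row])
                lp = _table_logprob(t)
                if lp <= lp_obs + 1e-9:
                    total += exp(lp)
            return
        lo = max(0, remaining - int(cols[j + 1 :].sum()))
        hi = min(int(cols[j]), remaining)
        for x in range(lo, hi + 1):
            row[j] = x
            rec(j + 1, remaining - x)

    rec(0, r1)
    return float(min(total, 1.0))


def joint_classification_test(investor_levels, trustee_levels) -> dict:
    """Pearson chi-square of association on the joint level table.

    Expects paired level labels per dyad; returns the statistic, dof, p and
    the joint table.  Degenerate tables (a single occupied row or column)
    are rejected with guidance to pool categories.
    """
    inv = np.asarray(investor_levels)
    tru = np.asarray(trustee_levels)
    if inv.size != tru.size or inv.size == 0:
        raise ValueError("need equal-length non-empty label vectors")
    table = pd.crosstab(pd.Series(inv, name="investor"), pd.Series(tru, name="trustee"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "degenerate joint table; pool categories before testing"
        )
    chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof), "table": table}
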