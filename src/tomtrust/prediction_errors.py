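"""Interpersonal prediction errors and the quintile high/low contrast.

Two learning signals are extracted per round from the investor's fitted
model state:

* **first-order PE** — the observed repayment ratio minus the investor's
  belief-averaged expectation of it, defined at the moment the repayment is
  revealed; undefined on zero-investment rounds (the trustee had no choice).
* **second-order PE** — the observed investment ratio minus the investor's
  model of the trustee's model of what the investor would send, defined at
  the moment the investment is submitted.  Computable at every
  depth-of-thought level via the nested partner model (the level-0 nested
  model is the myopic terminator).

Pooled within a depth-of-thought level, the errors are split into quintiles
by rank; rounds above the 60th percentile form the "high" group and rounds
at or below the 40th percentile the "low" group, mirroring the contrast used
to interrogate neural responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .game import FRAC_TOL, ExchangeHistory, GameConfig
from .model import (
    RecursiveModelState,
    advance_state,
    expected_investment_distribution,
    expected_repayment_distribution,
    initial_state,
)

__all__ = [
    "PESeries",
    "QuintileLabels",
    "first_order_pe",
    "second_order_pe",
    "extract_pe_series",
    "quintile_split",
    "membership_audit",
    "high_low_contrast",
]


@dataclass
class PESeries:
    """Per-round interpersonal prediction errors for one dyad.

    ``pe1[t]`` is ``None`` on zero-investment rounds.  ``units`` is
    ``"fraction"`` internally; :meth:`as_percent` rescales by 100.  The event
    timing is fixed by definition: pe1 at repayment reveal, pe2 at
    investment submission.
    """

    dyad_id: str
    pe1: list[float | None]
    pe2: list[float]
    units: str = "fraction"

    def as_percent(self) -> "PESeries":
        if self.units == "percent":
            return self
        return PESeries(
            self.dyad_id,
            [None if v is None else 100.0 * v for v in self.pe1],
            [100.0 * v for v in self.pe2],
            units="percent",
        )


@dataclass
class QuintileLabels:
    """Rank-based quintile assignment of pooled PE values.

    ``quintile`` holds indices 1-5; ``group`` holds "low" (quintiles 1-2,
    at or below the 40th percentile), "mid" (quintile 3) or "high"
    (quintiles 4-5, above the 60th percentile).
    """

    quintile: np.ndarray
    group: np.ndarray
    subject_ids: np.ndarray | None = None


def first_order_pe(
    state: RecursiveModelState,
    investment_fraction: float,
    actual_repayment_fraction: float | None,
    config: GameConfig,
) -> float | None:
    """Observed minus expected repayment ratio, at repayment reveal.

    ``state`` is the investor's state at the start of the round (before
    observing the repayment); the modeled expectation conditions on the
    actual investment.  Returns ``None`` for zero-investment rounds.
    """
    if abs(investment_fraction) <= FRAC_TOL or actual_repayment_fraction is None:
        return None
    dist = expected_repayment_distribution(state, investment_fraction, config)
    expected = float(dist @ np.asarray(config.trustee_grid))
    return float(actual_repayment_fraction - expected)


def second_order_pe(
    state: RecursiveModelState,
    actual_investment_fraction: float,
    config: GameConfig,
) -> float:
    """Observed investment minus the nested model's expectation of it."""
    dist = expected_investment_distribution(state, config)
    expected = float(dist @ np.asarray(config.investor_grid))
    return float(actual_investment_fraction - expected)


def extract_pe_series(
    history: ExchangeHistory,
    level: int,
    noise: float,
    config: GameConfig,
    guilt: float | None = None,
) -> PESeries:
    """Replay a history through a fitted investor model, collecting both
    prediction errors each round."""
    guilt = config.guilt_grid[0] if guilt is None else guilt
    state = initial_state("investor", level, config, noise, guilt=guilt)
    pe1s: list[float | None] = []
    pe2s: list[float] = []
    for rnd in history.rounds:
        pe2s.append(second_order_pe(state, rnd.investment_fraction, config))
        pe1s.append(
            first_order_pe(
                state, rnd.investment_fraction, rnd.repayment_fraction, config
            )
        )
        state = advance_state(
            state, rnd.investment_fraction, rnd.repayment_fraction, config
        )
    return PESeries(history.dyad_id, pe1s, pe2s)


def quintile_split(values, subject_ids=None) -> QuintileLabels:
    """Rank-based quintile labels for pooled PE values.

    Tied blocks take the quintile of their smallest rank (the conservative
    choice for the high-vs-low contrast); an all-equal input is wholly
    "mid".  Requires at least 5 observations.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or np.any(np.isnan(v)):
        raise ValueError("values must be a 1-d array with nulls already removed")
    n = v.size
    if n < 5:
        raise ValueError("need at least 5 observations to form quintiles")
    if np.all(v == v[0]):
        quint = np.full(n, 3, dtype=int)
    else:
        ranks = rankdata(v, method="min")
        quint = np.ceil(5.0 * ranks / n).astype(int)
    group = np.where(quint <= 2, "low", np.where(quint >= 4, "high", "mid"))
    sid = None if subject_ids is None else np.asarray(subject_ids)
    if sid is not None and sid.size != n:
        raise ValueError("subject_ids must align with values")
    return QuintileLabels(quintile=quint, group=group, subject_ids=sid)


def membership_audit(labels: QuintileLabels, subject_ids=None) -> dict:
    """Count subjects contributing rounds only to the high group, only to the
    low group, or to both (the audit guarding against a few subjects driving
    the high-vs-low contrast)."""
    sid = labels.subject_ids if subject_ids is None else np.asarray(subject_ids)
    if sid is None:
        raise ValueError("subject ids are required for the membership audit")
    out = {"only_high": 0, "only_low": 0, "both": 0, "neither": 0}
    for s in np.unique(sid):
        g = labels.group[sid == s]
        has_hi, has_lo = "high" in g, "low" in g
        if has_hi and has_lo:
            out["both"] += 1
        elif has_hi:
            out["only_high"] += 1
        elif has_lo:
            out["only_low"] += 1
        else:
            out["neither"] += 1
    total = sum(out.values())
    out["total"] = total
    out["fraction_both"] = out["both"] / total if total else float("nan")
    return out


def high_low_contrast(pe_values, labels: QuintileLabels) -> tuple[float, float]:
    """Difference of high-group and low-group means with its standard error."""
    v = np.asarray(pe_values, dtype=float)
    hi = v[labels.group == "high"]
    lo = v[labels.group == "low"]
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups need at least one observation")
    diff = hi.mean() - lo.mean()
    se = float(
        np.sqrt(
            (hi.var(ddof=1) / hi.size if hi.size > 1 else 0.0)
            + (lo.var(ddof=1) / lo.size if lo.size > 1 else 0.0)
        )
    )
    return float(diff), se
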