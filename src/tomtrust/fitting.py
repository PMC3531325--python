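"""Maximum-likelihood classification of players by depth-of-thought and guilt.

Each player's 10-round choice sequence is scored under every candidate
(level, guilt, noise) triple by replaying the history through the generative
model: beliefs are advanced with the true observations and each observed own
action is scored under the softmax of the model's action values.  The search
is a pure grid (types and levels are discrete), making ties and
reproducibility exact; ties break toward the lower level, then lower guilt,
then lower noise.

Model comparison is by summed log-likelihood; parameter counts are equal
across levels within this design, so no AIC/BIC correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import FRAC_TOL, ExchangeHistory, GameConfig
from .model import PlayerSpec, _softmax, get_engine

__all__ = [
    "FitResult",
    "CohortTable",
    "sequence_loglik",
    "fit_player",
    "classify_cohort",
]


@dataclass
class FitResult:
    """Best-fitting generative parameters for one player."""

    dyad_id: str
    role: str
    best_level: int | None
    best_guilt: float | None
    best_noise: float | None
    log_likelihood: float
    per_round_loglik: list[float]
    baseline_loglik: float
    n_observed: int
    identifiable: bool = True


@dataclass
class CohortTable:
    """Depth-of-thought histogram per cohort label."""

    counts: pd.DataFrame  # index: group_label; columns: levels 0..2

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _initial_arrays(level: int, n_types: int) -> tuple[np.ndarray, ...]:
    """Uniform beliefs at every nesting depth (level+2 vectors)."""
    return tuple(np.full(n_types, 1.0 / n_types) for _ in range(level + 2))


def _per_round_loglik_grid(
    history: ExchangeHistory,
    role: str,
    level: int,
    noise: float,
    config: GameConfig,
) -> np.ndarray:
    """Log-likelihood of each observed own choice, for every candidate own
    guilt at once: (n_guilt, n_rounds).  Trustee rounds after a zero
    investment contribute 0 (no observable choice)."""
    eng = get_engine(config, noise)
    nG = len(config.guilt_grid)
    arrays = _initial_arrays(level, nG)
    out = np.zeros((nG, len(history.rounds)))
    for t, rnd in enumerate(history.rounds, start=1):
        i_idx = config.grid_index(rnd.investment_fraction, config.investor_grid)
        r_idx = (
            None
            if rnd.repayment_fraction is None
            else config.grid_index(rnd.repayment_fraction, config.trustee_grid)
        )
        if role == "investor":
            q = eng.q_investor(level, arrays, t)  # (g, i)
            p = _softmax(noise * q, axis=-1)
            out[:, t - 1] = np.log(np.maximum(p[:, i_idx], 1e-300))
            arrays = eng.advance_investor_arrays_on_investment(level, arrays, i_idx, t)
            arrays = eng.advance_investor_arrays_on_repayment(
                level, arrays, i_idx, r_idx, t
            )
        else:
            arrays = eng.advance_trustee_arrays_on_investment(level, arrays, i_idx, t)
            if r_idx is not None and not eng.zero_rows[i_idx]:
                full = tuple(eng._full_i(a) for a in arrays)
                q = eng.q_trustee(level, full, t)[i_idx]  # (g, r)
                p = _softmax(noise * q, axis=-1)
                out[:, t - 1] = np.log(np.maximum(p[:, r_idx], 1e-300))
            arrays = eng.advance_trustee_arrays_on_repayment(
                level, arrays, i_idx, r_idx, t
            )
    return out


def sequence_loglik(
    history: ExchangeHistory, player_spec: PlayerSpec, config: GameConfig
) -> tuple[float, list[float]]:
    """Total and per-round log-likelihood of a player's observed choices."""
    if player_spec.guilt is None:
        raise ValueError("sequence_loglik needs a concrete guilt")
    g_idx = config.grid_index(player_spec.guilt, config.guilt_grid)
    grid = _per_round_loglik_grid(
        history, player_spec.role, player_spec.level, player_spec.noise, config
    )
    per_round = grid[g_idx]
    return float(per_round.sum()), per_round.tolist()


def _n_observed(history: ExchangeHistory, role: str) -> int:
    if role == "investor":
        return len(history.rounds)
    return sum(1 for r in history.rounds if r.investment_fraction > FRAC_TOL)


def fit_player(
    history: ExchangeHistory, role: str, config: GameConfig
) -> FitResult:
    """Exhaustive grid ML over level x guilt x noise for one player."""
    n_actions = len(config.grid_for_role(role))
    n_obs = _n_observed(history, role)
    baseline = n_obs * np.log(1.0 / n_actions)
    if n_obs == 0:
        return FitResult(
            dyad_id=history.dyad_id,
            role=role,
            best_level=None,
            best_guilt=None,
            best_noise=None,
            log_likelihood=0.0,
            per_round_loglik=[0.0] * len(history.rounds),
            baseline_loglik=0.0,
            n_observed=0,
            identifiable=False,
        )
    candidates = []  # (level, guilt, noise, total_ll, per_round)
    for level in (0, 1, 2):
        for noise in config.noise_grid:
            grid = _per_round_loglik_grid(history, role, level, noise, config)
            totals = grid.sum(axis=1)
            for g_idx, guilt in enumerate(config.guilt_grid):
                candidates.append(
                    (level, guilt, noise, float(totals[g_idx]), grid[g_idx])
                )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best = candidates[0]
    for c in candidates[1:]:
        if c[3] > best[3]:
            best = c
    return FitResult(
        dyad_id=history.dyad_id,
        role=role,
        best_level=best[0],
        best_guilt=best[1],
        best_noise=best[2],
        log_likelihood=best[3],
        per_round_loglik=best[4].tolist(),
        baseline_loglik=float(baseline),
        n_observed=n_obs,
    )


def classify_cohort(
    histories: list[ExchangeHistory],
    config: GameConfig,
    role: str = "investor",
) -> tuple[CohortTable, list[FitResult]]:
    """Fit every player of the given role and tabulate levels per cohort."""
    if not histories:
        raise ValueError("need at least one history")
    seen = set()
    for h in histories:
        if h.dyad_id in seen:
            raise ValueError(f"duplicate dyad_id {h.dyad_id!r}")
        seen.add(h.dyad_id)
    fits = [fit_player(h, role, config) for h in histories]
    rows: dict[str, dict[int, int]] = {}
    for h, f in zip(histories, fits):
        if f.best_level is None:
            continue
        rows.setdefault(h.group_label, {0: 0, 1: 0, 2: 0})
        rows[h.group_label][f.best_level] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=[0, 1, 2], fill_value=0
    )
    table.index.name = "group_label"
    return CohortTable(table.fillna(0).astype(int)), fits
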