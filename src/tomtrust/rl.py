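"""Inequity-averse reinforcement-learning comparison model.

A model-free alternative to the recursive theory-of-mind account: each
player keeps a running value estimate per own action, updated by a delta
rule toward the inequity-averse (guilt) utility realized on the round, and
chooses via a softmax with slope ``k`` mixed with a uniform lapse of weight
``b``.  With learning rate 0 and symmetric initial values the model is
exactly the uniform random-choice baseline — the degenerate regime the
theory-of-mind model is compared against.

Parameter semantics: the slope/lapse pair is one concrete realization of a
choice-precision and action-mixing parameterization; it can represent the
all-actions-equally-likely optimum exactly (``k -> 0`` or ``b -> 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game import FRAC_TOL, ExchangeHistory, GameConfig
from .model import _softmax, utility

__all__ = ["RLParams", "RLGrids", "rl_update", "rl_choice_distribution", "fit_rl"]


@dataclass(frozen=True)
class RLParams:
    """Parameters of the inequity-averse RL model."""

    learning_rate: float  # lambda in [0, 1]
    slope: float  # k >= 0, softmax precision
    mixing: float  # b in [0, 1], uniform-lapse weight
    guilt: float = 0.0
    initial_q: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")


@dataclass(frozen=True)
class RLGrids:
    """Search grids for the RL fit."""

    learning_rate: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    slope: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    mixing: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


def rl_update(
    q_values: np.ndarray,
    chosen_action: int,
    realized_utility: float,
    learning_rate: float,
) -> np.ndarray:
    """Delta-rule update of the chosen action's value; others unchanged."""
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError("learning_rate must lie in [0, 1]")
    q = np.array(q_values, dtype=float)
    q[chosen_action] += learning_rate * (realized_utility - q[chosen_action])
    return q


def rl_choice_distribution(q_values: np.ndarray, params: RLParams) -> np.ndarray:
    """``(1-b) * softmax(k*Q) + b * uniform``; every probability >= b/n."""
    q = np.asarray(q_values, dtype=float)
    n = q.size
    return (1 - params.mixing) * _softmax(params.slope * q) + params.mixing / n


def _observed_choices(history: ExchangeHistory, role: str, config: GameConfig):
    """(action_index, realized_utility_per_guilt) per observable choice.

    Utilities are the guilt utilities of the round's realized payoffs, one
    column per candidate guilt value.
    """
    out = []
    for rnd in history.rounds:
        if role == "investor":
            idx = config.grid_index(rnd.investment_fraction, config.investor_grid)
            own, other = rnd.investor_payoff, rnd.trustee_payoff
        else:
            if rnd.investment_fraction <= FRAC_TOL:
                continue
            idx = config.grid_index(rnd.repayment_fraction, config.trustee_grid)
            own, other = rnd.trustee_payoff, rnd.investor_payoff
        utils = np.array([utility(own, other, g) for g in config.guilt_grid])
        out.append((idx, utils))
    return out


def fit_rl(
    history: ExchangeHistory,
    role: str,
    config: GameConfig,
    grids: RLGrids | None = None,
) -> tuple[RLParams, float]:
    """Grid ML over learning rate x slope x mixing x guilt.

    Ties break toward smaller (learning_rate, slope, mixing, guilt), so the
    degenerate no-learning optimum is reported as such when nothing beats it.
    """
    grids = grids or RLGrids()
    n_actions = len(config.grid_for_role(role))
    choices = _observed_choices(history, role, config)
    if not choices:
        return RLParams(0.0, 0.0, 1.0), 0.0
    best: tuple | None = None
    ks = np.asarray(grids.slope)
    for lam in grids.learning_rate:
        for g_idx, guilt in enumerate(config.guilt_grid):
            # value trajectory depends only on (lambda, guilt)
            q = np.zeros(n_actions)
            # log-probabilities for every (k, b) pair at once
            logp = np.zeros((len(grids.slope), len(grids.mixing)))
            for idx, utils in choices:
                p_soft = _softmax(ks[:, None] * q[None, :], axis=-1)[:, idx]
                for b_j, b in enumerate(grids.mixing):
                    p = (1 - b) * p_soft + b / n_actions
                    logp[:, b_j] += np.log(np.maximum(p, 1e-300))
                q = rl_update(q, idx, float(utils[g_idx]), lam)
            for k_i, k in enumerate(grids.slope):
                for b_j, b in enumerate(grids.mixing):
                    cand = (
                        float(logp[k_i, b_j]),
                        -lam,
                        -k,
                        -b,
                        -guilt,
                        RLParams(lam, k, b, guilt),
                    )
                    if best is None or cand[:5] > best[:5]:
                        best = cand
    assert best is not None
    return best[5], best[0]
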