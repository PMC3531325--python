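"""Mechanics of the multi-round trust game.

Each round the investor is endowed with a fixed amount of money and sends a
fraction ``I`` of it to the trustee.  The investment is multiplied (tripled by
default) in transit, and the trustee returns a fraction ``R`` of the multiplied
amount.  Both players choose from small ordered grids of fractions ("five
possible actions" each by default).  A dyad plays ``num_rounds`` consecutive
rounds with the same partner.

This module knows nothing about beliefs or planning; it only implements money
flows, action grids, discretization of raw dollar amounts onto the grids, and
exchange histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GameConfig",
    "Round",
    "ExchangeHistory",
    "GridError",
    "ProtocolError",
    "RangeError",
    "EmptyHistoryError",
    "play_round",
    "discretize_amount",
    "total_earnings",
    "DEFAULT_INVESTOR_GRID",
    "DEFAULT_TRUSTEE_GRID",
    "DEFAULT_GUILT_GRID",
    "DEFAULT_NOISE_GRID",
]

#: Fractions of the endowment the investor may send.
DEFAULT_INVESTOR_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
#: Fractions of the multiplied investment the trustee may return.  Includes the
#: exact-return anchor (1/3 of 3I repays the original investment) and the
#: even-split anchor (1/2), the modal trustee behavior.
DEFAULT_TRUSTEE_GRID = (0.0, 1.0 / 6.0, 1.0 / 3.0, 0.5, 2.0 / 3.0)
#: Candidate guilt (advantageous-inequity-aversion) values for player types.
DEFAULT_GUILT_GRID = (0.0, 0.4, 1.0)
#: Candidate decision-noise (softmax inverse temperature) values, in 1/dollar.
DEFAULT_NOISE_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)

#: Tolerance for comparing money fractions.
FRAC_TOL = 1e-9


class GridError(ValueError):
    """A fraction is not an element of the relevant action grid."""


class ProtocolError(ValueError):
    """An exchange violates the game protocol (e.g. repayment on zero investment)."""


class RangeError(ValueError):
    """A raw amount exceeds the base amount it is a fraction of."""


class EmptyHistoryError(ValueError):
    """An operation requiring at least one round received an empty history."""


@dataclass(frozen=True)
class GameConfig:
    """Static parameters of the trust game and of the model grids.

    Money is in dollars ("points").  ``horizon`` is the number of rounds a
    player evaluates when planning (the current round and the round after).
    """

    endowment: float = 20.0
    multiplier: float = 3.0
    num_rounds: int = 10
    investor_grid: tuple[float, ...] = DEFAULT_INVESTOR_GRID
    trustee_grid: tuple[float, ...] = DEFAULT_TRUSTEE_GRID
    guilt_grid: tuple[float, ...] = DEFAULT_GUILT_GRID
    noise_grid: tuple[float, ...] = DEFAULT_NOISE_GRID
    horizon: int = 2

    def __post_init__(self) -> None:
        if self.endowment <= 0:
            raise ValueError("endowment must be positive")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.num_rounds < 1:
            raise ValueError("num_rounds must be at least 1")
        if self.horizon != 2:
            raise ValueError("only a two-round planning horizon is supported")
        for name in ("investor_grid", "trustee_grid", "guilt_grid", "noise_grid"):
            grid = getattr(self, name)
            if len(grid) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b - a <= 0 for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        for name in ("investor_grid", "trustee_grid"):
            grid = getattr(self, name)
            if grid[0] < -FRAC_TOL or grid[-1] > 1 + FRAC_TOL:
                raise ValueError(f"{name} fractions must lie in [0, 1]")
        if any(g < 0 for g in self.guilt_grid):
            raise ValueError("guilt values must be non-negative")
        if any(n < 0 for n in self.noise_grid):
            raise ValueError("noise values must be non-negative")

    def grid_for_role(self, role: str) -> tuple[float, ...]:
        if role == "investor":
            return self.investor_grid
        if role == "trustee":
            return self.trustee_grid
        raise ValueError(f"unknown role {role!r}")

    def grid_index(self, fraction: float, grid: tuple[float, ...]) -> int:
        """Index of ``fraction`` on ``grid``; raises :class:`GridError` if absent."""
        for idx, g in enumerate(grid):
            if abs(g - fraction) <= FRAC_TOL:
                return idx
        raise GridError(f"fraction {fraction!r} is not on grid {grid!r}")


@dataclass(frozen=True)
class Round:
    """One completed exchange: fractions chosen and the resulting payoffs.

    ``repayment_fraction`` is ``None`` exactly when the investment was zero
    (the trustee then has no observable choice).
    """

    investment_fraction: float
    repayment_fraction: float | None
    investor_payoff: float
    trustee_payoff: float


@dataclass
class ExchangeHistory:
    """The per-dyad record of play, rounds in 1..t order."""

    dyad_id: str
    rounds: list[Round] = field(default_factory=list)
    group_label: str = ""

    def __len__(self) -> int:
        return len(self.rounds)


def play_round(
    investment_fraction: float,
    repayment_fraction: float | None,
    config: GameConfig,
) -> Round:
    """Resolve one round of the trust game into payoffs.

    The investor keeps ``endowment * (1 - I)``; the trustee receives
    ``multiplier * I * endowment`` and returns fraction ``R`` of it.
    """
    i_idx = config.grid_index(investment_fraction, config.investor_grid)
    invest = config.investor_grid[i_idx]
    if abs(invest) <= FRAC_TOL:
        if repayment_fraction is not None:
            raise ProtocolError("repayment given on a zero investment")
        return Round(invest, None, config.endowment, 0.0)
    if repayment_fraction is None:
        raise ProtocolError("missing repayment on a positive investment")
    r_idx = config.grid_index(repayment_fraction, config.trustee_grid)
    repay = config.trustee_grid[r_idx]
    pot = config.multiplier * invest * config.endowment
    investor_payoff = config.endowment * (1 - invest) + repay * pot
    trustee_payoff = pot * (1 - repay)
    return Round(invest, repay, investor_payoff, trustee_payoff)


def discretize_amount(
    raw_amount: float, base_amount: float, grid: tuple[float, ...]
) -> float:
    """Map an observed dollar amount onto the nearest grid fraction of ``base_amount``.

    Ties are broken toward the smaller fraction.  Raises :class:`RangeError`
    when the amount exceeds the base beyond tolerance.
    """
    if base_amount <= 0:
        raise ValueError("base_amount must be positive")
    if raw_amount < -FRAC_TOL:
        raise ValueError("raw_amount must be non-negative")
    ratio = raw_amount / base_amount
    if ratio > 1 + 1e-6:
        raise RangeError(
            f"amount {raw_amount} exceeds base {base_amount} beyond tolerance"
        )
    best = grid[0]
    best_dist = abs(ratio - grid[0])
    for g in grid[1:]:
        d = abs(ratio - g)
        if d < best_dist - FRAC_TOL:
            best, best_dist = g, d
        # ties (within tolerance) keep the earlier, smaller fraction
    return best


def total_earnings(history: ExchangeHistory) -> tuple[float, float]:
    """Total money earned by (investor, trustee) over a history."""
    if not history.rounds:
        raise EmptyHistoryError("history has no rounds")
    inv = sum(r.investor_payoff for r in history.rounds)
    tr = sum(r.trustee_payoff for r in history.rounds)
    return inv, tr
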