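"""Synthetic dyad generation under the generative level-k model.

No behavioral logs are publicly deposited for the original cohorts, so every
analysis stage in this package is exercised on dyads simulated from the
generative model itself.  A cohort draws each investor's depth-of-thought
level and guilt type from stated mixtures; trustees come in two behavioral
phenotypes:

* ``healthy`` — levels and guilt drawn from cooperative mixtures (most
  trustees are inequity-averse enough to repay), emulating the anonymous
  healthy partners;
* ``uncooperative`` — guilt-0, myopic (level 0), near-greedy trustees who
  keep what they receive, a purely behavioral stand-in for the partners who
  could not sustain their investors' cooperation.  It is not a clinical
  model of borderline personality disorder.

Every dyad is simulated from its own seed substream spawned from the cohort
master seed, so cohorts are reproducible and individually re-simulable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import ExchangeHistory, GameConfig, play_round
from .model import PlayerSpec, _softmax, get_engine

__all__ = ["CohortSpec", "DyadTrace", "simulate_dyad", "generate_cohort"]

#: Generation decision noise (softmax inverse temperature, 1/dollar).
#: Calibrated so that level recovery by the fitting grid is feasible but
#: imperfect (confusion-matrix diagonal targeted at roughly the 0.7-0.9
#: band), keeping recovery experiments informative.  Softer policies are
#: essential here: at sharp noise the level-1 and level-2 partner models
#: produce identical action distributions and the levels become
#: unidentifiable.
DEFAULT_GENERATION_NOISE = 0.5

#: Cooperative-trustee phenotype mixtures.
HEALTHY_TRUSTEE_LEVELS = (0.5, 0.25, 0.25)
HEALTHY_TRUSTEE_GUILT = (0.2, 0.4, 0.4)


@dataclass
class CohortSpec:
    """Generative description of a simulated cohort of dyads."""

    n_dyads: int
    investor_level_proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    investor_guilt_mixture: tuple[float, ...] = (0.25, 0.5, 0.25)
    noise: float = DEFAULT_GENERATION_NOISE
    trustee_style: str = "healthy"
    seed: int = 0
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be at least 1")
        for name in ("investor_level_proportions", "investor_guilt_mixture"):
            p = getattr(self, name)
            if abs(sum(p) - 1.0) > 1e-9 or any(x < 0 for x in p):
                raise ValueError(f"{name} must be a probability vector")
        if self.trustee_style not in ("healthy", "uncooperative"):
            raise ValueError("trustee_style must be 'healthy' or 'uncooperative'")


@dataclass
class DyadTrace:
    """The generative ground truth of one simulated dyad: per-round choice
    probabilities, beliefs and prediction errors (the oracle surface for
    self-consistency tests), plus the true player specs."""

    investor_spec: PlayerSpec
    trustee_spec: PlayerSpec
    rounds: list[dict] = field(default_factory=list)

    @property
    def investor_loglik(self) -> float:
        return float(sum(np.log(r["investor_prob_chosen"]) for r in self.rounds))

    @property
    def trustee_loglik(self) -> float:
        return float(
            sum(
                np.log(r["trustee_prob_chosen"])
                for r in self.rounds
                if r["trustee_prob_chosen"] is not None
            )
        )


def _initial_arrays(level: int, n_types: int) -> tuple[np.ndarray, ...]:
    return tuple(np.full(n_types, 1.0 / n_types) for _ in range(level + 2))


def simulate_dyad(
    investor_spec: PlayerSpec,
    trustee_spec: PlayerSpec,
    config: GameConfig,
    seed: int | np.random.Generator,
    dyad_id: str = "dyad",
    group_label: str = "",
) -> tuple[ExchangeHistory, DyadTrace]:
    """Play one full game between two generative agents.

    Actions are sampled from each player's softmax action distribution;
    the trace records every per-round choice probability, the investor's
    belief, and both interpersonal prediction errors.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nG = len(config.guilt_grid)
    eng_i = get_engine(config, investor_spec.noise)
    eng_t = get_engine(config, trustee_spec.noise)
    gi = config.grid_index(investor_spec.guilt, config.guilt_grid)
    gt = config.grid_index(trustee_spec.guilt, config.guilt_grid)
    li, lt = investor_spec.level, trustee_spec.level
    inv_arrays = _initial_arrays(li, nG)
    tr_arrays = _initial_arrays(lt, nG)
    gI = np.asarray(config.investor_grid)
    gR = np.asarray(config.trustee_grid)

    history = ExchangeHistory(dyad_id, [], group_label)
    trace = DyadTrace(investor_spec, trustee_spec)
    for t in range(1, config.num_rounds + 1):
        pred_inv = eng_i.nested_investment_prediction(li, inv_arrays, t)
        e_invest = float(pred_inv @ gI)

        qi = eng_i.q_investor(li, inv_arrays, t)[gi]
        pi = _softmax(investor_spec.noise * qi)
        i_idx = int(rng.choice(len(gI), p=pi))
        pe2 = float(gI[i_idx] - e_invest)

        P = eng_i.investor_trustee_policy(li, inv_arrays, i_idx, t)
        e_repay = float((inv_arrays[0] @ P) @ gR)

        tr_arrays = eng_t.advance_trustee_arrays_on_investment(
            lt, tr_arrays, i_idx, t
        )
        if eng_t.zero_rows[i_idx]:
            r_idx = None
            pt = None
            qt = None
            pe1 = None
        elif trustee_spec.myopic:
            # single-round greedy phenotype: softmax of immediate utility
            qt = eng_t.U_tr[gt, i_idx, :]
            pt = _softmax(trustee_spec.noise * qt)
            r_idx = int(rng.choice(len(gR), p=pt))
            pe1 = float(gR[r_idx] - e_repay)
        else:
            full = tuple(eng_t._full_i(a) for a in tr_arrays)
            qt = eng_t.q_trustee(lt, full, t)[i_idx, gt]
            pt = _softmax(trustee_spec.noise * qt)
            r_idx = int(rng.choice(len(gR), p=pt))
            pe1 = float(gR[r_idx] - e_repay)

        rep = None if r_idx is None else float(gR[r_idx])
        history.rounds.append(play_round(float(gI[i_idx]), rep, config))
        trace.rounds.append(
            {
                "round": t,
                "investor_q": qi.tolist(),
                "investor_probs": pi.tolist(),
                "investor_prob_chosen": float(pi[i_idx]),
                "investment_fraction": float(gI[i_idx]),
                "trustee_q": None if qt is None else qt.tolist(),
                "trustee_probs": None if pt is None else pt.tolist(),
                "trustee_prob_chosen": None if pt is None else float(pt[r_idx]),
                "repayment_fraction": rep,
                "investor_belief": inv_arrays[0].tolist(),
                "pe1": pe1,
                "pe2": pe2,
            }
        )

        inv_arrays = eng_i.advance_investor_arrays_on_investment(
            li, inv_arrays, i_idx, t
        )
        inv_arrays = eng_i.advance_investor_arrays_on_repayment(
            li, inv_arrays, i_idx, r_idx, t
        )
        tr_arrays = eng_t.advance_trustee_arrays_on_repayment(
            lt, tr_arrays, i_idx, r_idx, t
        )
    return history, trace


def _draw_specs(
    spec: CohortSpec, config: GameConfig, rng: np.random.Generator
) -> tuple[PlayerSpec, PlayerSpec]:
    guilt_grid = config.guilt_grid
    inv_level = int(rng.choice(3, p=spec.investor_level_proportions))
    inv_guilt = float(rng.choice(guilt_grid, p=spec.investor_guilt_mixture))
    investor = PlayerSpec("investor", inv_level, inv_guilt, spec.noise)
    if spec.trustee_style == "uncooperative":
        trustee = PlayerSpec("trustee", 0, guilt_grid[0], 4.0, myopic=True)
    else:
        tr_level = int(rng.choice(3, p=HEALTHY_TRUSTEE_LEVELS))
        tr_guilt = float(rng.choice(guilt_grid, p=HEALTHY_TRUSTEE_GUILT))
        trustee = PlayerSpec("trustee", tr_level, tr_guilt, spec.noise)
    return investor, trustee


def generate_cohort(
    spec: CohortSpec,
    config: GameConfig,
    return_details: bool = False,
):
    """Simulate ``n_dyads`` independent dyads from a cohort description.

    Each dyad runs on its own seed substream spawned from ``spec.seed``.
    With ``return_details`` the traces and true player specs are returned as
    well (for recovery experiments and self-consistency tests).
    """
    master = np.random.SeedSequence(spec.seed)
    histories: list[ExchangeHistory] = []
    traces: list[DyadTrace] = []
    for k, child in enumerate(master.spawn(spec.n_dyads)):
        rng = np.random.default_rng(child)
        investor, trustee = _draw_specs(spec, config, rng)
        label = spec.group_label or spec.trustee_style
        h, tr = simulate_dyad(
            investor, trustee, config, rng, dyad_id=f"{label}-{k:04d}",
            group_label=label,
        )
        histories.append(h)
        traces.append(tr)
    if return_details:
        return histories, traces
    return histories
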