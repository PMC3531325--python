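"""Generative level-k theory-of-mind model of trust-game play.

Players are characterized by a *type* (the guilt parameter of an
inequity-averse utility; envy is fixed to zero) and a *depth-of-thought*
level k in {0, 1, 2}.  A player maintains a probability distribution
("belief") over the partner's guilt type and updates it by Bayes' rule from
observed actions.  A level-k player interprets the partner as a level-(k-1)
player and simulates that partner's play, including the partner's beliefs
about the player; recursion terminates at a *myopic* model that evaluates
single-round utilities only.

Action values follow a two-round evaluation: the value of an action is its
expected current-round utility under the believed partner policy plus, except
in the last round, the expectation (over partner types and partner actions)
of the best achievable next-round expected utility with beliefs updated by
the same Bayes operator.  Stochastic choice is a softmax over action values
with inverse temperature ``noise`` (dollars^-1).

Model semantics in one place
----------------------------
With investment grid ``I``, repayment grid ``R``, guilt grid ``Theta``,
endowment ``E`` and multiplier ``M``:

* money: investor gets ``E(1-I) + R*M*E*I``; trustee gets ``M*E*I*(1-R)``;
  a zero investment leaves the trustee no choice (null action).
* utility: ``u(own, other; beta) = own - beta * max(own - other, 0)``.
* myopic trustee policy ``pi_m(R | I, theta)``: softmax of the trustee's
  single-round utility.  This is the recursion terminator.
* myopic investor policy ``pi_m(I | theta, c)``: softmax of the single-round
  investment utility expected under the myopic trustee policy averaged over a
  belief ``c`` about the trustee's guilt (uniform when the model in question
  carries no such belief).
* a level-0 player interprets the partner through the myopic policy; its
  nested partner model carries only a belief about the player (used for the
  second-order expectation and updated with the uniform-belief myopic
  likelihood).
* a level-k (k>=1) player interprets the partner as a level-(k-1) player:
  the modeled partner's action distribution is the softmax of that partner's
  own two-round action values, computed on the nested state.
* observation flow within a round: the trustee (and every nested model of a
  trustee) updates its belief about the investor when the investment is
  observed, *before* choosing the repayment; beliefs about the trustee update
  when the repayment is revealed.  Zero investments reveal nothing about the
  trustee.  The same operators run inside the lookahead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .game import FRAC_TOL, GameConfig

__all__ = [
    "PlayerSpec",
    "Belief",
    "MyopicModel",
    "RecursiveModelState",
    "QTable",
    "utility",
    "myopic_partner_policy",
    "partner_policy",
    "update_belief",
    "q_values",
    "action_distribution",
    "initial_state",
    "advance_state",
    "expected_repayment_distribution",
    "expected_investment_distribution",
    "get_engine",
]

_BELIEF_TOL = 1e-9


# ---------------------------------------------------------------------------
# public domain types
# ---------------------------------------------------------------------------


@dataclass
class Belief:
    """A normalized probability distribution over the guilt grid."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("belief must be a non-empty vector")
        if np.any(p < -_BELIEF_TOL):
            raise ValueError("belief entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("belief must sum to 1")
        self.probabilities = p / p.sum()

    @classmethod
    def uniform(cls, n: int) -> "Belief":
        return cls(np.full(n, 1.0 / n))


@dataclass
class PlayerSpec:
    """A player's generative parameters.

    ``guilt`` is the Fehr-Schmidt advantageous-inequity-aversion parameter
    (the player's type); ``envy`` is fixed to zero.  ``noise`` is the softmax
    inverse temperature in 1/dollar.  ``guilt`` may be ``None`` for nested
    partner models, whose type is what the enclosing belief ranges over.
    """

    role: str
    level: int
    guilt: float | None
    noise: float
    envy: float = 0.0
    prior: Belief | None = None
    #: a purely myopic agent evaluates single-round utility only (no
    #: lookahead, no partner simulation); used for the uncooperative
    #: trustee phenotype in simulation, never fit
    myopic: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("investor", "trustee"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.level not in (0, 1, 2):
            raise ValueError("level must be 0, 1 or 2")
        if self.guilt is not None and self.guilt < 0:
            raise ValueError("guilt must be non-negative")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if self.envy != 0.0:
            raise ValueError("envy is fixed to zero in this model")


@dataclass
class MyopicModel:
    """Terminal nested partner model: a belief about the player, nothing more."""

    belief: Belief


@dataclass
class RecursiveModelState:
    """A level-k player's full epistemic state at the start of a round.

    ``belief`` ranges over the partner's guilt types.  ``partner_model`` is
    the state of the simulated level-(k-1) partner (including that partner's
    belief about the player); at level 0 it is a :class:`MyopicModel`.
    """

    round_index: int
    self_spec: PlayerSpec
    belief: Belief
    partner_model: "RecursiveModelState | MyopicModel"

    def __post_init__(self) -> None:
        depth = 0
        node = self.partner_model
        while isinstance(node, RecursiveModelState):
            depth += 1
            node = node.partner_model
        if depth != self.self_spec.level:
            raise ValueError(
                f"recursion depth {depth} does not match level {self.self_spec.level}"
            )


@dataclass
class QTable:
    """Two-round expected utilities, keyed by own action (grid fraction).

    The null trustee action (zero investment) is keyed by ``None``.
    """

    values: dict[float | None, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def utility(own_money: float, other_money: float, guilt: float) -> float:
    """Inequity-averse utility: money minus guilt times advantageous inequity."""
    if guilt < 0:
        raise ValueError("guilt must be non-negative")
    return own_money - guilt * max(own_money - other_money, 0.0)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _bayes(prior: np.ndarray, like: np.ndarray) -> np.ndarray:
    """Normalized posterior ``prior * like`` along the last axis.

    Rows whose total likelihood vanishes fall back to the prior (off-model
    actions from discretized real data must not destroy the state).
    """
    post = prior * like
    tot = post.sum(axis=-1, keepdims=True)
    bad = tot <= 1e-300
    safe = np.where(bad, 1.0, tot)
    post = post / safe
    if np.any(bad):
        post = np.where(bad, np.broadcast_to(prior, post.shape), post)
    return post


def myopic_partner_policy(
    partner_guilt: float,
    pending_splits: list[tuple[float, float]],
    noise: float,
) -> np.ndarray:
    """Softmax over the partner's single-round utilities of each pending action.

    ``pending_splits`` lists ``(partner_money, own_money)`` for each action the
    partner could take this round.  With no legal action the distribution is
    the degenerate point mass on the null action.
    """
    if not pending_splits:
        return np.array([1.0])
    u = np.array(
        [utility(pm, om, partner_guilt) for pm, om in pending_splits], dtype=float
    )
    return _softmax(noise * u)


# ---------------------------------------------------------------------------
# the batched planning engine
# ---------------------------------------------------------------------------


class Engine:
    """Vectorized evaluator of the level-k model for one (config, noise) pair.

    All `q_*` methods accept belief arrays with arbitrary leading batch
    dimensions; type axes (length ``len(guilt_grid)``) are always last.
    Trustee-side methods carry an explicit investment axis (the trustee's
    value depends on the investment on the table) as the second-to-last
    batch axis of their inputs.
    """

    def __init__(self, config: GameConfig, noise: float):
        self.cfg = config
        self.tau = float(noise)
        self.T = config.num_rounds
        gI = np.asarray(config.investor_grid)
        gR = np.asarray(config.trustee_grid)
        G = np.asarray(config.guilt_grid)
        self.gI, self.gR, self.G = gI, gR, G
        self.nI, self.nR, self.nG = len(gI), len(gR), len(G)
        E, M = config.endowment, config.multiplier

        inv_money = E * (1 - gI)[:, None] + gR[None, :] * M * E * gI[:, None]
        tr_money = M * E * gI[:, None] * (1 - gR)[None, :]
        adv_inv = np.maximum(inv_money - tr_money, 0.0)
        adv_tr = np.maximum(tr_money - inv_money, 0.0)
        # U[g, i, r]: utility of the round for each own-guilt candidate
        self.U_inv = inv_money[None] - G[:, None, None] * adv_inv[None]
        self.U_tr = tr_money[None] - G[:, None, None] * adv_tr[None]

        self.zero_rows = np.abs(gI) <= FRAC_TOL  # investments with no trustee choice
        # myopic trustee policy (type, i, r); point mass on the null action
        # (represented at index 0) when the investment is zero
        P = _softmax(self.tau * self.U_tr, axis=-1)
        if self.zero_rows.any():
            P[:, self.zero_rows, :] = 0.0
            P[:, self.zero_rows, 0] = 1.0
        self.PmT = P
        self.maxUtr = self.U_tr.max(axis=-1)  # (g, i) trustee best response value
        # expected investor utility under a myopic trustee of each type
        self.Wm = np.einsum("tir,gir->tgi", self.PmT, self.U_inv)
        # myopic investor policy with a uniform belief about the trustee (g, i)
        self.Lmyo_unif = self.pol_m_inv(np.full(self.nG, 1.0 / self.nG))
        # likelihood of a repayment under the myopic trustee model, as
        # (i, r, type) for posterior updates
        self._likeR = self.PmT.transpose(1, 2, 0)

    # -- small helpers ------------------------------------------------------

    def _keep_prior_on_zero_rows(
        self, post: np.ndarray, prior: np.ndarray, i_axis_offset: int
    ) -> np.ndarray:
        """Undo belief-on-repayment updates for zero-investment rows.

        ``i_axis_offset`` is the (negative) position of the investment axis in
        ``post``; ``prior`` must broadcast against ``post``.
        """
        if not self.zero_rows.any():
            return post
        shape = [1] * post.ndim
        shape[i_axis_offset] = self.nI
        mask = self.zero_rows.reshape(shape)
        return np.where(mask, np.broadcast_to(prior, post.shape), post)

    def pol_m_inv(self, c: np.ndarray) -> np.ndarray:
        """Myopic investor policy (..., type_inv, i) given belief ``c`` (..., type_tr)."""
        eu = np.einsum("...t,tgi->...gi", c, self.Wm)
        return _softmax(self.tau * eu, axis=-1)

    def _trustee_policy(self, qtr: np.ndarray) -> np.ndarray:
        """Softmax over repayments of trustee Q values (..., i, g, r) ->
        per-type policy (..., i, g, r); zero-investment rows become the point
        mass on the null action."""
        P = _softmax(self.tau * qtr, axis=-1)
        if self.zero_rows.any():
            shape = [1] * P.ndim
            shape[-3] = self.nI
            mask = self.zero_rows.reshape(shape)
            point = np.zeros(self.nR)
            point[0] = 1.0
            P = np.where(mask, point, P)
        return P

    # -- level 0 ------------------------------------------------------------

    def q_inv0(self, b: np.ndarray, t: int) -> np.ndarray:
        """Level-0 investor values (..., own_guilt, i); ``b`` (..., type_tr)."""
        imm = np.einsum("...t,tgi->...gi", b, self.Wm)
        if t >= self.T:
            return imm
        Bp = _bayes(b[..., None, None, :], self._likeR)  # (..., i, r, type)
        Bp = self._keep_prior_on_zero_rows(Bp, b[..., None, None, :], -3)
        Qn = np.einsum("...irt,tgj->...irgj", Bp, self.Wm)
        V = Qn.max(axis=-1)  # (..., i, r, g)
        fut = np.einsum("...t,tir,...irg->...gi", b, self.PmT, V)
        return imm + fut

    def q_tr0(self, b: np.ndarray, c: np.ndarray, t: int) -> np.ndarray:
        """Level-0 trustee values (..., i, own_guilt, r).

        ``b`` (..., i, type_inv): belief about the investor, already updated on
        the investment; ``c`` (..., i, type_tr): the nested myopic investor
        model's belief about the trustee.
        """
        imm = self.U_tr.transpose(1, 0, 2)  # (i, g, r)
        if t >= self.T:
            shape = np.broadcast_shapes(b.shape[:-2], c.shape[:-2]) + imm.shape
            return np.broadcast_to(imm, shape)
        # the modeled investor sees the repayment r and updates its belief
        Cp = _bayes(c[..., :, None, :], self._likeR)  # (..., i, r, type_tr)
        Cp = self._keep_prior_on_zero_rows(Cp, c[..., :, None, :], -3)
        Pinv = self.pol_m_inv(Cp)  # (..., i, r, type_inv, j)
        fut = np.einsum("...it,...irtj,gj->...igr", b, Pinv, self.maxUtr)
        return imm + fut

    # -- level 1 ------------------------------------------------------------

    def q_inv1(
        self, b: np.ndarray, btr: np.ndarray, ctr: np.ndarray, t: int
    ) -> np.ndarray:
        """Level-1 investor values (..., own_guilt, i).

        ``b`` (..., type_tr): own belief; the nested level-0 trustee holds
        ``btr`` (..., type_inv) about the investor and its myopic investor
        model holds ``ctr`` (..., type_tr).
        """
        # nested trustee observes each candidate investment
        Lc = self.pol_m_inv(ctr)  # (..., type_inv, i)
        btr_i = _bayes(btr[..., None, :], np.moveaxis(Lc, -1, -2))  # (..., i, tI)
        ctr_i = np.broadcast_to(ctr[..., None, :], btr_i.shape[:-1] + (self.nG,))
        P1 = self._trustee_policy(self.q_tr0(btr_i, ctr_i, t))  # (..., i, tT, r)
        imm = np.einsum("...t,...itr,gir->...gi", b, P1, self.U_inv)
        if t >= self.T:
            return imm
        like = np.swapaxes(P1, -1, -2)  # (..., i, r, tT)
        Bp = _bayes(b[..., None, None, :], like)
        Bp = self._keep_prior_on_zero_rows(Bp, b[..., None, None, :], -3)
        # nested myopic investor model sees the repayment
        Ctr2 = _bayes(ctr[..., None, None, :], self._likeR)  # (..., i, r, tT)
        Ctr2 = self._keep_prior_on_zero_rows(Ctr2, ctr[..., None, None, :], -3)
        # next round: nested trustee observes each candidate next investment j
        Lc2 = self.pol_m_inv(Ctr2)  # (..., i, r, tI, j)
        btr2 = _bayes(btr_i[..., :, None, None, :], np.moveaxis(Lc2, -1, -2))
        # btr2: (..., i, r, j, tI)
        ctr2j = np.broadcast_to(Ctr2[..., :, :, None, :], btr2.shape)
        P1n = self._trustee_policy(self.q_tr0(btr2, ctr2j, t + 1))
        # P1n: (..., i, r, j, tT, r')
        Qn = np.einsum("...irt,...irjts,gjs->...irgj", Bp, P1n, self.U_inv)
        V = Qn.max(axis=-1)  # (..., i, r, g)
        fut = np.einsum("...t,...itr,...irg->...gi", b, P1, V)
        return imm + fut

    def q_tr1(
        self, b: np.ndarray, b0: np.ndarray, c0: np.ndarray, t: int
    ) -> np.ndarray:
        """Level-1 trustee values (..., i, own_guilt, r).

        ``b`` (..., i, type_inv): belief about the investor, updated on the
        investment.  The nested level-0 investor model holds ``b0``
        (..., i, type_tr) and a myopic trustee model with ``c0``
        (..., i, type_inv); ``c0`` does not enter the investor's own values.
        """
        imm = self.U_tr.transpose(1, 0, 2)
        if t >= self.T:
            shape = np.broadcast_shapes(b.shape[:-2], b0.shape[:-2]) + imm.shape
            return np.broadcast_to(imm, shape)
        # the modeled level-0 investor sees the repayment, then plans at t+1
        B0r = _bayes(b0[..., :, None, :], self._likeR)  # (..., i, r, tT)
        B0r = self._keep_prior_on_zero_rows(B0r, b0[..., :, None, :], -3)
        Pinv0 = _softmax(self.tau * self.q_inv0(B0r, t + 1), axis=-1)
        # Pinv0: (..., i, r, type_inv, j)
        fut = np.einsum("...it,...irtj,gj->...igr", b, Pinv0, self.maxUtr)
        return imm + fut

    # -- level 2 ------------------------------------------------------------

    def q_inv2(
        self,
        b: np.ndarray,
        b1: np.ndarray,
        b0: np.ndarray,
        c0: np.ndarray,
        t: int,
    ) -> np.ndarray:
        """Level-2 investor values (..., own_guilt, i).

        ``b`` (..., type_tr): own belief over the trustee.  The nested level-1
        trustee holds ``b1`` (..., type_inv); its nested level-0 investor
        model holds ``b0`` (..., type_tr) and ``c0`` (..., type_inv).
        """
        # nested level-1 trustee observes each candidate investment, using the
        # level-0 investor policy as its likelihood model
        P0now = _softmax(self.tau * self.q_inv0(b0, t), axis=-1)  # (..., tI, i)
        b1_i = _bayes(b1[..., None, :], np.moveaxis(P0now, -1, -2))  # (..., i, tI)
        c0_i = _bayes(c0[..., None, :], self.Lmyo_unif.T)  # (..., i, tI)
        b0_i = np.broadcast_to(b0[..., None, :], b1_i.shape[:-1] + (self.nG,))
        P2 = self._trustee_policy(self.q_tr1(b1_i, b0_i, c0_i, t))  # (..., i, tT, r)
        imm = np.einsum("...t,...itr,gir->...gi", b, P2, self.U_inv)
        if t >= self.T:
            return imm
        like = np.swapaxes(P2, -1, -2)
        Bp = _bayes(b[..., None, None, :], like)  # (..., i, r, tT)
        Bp = self._keep_prior_on_zero_rows(Bp, b[..., None, None, :], -3)
        # nested level-0 investor model sees the repayment
        B0r = _bayes(b0[..., None, None, :], self._likeR)  # (..., i, r, tT)
        B0r = self._keep_prior_on_zero_rows(B0r, b0[..., None, None, :], -3)
        # next round: level-1 trustee observes each candidate next investment
        P0next = _softmax(self.tau * self.q_inv0(B0r, t + 1), axis=-1)
        # P0next: (..., i, r, tI, j)
        b1_irj = _bayes(b1_i[..., :, None, None, :], np.moveaxis(P0next, -1, -2))
        # b1_irj: (..., i, r, j, tI)
        c0_irj = _bayes(c0_i[..., :, None, None, :], self.Lmyo_unif.T)
        c0_irj = np.broadcast_to(c0_irj, b1_irj.shape)
        b0_irj = np.broadcast_to(B0r[..., :, :, None, :], b1_irj.shape)
        P2n = self._trustee_policy(self.q_tr1(b1_irj, b0_irj, c0_irj, t + 1))
        # P2n: (..., i, r, j, tT, r')
        Qn = np.einsum("...irt,...irjts,gjs->...irgj", Bp, P2n, self.U_inv)
        V = Qn.max(axis=-1)
        fut = np.einsum("...t,...itr,...irg->...gi", b, P2, V)
        return imm + fut

    def q_tr2(
        self,
        b: np.ndarray,
        b1: np.ndarray,
        btr: np.ndarray,
        ctr: np.ndarray,
        t: int,
    ) -> np.ndarray:
        """Level-2 trustee values (..., i, own_guilt, r).

        ``b`` (..., i, type_inv): belief about the investor, updated on the
        investment.  The nested level-1 investor holds ``b1`` (..., i, type_tr)
        about the trustee, and its nested level-0 trustee model holds ``btr``
        (..., i, type_inv) with myopic-investor belief ``ctr`` (..., i, type_tr).
        """
        imm = self.U_tr.transpose(1, 0, 2)
        if t >= self.T:
            shape = np.broadcast_shapes(b.shape[:-2], b1.shape[:-2]) + imm.shape
            return np.broadcast_to(imm, shape)
        # the modeled level-1 investor sees the repayment ...
        P1 = self._trustee_policy(self.q_tr0(btr, ctr, t))  # (..., i, tT, r)
        b1r = _bayes(b1[..., :, None, :], np.swapaxes(P1, -1, -2))  # (..., i, r, tT)
        b1r = self._keep_prior_on_zero_rows(b1r, b1[..., :, None, :], -3)
        ctr_r = _bayes(ctr[..., :, None, :], self._likeR)
        ctr_r = self._keep_prior_on_zero_rows(ctr_r, ctr[..., :, None, :], -3)
        btr_r = np.broadcast_to(btr[..., :, None, :], b1r.shape)
        # ... and plans its next investment at t+1
        Pinv1 = _softmax(self.tau * self.q_inv1(b1r, btr_r, ctr_r, t + 1), axis=-1)
        # Pinv1: (..., i, r, type_inv, j)
        fut = np.einsum("...it,...irtj,gj->...igr", b, Pinv1, self.maxUtr)
        return imm + fut

    # -- dispatch on (role, level) ------------------------------------------

    def q_investor(self, level: int, arrays: tuple[np.ndarray, ...], t: int) -> np.ndarray:
        if level == 0:
            return self.q_inv0(arrays[0], t)
        if level == 1:
            return self.q_inv1(*arrays, t)
        return self.q_inv2(*arrays, t)

    def q_trustee(self, level: int, arrays: tuple[np.ndarray, ...], t: int) -> np.ndarray:
        """Trustee values for every candidate investment: (..., i, own_guilt, r)."""
        if level == 0:
            return self.q_tr0(*arrays, t)
        if level == 1:
            return self.q_tr1(*arrays, t)
        return self.q_tr2(*arrays, t)

    # -- state advancement on real observations -----------------------------
    #
    # Investor-owner states are flat tuples of belief vectors:
    #   level 0: (b, c)           level 1: (b, btr, ctr)
    #   level 2: (b, b1, b0, c0)
    # Trustee-owner states mirror them with roles swapped:
    #   level 0: (b, c)           level 1: (b, b0, c0)
    #   level 2: (b, b1, btr, ctr)

    def _full_i(self, a: np.ndarray) -> np.ndarray:
        """Broadcast a (type,) belief to the (i, type) layout trustee-side
        methods expect (named einsum axes do not broadcast)."""
        return np.broadcast_to(a, (self.nI, self.nG))

    def investor_trustee_policy(
        self, level: int, arrays: tuple[np.ndarray, ...], i_idx: int, t: int
    ) -> np.ndarray:
        """The trustee policy (type_tr, r) an investor attributes to the
        partner for investment ``i_idx``, with nested models having seen it."""
        if level == 0:
            return self.PmT[:, i_idx, :]
        adv = self.advance_investor_arrays_on_investment(level, arrays, i_idx, t)
        if level == 1:
            b, btr, ctr = adv
            qtr = self.q_tr0(self._full_i(btr), self._full_i(ctr), t)
        else:
            b, b1, b0, c0 = adv
            qtr = self.q_tr1(self._full_i(b1), self._full_i(b0), self._full_i(c0), t)
        return self._trustee_policy(qtr)[i_idx]

    def trustee_investor_policy(
        self, level: int, arrays: tuple[np.ndarray, ...], t: int
    ) -> np.ndarray:
        """The investor policy (type_inv, i) a trustee attributes to the partner."""
        if level == 0:
            b, c = arrays
            return self.pol_m_inv(c)
        if level == 1:
            b, b0, c0 = arrays
            return _softmax(self.tau * self.q_inv0(b0, t), axis=-1)
        b, b1, btr, ctr = arrays
        return _softmax(self.tau * self.q_inv1(b1, btr, ctr, t), axis=-1)

    def nested_investment_prediction(
        self, level: int, arrays: tuple[np.ndarray, ...], t: int
    ) -> np.ndarray:
        """The investor-side nested trustee model's predicted distribution of
        the investor's own next investment (second-order expectation)."""
        if level == 0:
            b, c = arrays
            return c @ self.Lmyo_unif
        if level == 1:
            b, btr, ctr = arrays
            return btr @ self.pol_m_inv(ctr)
        b, b1, b0, c0 = arrays
        P = _softmax(self.tau * self.q_inv0(b0, t), axis=-1)
        return b1 @ P

    def advance_investor_arrays_on_investment(
        self, level: int, arrays: tuple[np.ndarray, ...], i_idx: int, t: int
    ) -> tuple[np.ndarray, ...]:
        """Nested models of the trustee observe the investor's own action."""
        if level == 0:
            b, c = arrays
            return b, _bayes(c, self.Lmyo_unif[:, i_idx])
        if level == 1:
            b, btr, ctr = arrays
            like = self.pol_m_inv(ctr)[:, i_idx]
            return b, _bayes(btr, like), ctr
        b, b1, b0, c0 = arrays
        like = _softmax(self.tau * self.q_inv0(b0, t), axis=-1)[:, i_idx]
        return b, _bayes(b1, like), b0, _bayes(c0, self.Lmyo_unif[:, i_idx])

    def advance_investor_arrays_on_repayment(
        self,
        level: int,
        arrays: tuple[np.ndarray, ...],
        i_idx: int,
        r_idx: int | None,
        t: int,
    ) -> tuple[np.ndarray, ...]:
        """Own and nested beliefs update on the revealed repayment.

        ``arrays`` must already be advanced on the investment.  A zero
        investment (``r_idx`` None) reveals nothing about the trustee.
        """
        if r_idx is None or self.zero_rows[i_idx]:
            return arrays
        likeR = self.PmT[:, i_idx, r_idx]
        if level == 0:
            b, c = arrays
            return _bayes(b, likeR), c
        if level == 1:
            b, btr, ctr = arrays
            P = self._trustee_policy(self.q_tr0(self._full_i(btr), self._full_i(ctr), t))
            b = _bayes(b, P[i_idx, :, r_idx])
            return b, btr, _bayes(ctr, likeR)
        b, b1, b0, c0 = arrays
        P = self._trustee_policy(
            self.q_tr1(self._full_i(b1), self._full_i(b0), self._full_i(c0), t)
        )
        b = _bayes(b, P[i_idx, :, r_idx])
        return b, b1, _bayes(b0, likeR), c0

    def advance_trustee_arrays_on_investment(
        self, level: int, arrays: tuple[np.ndarray, ...], i_idx: int, t: int
    ) -> tuple[np.ndarray, ...]:
        """The trustee's belief about the investor updates on the investment;
        nested models of the investor register the action as their own."""
        like_self = self.trustee_investor_policy(level, arrays, t)[:, i_idx]
        if level == 0:
            b, c = arrays
            return _bayes(b, like_self), c
        if level == 1:
            b, b0, c0 = arrays
            return _bayes(b, like_self), b0, _bayes(c0, self.Lmyo_unif[:, i_idx])
        b, b1, btr, ctr = arrays
        nested_like = self.pol_m_inv(ctr)[:, i_idx]
        return _bayes(b, like_self), b1, _bayes(btr, nested_like), ctr

    def advance_trustee_arrays_on_repayment(
        self,
        level: int,
        arrays: tuple[np.ndarray, ...],
        i_idx: int,
        r_idx: int | None,
        t: int,
    ) -> tuple[np.ndarray, ...]:
        """Nested models of the investor observe the trustee's repayment."""
        if r_idx is None or self.zero_rows[i_idx]:
            return arrays
        likeR = self.PmT[:, i_idx, r_idx]
        if level == 0:
            b, c = arrays
            return b, _bayes(c, likeR)
        if level == 1:
            b, b0, c0 = arrays
            return b, _bayes(b0, likeR), c0
        b, b1, btr, ctr = arrays
        P = self._trustee_policy(self.q_tr0(self._full_i(btr), self._full_i(ctr), t))
        b1 = _bayes(b1, P[i_idx, :, r_idx])
        return b, b1, btr, _bayes(ctr, likeR)


_ENGINE_CACHE: dict[tuple[GameConfig, float], Engine] = {}


def get_engine(config: GameConfig, noise: float) -> Engine:
    key = (config, float(noise))
    eng = _ENGINE_CACHE.get(key)
    if eng is None:
        eng = _ENGINE_CACHE[key] = Engine(config, noise)
    return eng


# ---------------------------------------------------------------------------
# public state API (dataclass states over the engine)
# ---------------------------------------------------------------------------


def initial_state(
    role: str,
    level: int,
    config: GameConfig,
    noise: float,
    guilt: float | None = None,
    prior: Belief | None = None,
) -> RecursiveModelState:
    """A fresh round-1 state with uniform beliefs at every nesting depth."""
    n = len(config.guilt_grid)
    top = prior if prior is not None else Belief.uniform(n)

    def build(r: str, lv: int, bel: Belief, depth: int) -> RecursiveModelState:
        partner_role = "trustee" if r == "investor" else "investor"
        if lv == 0:
            nested: RecursiveModelState | MyopicModel = MyopicModel(Belief.uniform(n))
        else:
            nested = build(partner_role, lv - 1, Belief.uniform(n), depth + 1)
        return RecursiveModelState(
            round_index=1,
            self_spec=PlayerSpec(role=r, level=lv, guilt=guilt if depth == 0 else None,
                                 noise=noise),
            belief=bel,
            partner_model=nested,
        )

    return build(role, level, top, 0)


def _state_arrays(state: RecursiveModelState) -> tuple[np.ndarray, ...]:
    out = [np.asarray(state.belief.probabilities)]
    node = state.partner_model
    while isinstance(node, RecursiveModelState):
        out.append(np.asarray(node.belief.probabilities))
        node = node.partner_model
    out.append(np.asarray(node.belief.probabilities))
    return tuple(out)


def _rebuild_state(
    state: RecursiveModelState, arrays: tuple[np.ndarray, ...], round_index: int
) -> RecursiveModelState:
    def build(node, idx):
        if isinstance(node, MyopicModel):
            return MyopicModel(Belief(arrays[idx]))
        nested = build(node.partner_model, idx + 1)
        return RecursiveModelState(
            round_index=round_index,
            self_spec=node.self_spec,
            belief=Belief(arrays[idx]),
            partner_model=nested,
        )

    return build(state, 0)


def q_values(
    state: RecursiveModelState,
    config: GameConfig,
    investment_fraction: float | None = None,
) -> QTable:
    """Two-round action values for the state's owner at its current round.

    For a trustee the pending ``investment_fraction`` is required; a zero
    investment yields the degenerate table over the null action.
    """
    spec = state.self_spec
    if spec.guilt is None:
        raise ValueError("q_values requires a concrete guilt in self_spec")
    g_idx = config.grid_index(spec.guilt, config.guilt_grid)
    eng = get_engine(config, spec.noise)
    t = state.round_index
    if t > config.num_rounds:
        raise IndexError(f"round {t} is beyond the {config.num_rounds}-round game")
    arrays = _state_arrays(state)
    if spec.role == "investor":
        q = eng.q_investor(spec.level, arrays, t)[g_idx]
        return QTable(dict(zip(config.investor_grid, q.tolist())))
    if investment_fraction is None:
        raise ValueError("trustee q_values require the pending investment_fraction")
    i_idx = config.grid_index(investment_fraction, config.investor_grid)
    if eng.zero_rows[i_idx]:
        return QTable({None: 0.0})
    batched = tuple(eng._full_i(a) for a in arrays)
    q = eng.q_trustee(spec.level, batched, t)
    return QTable(dict(zip(config.trustee_grid, q[i_idx, g_idx].tolist())))


def action_distribution(qtable: QTable, noise: float) -> dict[float | None, float]:
    """Softmax choice probabilities over a Q table; invariant to value shifts."""
    if not qtable.values:
        raise ValueError("empty Q table")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    keys = list(qtable.values.keys())
    p = _softmax(noise * np.array([qtable.values[k] for k in keys], dtype=float))
    return dict(zip(keys, p.tolist()))


def partner_policy(
    level: int,
    partner_guilt: float,
    state: RecursiveModelState,
    config: GameConfig,
    investment_fraction: float | None = None,
) -> np.ndarray:
    """The action distribution the state's owner attributes to a partner of
    the given guilt type (simulated at one level below the owner).

    For an investor owner this is the modeled trustee's repayment
    distribution given the pending investment; for a trustee owner, the
    modeled investor's investment distribution.
    """
    if level != state.self_spec.level:
        raise ValueError("level does not match the state's recursion depth")
    eng = get_engine(config, state.self_spec.noise)
    g_idx = config.grid_index(partner_guilt, config.guilt_grid)
    arrays = _state_arrays(state)
    t = state.round_index
    if state.self_spec.role == "investor":
        if investment_fraction is None:
            raise ValueError("predicting a trustee requires investment_fraction")
        i_idx = config.grid_index(investment_fraction, config.investor_grid)
        return eng.investor_trustee_policy(level, arrays, i_idx, t)[g_idx]
    return eng.trustee_investor_policy(level, arrays, t)[g_idx]


def update_belief(
    belief: Belief,
    observed_partner_action: float | None,
    state: RecursiveModelState,
    config: GameConfig,
    investment_fraction: float | None = None,
) -> Belief:
    """Bayes update of a belief over partner types from an observed action.

    The likelihood of the action under each candidate type comes from the
    partner policy the state's owner simulates.  If every type assigns zero
    likelihood the prior is kept (with a warning): discretized real data can
    produce off-model actions.
    """
    eng = get_engine(config, state.self_spec.noise)
    arrays = _state_arrays(state)
    t = state.round_index
    prior = belief.probabilities
    if state.self_spec.role == "investor":
        if observed_partner_action is None:
            return Belief(prior.copy())  # zero-investment round: no evidence
        if investment_fraction is None:
            raise ValueError("updating on a repayment requires investment_fraction")
        i_idx = config.grid_index(investment_fraction, config.investor_grid)
        r_idx = config.grid_index(observed_partner_action, config.trustee_grid)
        like = eng.investor_trustee_policy(state.self_spec.level, arrays, i_idx, t)[
            :, r_idx
        ]
    else:
        i_idx = config.grid_index(observed_partner_action, config.investor_grid)
        like = eng.trustee_investor_policy(state.self_spec.level, arrays, t)[:, i_idx]
    if like.sum() <= 1e-300:
        warnings.warn("zero total likelihood for observed action; keeping prior")
    return Belief(_bayes(prior, like))


def advance_state(
    state: RecursiveModelState,
    investment_fraction: float,
    repayment_fraction: float | None,
    config: GameConfig,
) -> RecursiveModelState:
    """Advance a player's full epistemic state through one completed round.

    Applies the investment-observation update (the trustee side of the
    hierarchy learns about the investor) and then the repayment-observation
    update (the investor side learns about the trustee), at every nesting
    depth, and increments the round index.
    """
    spec = state.self_spec
    eng = get_engine(config, spec.noise)
    t = state.round_index
    i_idx = config.grid_index(investment_fraction, config.investor_grid)
    r_idx = (
        None
        if repayment_fraction is None
        else config.grid_index(repayment_fraction, config.trustee_grid)
    )
    arrays = _state_arrays(state)
    if spec.role == "investor":
        arrays = eng.advance_investor_arrays_on_investment(spec.level, arrays, i_idx, t)
        arrays = eng.advance_investor_arrays_on_repayment(
            spec.level, arrays, i_idx, r_idx, t
        )
    else:
        arrays = eng.advance_trustee_arrays_on_investment(spec.level, arrays, i_idx, t)
        arrays = eng.advance_trustee_arrays_on_repayment(
            spec.level, arrays, i_idx, r_idx, t
        )
    return _rebuild_state(state, arrays, t + 1)


def expected_repayment_distribution(
    state: RecursiveModelState, investment_fraction: float, config: GameConfig
) -> np.ndarray:
    """Belief-averaged modeled trustee repayment distribution for this round.

    Evaluated before the repayment is revealed, with nested models having
    seen the investment.  Used for the first-order interpersonal prediction
    error.
    """
    eng = get_engine(config, state.self_spec.noise)
    i_idx = config.grid_index(investment_fraction, config.investor_grid)
    arrays = _state_arrays(state)
    P = eng.investor_trustee_policy(
        state.self_spec.level, arrays, i_idx, state.round_index
    )
    return arrays[0] @ P


def expected_investment_distribution(
    state: RecursiveModelState, config: GameConfig
) -> np.ndarray:
    """The nested trustee model's prediction of the investor's investment.

    This is the "model of the partner's model of me" expectation underlying
    the second-order interpersonal prediction error, evaluated at submission
    time (before this round's actions).  Defined for every level: at level 0
    the nested myopic model predicts via the uniform-belief myopic investor
    policy.
    """
    spec = state.self_spec
    if spec.role != "investor":
        raise ValueError("second-order expectations are defined for investor states")
    eng = get_engine(config, spec.noise)
    return eng.nested_investment_prediction(
        spec.level, _state_arrays(state), state.round_index
    )
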