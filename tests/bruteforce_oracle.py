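"""Brute-force enumeration oracle for the level-k trust-game model.

An independent, unvectorized implementation used only by the test suite:
action values, modeled partner policies, belief updates and interpersonal
prediction errors are computed by explicit loops over the full two-round
game tree, with per-branch belief updates, using plain Python floats.

States are nested tuples:
    investor:  ("inv", level, belief, nested)
    trustee:   ("tr",  level, belief, nested)
    terminal:  ("myo", belief)
where beliefs are tuples over the guilt grid.  An investor's belief ranges
over trustee types and vice versa; the terminal myopic model's belief is
about the player the model belongs to.
"""

from __future__ import annotations

import math

from tomtrust.game import FRAC_TOL, GameConfig


def softmax(values, tau):
    m = max(values)
    e = [math.exp(tau * (v - m)) for v in values]
    s = sum(e)
    return [x / s for x in e]


def bayes(prior, like):
    post = [p * l for p, l in zip(prior, like)]
    s = sum(post)
    if s <= 1e-300:
        return tuple(prior)
    return tuple(p / s for p in post)


def uniform(n):
    return tuple(1.0 / n for _ in range(n))


def is_zero(cfg: GameConfig, i_idx: int) -> bool:
    return abs(cfg.investor_grid[i_idx]) <= FRAC_TOL


def money(cfg: GameConfig, i_idx: int, r_idx: int):
    I = cfg.investor_grid[i_idx]
    R = cfg.trustee_grid[r_idx]
    if is_zero(cfg, i_idx):
        return cfg.endowment, 0.0
    pot = cfg.multiplier * I * cfg.endowment
    return cfg.endowment * (1 - I) + R * pot, pot * (1 - R)


def util(own, other, beta):
    return own - beta * max(own - other, 0.0)


def u_inv(cfg, i_idx, r_idx, beta):
    mi, mt = money(cfg, i_idx, r_idx)
    return util(mi, mt, beta)


def u_tr(cfg, i_idx, r_idx, beta):
    mi, mt = money(cfg, i_idx, r_idx)
    return util(mt, mi, beta)


def myop_tr_policy(cfg, tau, theta, i_idx):
    nR = len(cfg.trustee_grid)
    if is_zero(cfg, i_idx):
        return [1.0] + [0.0] * (nR - 1)
    return softmax([u_tr(cfg, i_idx, r, theta) for r in range(nR)], tau)


def myop_inv_policy(cfg, tau, theta, c):
    nI = len(cfg.investor_grid)
    nR = len(cfg.trustee_grid)
    eu = []
    for i in range(nI):
        v = 0.0
        for ti, w in enumerate(c):
            pol = myop_tr_policy(cfg, tau, cfg.guilt_grid[ti], i)
            v += w * sum(pol[r] * u_inv(cfg, i, r, theta) for r in range(nR))
        eu.append(v)
    return softmax(eu, tau)


# ---------------------------------------------------------------------------
# state constructors and advancement
# ---------------------------------------------------------------------------


def initial_state(cfg, role, level):
    n = len(cfg.guilt_grid)
    tag = "inv" if role == "investor" else "tr"
    if level == 0:
        return (tag, 0, uniform(n), ("myo", uniform(n)))
    other = "trustee" if role == "investor" else "investor"
    return (tag, level, uniform(n), initial_state(cfg, other, level - 1))


def adv_inv_on_I(cfg, tau, st, i_idx, t):
    _, k, b, nested = st
    if k == 0:
        c = nested[1]
        like = [myop_inv_policy(cfg, tau, cfg.guilt_grid[g], uniform(len(c)))[i_idx]
                for g in range(len(c))]
        return ("inv", 0, b, ("myo", bayes(c, like)))
    return ("inv", k, b, adv_tr_on_I(cfg, tau, nested, i_idx, t))


def adv_inv_on_R(cfg, tau, st, i_idx, r_idx, t):
    """Own belief and nested models update on the repayment; the state must
    already be advanced on the investment."""
    _, k, b, nested = st
    if r_idx is None or is_zero(cfg, i_idx):
        return st
    like = [
        trustee_policy(cfg, tau, k - 1, cfg.guilt_grid[g], nested, i_idx, t)[r_idx]
        for g in range(len(b))
    ]
    b2 = bayes(b, like)
    if k == 0:
        return ("inv", 0, b2, nested)
    return ("inv", k, b2, adv_tr_on_R(cfg, tau, nested, i_idx, r_idx, t))


def adv_tr_on_I(cfg, tau, st, i_idx, t):
    _, k, b, nested = st
    if k == 0:
        c = nested[1]
        like = [myop_inv_policy(cfg, tau, cfg.guilt_grid[g], c)[i_idx]
                for g in range(len(b))]
        return ("tr", 0, bayes(b, like), nested)
    like = [
        investor_policy(cfg, tau, k - 1, cfg.guilt_grid[g], nested, t)[i_idx]
        for g in range(len(b))
    ]
    return ("tr", k, bayes(b, like), adv_inv_on_I(cfg, tau, nested, i_idx, t))


def adv_tr_on_R(cfg, tau, st, i_idx, r_idx, t):
    _, k, b, nested = st
    if r_idx is None or is_zero(cfg, i_idx):
        return st
    if k == 0:
        c = nested[1]
        like = [myop_tr_policy(cfg, tau, cfg.guilt_grid[g], i_idx)[r_idx]
                for g in range(len(c))]
        return ("tr", 0, b, ("myo", bayes(c, like)))
    return ("tr", k, b, adv_inv_on_R(cfg, tau, nested, i_idx, r_idx, t))


def advance_round(cfg, tau, st, i_idx, r_idx, t):
    """Both observations of one completed round, in play order."""
    if st[0] == "inv":
        st = adv_inv_on_I(cfg, tau, st, i_idx, t)
        return adv_inv_on_R(cfg, tau, st, i_idx, r_idx, t)
    st = adv_tr_on_I(cfg, tau, st, i_idx, t)
    return adv_tr_on_R(cfg, tau, st, i_idx, r_idx, t)


# ---------------------------------------------------------------------------
# modeled policies and action values
# ---------------------------------------------------------------------------


def trustee_policy(cfg, tau, modeled_level, theta, state, i_idx, t):
    """Policy attributed to a trustee of type ``theta``; ``modeled_level`` -1
    means the myopic terminator, otherwise ``state`` is the modeled trustee's
    ("tr", level, ...) state already advanced on the investment."""
    nR = len(cfg.trustee_grid)
    if is_zero(cfg, i_idx):
        return [1.0] + [0.0] * (nR - 1)
    if modeled_level < 0:
        return myop_tr_policy(cfg, tau, theta, i_idx)
    return softmax(q_trustee(cfg, tau, theta, state, i_idx, t), tau)


def investor_policy(cfg, tau, modeled_level, theta, state, t):
    """Policy attributed to an investor of type ``theta``; ``modeled_level``
    -1 means myopic with the ("myo", c) model's belief."""
    if modeled_level < 0:
        return myop_inv_policy(cfg, tau, theta, state[1])
    return softmax(q_investor(cfg, tau, theta, state, t), tau)


def q_investor(cfg, tau, beta, st, t):
    """Two-round action values of the investor whose state is ``st``."""
    _, k, b, nested = st
    nI, nR = len(cfg.investor_grid), len(cfg.trustee_grid)
    T = cfg.num_rounds
    Q = []
    for i in range(nI):
        nested_i = (
            adv_tr_on_I(cfg, tau, nested, i, t) if k >= 1 else nested
        )
        pols = [
            trustee_policy(cfg, tau, k - 1, cfg.guilt_grid[g], nested_i, i, t)
            for g in range(len(b))
        ]
        val = 0.0
        for r in range(nR):
            if t < T:
                if is_zero(cfg, i):
                    b_ir, nested_ir = b, nested_i
                else:
                    b_ir = bayes(b, [pols[g][r] for g in range(len(b))])
                    nested_ir = (
                        adv_tr_on_R(cfg, tau, nested_i, i, r, t)
                        if k >= 1
                        else nested_i
                    )
                v_next = max(
                    _terminal_inv_value(cfg, tau, beta, k, b_ir, nested_ir, j, t + 1)
                    for j in range(nI)
                )
            else:
                v_next = 0.0
            for g in range(len(b)):
                val += b[g] * pols[g][r] * (u_inv(cfg, i, r, beta) + v_next)
        Q.append(val)
    return Q


def _terminal_inv_value(cfg, tau, beta, k, b, nested, j, t):
    """Expected immediate utility of investing ``j`` at the lookahead's second
    step, under the modeled trustee policy with beliefs carried forward."""
    nested_j = adv_tr_on_I(cfg, tau, nested, j, t) if k >= 1 else nested
    v = 0.0
    for g in range(len(b)):
        pol = trustee_policy(cfg, tau, k - 1, cfg.guilt_grid[g], nested_j, j, t)
        for r in range(len(cfg.trustee_grid)):
            v += b[g] * pol[r] * u_inv(cfg, j, r, beta)
    return v


def q_trustee(cfg, tau, beta, st, i_idx, t):
    """Two-round action values of the trustee whose state is ``st`` (already
    advanced on the observed investment)."""
    _, k, b, nested = st
    nI, nR = len(cfg.investor_grid), len(cfg.trustee_grid)
    T = cfg.num_rounds
    Q = []
    for r in range(nR):
        val = u_tr(cfg, i_idx, r, beta)
        if t < T:
            st_r = adv_tr_on_R(cfg, tau, st, i_idx, r, t)
            nested_r = st_r[3]
            for g in range(len(b)):
                if k == 0:
                    pol = myop_inv_policy(cfg, tau, cfg.guilt_grid[g], nested_r[1])
                else:
                    pol = investor_policy(
                        cfg, tau, k - 1, cfg.guilt_grid[g], nested_r, t + 1
                    )
                for j in range(nI):
                    best = max(u_tr(cfg, j, rr, beta) for rr in range(nR))
                    val += b[g] * pol[j] * best
        Q.append(val)
    return Q


# ---------------------------------------------------------------------------
# interpersonal prediction errors
# ---------------------------------------------------------------------------


def pe1(cfg, tau, st, i_idx, r_idx, t):
    """Observed repayment fraction minus the belief-averaged modeled
    expectation, at repayment reveal."""
    if is_zero(cfg, i_idx):
        return None
    _, k, b, nested = st
    nested_i = adv_tr_on_I(cfg, tau, nested, i_idx, t) if k >= 1 else nested
    exp = 0.0
    for g in range(len(b)):
        pol = trustee_policy(cfg, tau, k - 1, cfg.guilt_grid[g], nested_i, i_idx, t)
        exp += b[g] * sum(p * f for p, f in zip(pol, cfg.trustee_grid))
    return cfg.trustee_grid[r_idx] - exp


def pe2(cfg, tau, st, i_idx, t):
    """Observed investment fraction minus the nested trustee model's
    expectation of it, at submission."""
    _, k, b, nested = st
    exp = 0.0
    if k == 0:
        c = nested[1]
        for g in range(len(c)):
            pol = myop_inv_policy(cfg, tau, cfg.guilt_grid[g], uniform(len(c)))
            exp += c[g] * sum(p * f for p, f in zip(pol, cfg.investor_grid))
    else:
        _, km1, btr, inner = nested
        for g in range(len(btr)):
            pol = investor_policy(cfg, tau, km1 - 1, cfg.guilt_grid[g], inner, t)
            exp += btr[g] * sum(p * f for p, f in zip(pol, cfg.investor_grid))
    return cfg.investor_grid[i_idx] - exp
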