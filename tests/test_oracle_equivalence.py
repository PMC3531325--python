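"""The vectorized planning engine must agree with the brute-force tree
enumerator on every small game, level, role and reachable state."""

import numpy as np
import pytest

import bruteforce_oracle as oracle
from tomtrust.game import FRAC_TOL
from tomtrust.model import (
    action_distribution,
    advance_state,
    get_engine,
    initial_state,
    partner_policy,
    q_values,
)
from tomtrust.prediction_errors import first_order_pe, second_order_pe

TOL = 1e-10


def _oracle_states_match(cfg, tau, eng_state, orc_state):
    """Walk both nested states and compare every belief vector."""
    from tomtrust.model import MyopicModel, _state_arrays

    arrays = _state_arrays(eng_state)
    node = orc_state
    beliefs = []
    while node[0] != "myo":
        beliefs.append(node[2])
        node = node[3]
    beliefs.append(node[1])
    assert len(arrays) == len(beliefs)
    for a, b in zip(arrays, beliefs):
        np.testing.assert_allclose(a, np.array(b), atol=TOL)


def _observation_sequences(cfg, n_rounds):
    """A deterministic spread of (investment, repayment) observations."""
    nI, nR = len(cfg.investor_grid), len(cfg.trustee_grid)
    seqs = [[]]
    picks = [(0, 0), (nI - 1, nR - 1), (nI - 1, 0), (nI // 2, nR // 2)]
    for i_idx, r_idx in picks[: max(1, n_rounds)]:
        r = None if abs(cfg.investor_grid[i_idx]) <= FRAC_TOL else r_idx
        seqs.append(seqs[-1] + [(i_idx, r)])
    return [s for s in seqs if len(s) < cfg.num_rounds]


@pytest.mark.parametrize("level", [0, 1, 2])
def test_investor_values_match_enumeration(toy_configs, level):
    for cfg in toy_configs:
        tau = cfg.noise_grid[0]
        for obs in _observation_sequences(cfg, cfg.num_rounds):
            st = initial_state("investor", level, cfg, tau, guilt=cfg.guilt_grid[0])
            ost = oracle.initial_state(cfg, "investor", level)
            for t, (i_idx, r_idx) in enumerate(obs, start=1):
                st = advance_state(
                    st,
                    cfg.investor_grid[i_idx],
                    None if r_idx is None else cfg.trustee_grid[r_idx],
                    cfg,
                )
                ost = oracle.advance_round(cfg, tau, ost, i_idx, r_idx, t)
            _oracle_states_match(cfg, tau, st, ost)
            t = len(obs) + 1
            for g in cfg.guilt_grid:
                st.self_spec.guilt = g
                q = q_values(st, cfg)
                expected = oracle.q_investor(cfg, tau, g, ost, t)
                np.testing.assert_allclose(
                    [q.values[f] for f in cfg.investor_grid], expected, atol=TOL
                )


@pytest.mark.parametrize("level", [0, 1, 2])
def test_trustee_values_match_enumeration(toy_configs, level):
    for cfg in toy_configs:
        tau = cfg.noise_grid[0]
        for obs in _observation_sequences(cfg, cfg.num_rounds):
            st = initial_state("trustee", level, cfg, tau, guilt=cfg.guilt_grid[0])
            ost = oracle.initial_state(cfg, "trustee", level)
            for t, (i_idx, r_idx) in enumerate(obs, start=1):
                st = advance_state(
                    st,
                    cfg.investor_grid[i_idx],
                    None if r_idx is None else cfg.trustee_grid[r_idx],
                    cfg,
                )
                ost = oracle.advance_round(cfg, tau, ost, i_idx, r_idx, t)
            _oracle_states_match(cfg, tau, st, ost)
            t = len(obs) + 1
            for i_idx, inv in enumerate(cfg.investor_grid):
                if abs(inv) <= FRAC_TOL:
                    continue
                # the trustee sees the investment before choosing
                from tomtrust.model import _rebuild_state, _state_arrays

                eng = get_engine(cfg, tau)
                arrays = eng.advance_trustee_arrays_on_investment(
                    level, _state_arrays(st), i_idx, t
                )
                st_i = _rebuild_state(st, arrays, t)
                st_i = _set_round(st_i, t)
                ost_i = oracle.adv_tr_on_I(cfg, tau, ost, i_idx, t)
                for g in cfg.guilt_grid:
                    st_i.self_spec.guilt = g
                    q = q_values(st_i, cfg, investment_fraction=inv)
                    expected = oracle.q_trustee(cfg, tau, g, ost_i, i_idx, t)
                    np.testing.assert_allclose(
                        [q.values[f] for f in cfg.trustee_grid], expected, atol=TOL
                    )


def _set_round(state, t):
    state.round_index = t
    node = state.partner_model
    while hasattr(node, "round_index"):
        node.round_index = t
        node = node.partner_model
    return state


@pytest.mark.parametrize("level", [0, 1, 2])
def test_modeled_partner_policies_match_enumeration(toy_configs, level):
    for cfg in toy_configs:
        tau = cfg.noise_grid[0]
        st = initial_state("investor", level, cfg, tau, guilt=cfg.guilt_grid[0])
        ost = oracle.initial_state(cfg, "investor", level)
        for i_idx, inv in enumerate(cfg.investor_grid):
            if abs(inv) <= FRAC_TOL:
                continue
            nested_i = (
                oracle.adv_tr_on_I(cfg, tau, ost[3], i_idx, 1)
                if level >= 1
                else ost[3]
            )
            for g in cfg.guilt_grid:
                got = partner_policy(level, g, st, cfg, investment_fraction=inv)
                expected = oracle.trustee_policy(
                    cfg, tau, level - 1, g, nested_i, i_idx, 1
                )
                np.testing.assert_allclose(got, expected, atol=TOL)

        st_t = initial_state("trustee", level, cfg, tau, guilt=cfg.guilt_grid[0])
        ost_t = oracle.initial_state(cfg, "trustee", level)
        for g in cfg.guilt_grid:
            got = partner_policy(level, g, st_t, cfg)
            if level == 0:
                expected = oracle.myop_inv_policy(cfg, tau, g, ost_t[3][1])
            else:
                expected = oracle.investor_policy(cfg, tau, level - 1, g, ost_t[3], 1)
            np.testing.assert_allclose(got, expected, atol=TOL)


@pytest.mark.parametrize("level", [0, 1, 2])
def test_prediction_errors_match_enumeration(toy_configs, level):
    for cfg in toy_configs:
        tau = cfg.noise_grid[0]
        for obs in _observation_sequences(cfg, cfg.num_rounds):
            st = initial_state("investor", level, cfg, tau, guilt=cfg.guilt_grid[0])
            ost = oracle.initial_state(cfg, "investor", level)
            for t, (i_idx, r_idx) in enumerate(obs, start=1):
                st = advance_state(
                    st,
                    cfg.investor_grid[i_idx],
                    None if r_idx is None else cfg.trustee_grid[r_idx],
                    cfg,
                )
                ost = oracle.advance_round(cfg, tau, ost, i_idx, r_idx, t)
            t = len(obs) + 1
            for i_idx, inv in enumerate(cfg.investor_grid):
                got2 = second_order_pe(st, inv, cfg)
                exp2 = oracle.pe2(cfg, tau, ost, i_idx, t)
                assert got2 == pytest.approx(exp2, abs=TOL)
                if abs(inv) <= FRAC_TOL:
                    continue
                for r_idx, rep in enumerate(cfg.trustee_grid):
                    got1 = first_order_pe(st, inv, rep, cfg)
                    exp1 = oracle.pe1(cfg, tau, ost, i_idx, r_idx, t)
                    assert got1 == pytest.approx(exp1, abs=TOL)


def test_zero_noise_gives_uniform_choice(toy_configs):
    cfg = toy_configs[0]
    st = initial_state("investor", 1, cfg, 0.0, guilt=cfg.guilt_grid[0])
    q = q_values(st, cfg)
    dist = action_distribution(q, 0.0)
    np.testing.assert_allclose(
        list(dist.values()), np.full(len(cfg.investor_grid), 1 / len(cfg.investor_grid))
    )
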