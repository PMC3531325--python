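import math

import numpy as np
import pytest

from tomtrust.game import GameConfig
from tomtrust.model import (
    Belief,
    QTable,
    action_distribution,
    advance_state,
    get_engine,
    initial_state,
    myopic_partner_policy,
    q_values,
    update_belief,
    utility,
)


@pytest.mark.parametrize(
    "own,other,guilt,expected",
    [(25, 15, 0.0, 25.0), (25, 15, 0.5, 20.0), (15, 25, 0.5, 15.0)],
)
def test_utility_guilt_only(own, other, guilt, expected):
    """Guilt penalizes advantageous inequity; envy is fixed to zero."""
    assert utility(own, other, guilt) == expected


def test_utility_rejects_negative_guilt():
    with pytest.raises(ValueError):
        utility(10, 10, -0.1)


def test_myopic_policy_limits_and_hand_softmax():
    # trustee holding $60 (full investment), guilt 1.0, default grid
    cfg = GameConfig()
    splits = []
    for rep in cfg.trustee_grid:
        tr = 60 * (1 - rep)
        inv = 60 * rep  # investor kept nothing
        splits.append((tr, inv))
    # tau=0: uniform
    np.testing.assert_allclose(
        myopic_partner_policy(1.0, splits, 0.0), np.full(5, 0.2)
    )
    # tau=1: hand-computed softmax of the five utilities
    utils = [tr - 1.0 * max(tr - inv, 0.0) for tr, inv in splits]
    e = np.exp(np.array(utils) - max(utils))
    np.testing.assert_allclose(
        myopic_partner_policy(1.0, splits, 1.0), e / e.sum(), atol=1e-12
    )
    # near-greedy limit: point mass on the even split (the maximizer)
    p = myopic_partner_policy(1.0, splits, 50.0)
    assert np.argmax(p) == int(np.argmax(utils))
    assert p[np.argmax(p)] > 0.999


def test_guilt_monotonicity_of_even_split(config):
    """More trustee guilt never lowers the myopic probability of the even
    split when it is the high-guilt maximizer (default grids, full pot)."""
    eng = get_engine(config, 1.0)
    i_idx = len(config.investor_grid) - 1
    even = config.trustee_grid.index(0.5)
    probs = eng.PmT[:, i_idx, even]
    assert np.all(np.diff(probs) >= -1e-12)


def test_action_distribution_shift_invariance():
    q = QTable({0.0: 1.0, 0.5: 2.0, 1.0: 3.0})
    q_shift = QTable({k: v + 7.0 for k, v in q.values.items()})
    d1 = action_distribution(q, 1.3)
    d2 = action_distribution(q_shift, 1.3)
    for k in q.values:
        assert d1[k] == pytest.approx(d2[k], abs=1e-12)
    # equal Q values: uniform at any noise
    d3 = action_distribution(QTable({0.0: 4.0, 1.0: 4.0}), 9.0)
    assert d3[0.0] == pytest.approx(0.5)


def test_update_belief_hand_bayes(config):
    """Posterior proportional to prior times likelihood on a 2-type grid."""
    cfg = GameConfig(guilt_grid=(0.0, 1.0), noise_grid=(1.0,))
    st = initial_state("investor", 0, cfg, 1.0, guilt=0.0)
    eng = get_engine(cfg, 1.0)
    i_idx, r_idx = 2, 1
    like = eng.PmT[:, i_idx, r_idx]
    prior = Belief(np.array([0.5, 0.5]))
    post = update_belief(
        prior, cfg.trustee_grid[r_idx], st, cfg,
        investment_fraction=cfg.investor_grid[i_idx],
    )
    expected = prior.probabilities * like
    expected /= expected.sum()
    np.testing.assert_allclose(post.probabilities, expected, atol=1e-12)
    # uniform likelihood keeps a uniform posterior
    st0 = initial_state("investor", 0, cfg, 0.0, guilt=0.0)
    post0 = update_belief(
        prior, cfg.trustee_grid[r_idx], st0, cfg,
        investment_fraction=cfg.investor_grid[i_idx],
    )
    np.testing.assert_allclose(post0.probabilities, [0.5, 0.5], atol=1e-12)


def test_beliefs_stay_normalized_through_play(config):
    """Every belief at every nesting depth remains a distribution as a game
    is advanced through arbitrary observations."""
    from tomtrust.model import _state_arrays

    rng = np.random.default_rng(7)
    for level in (0, 1, 2):
        st = initial_state("investor", level, config, 2.0, guilt=0.4)
        for t in range(1, config.num_rounds + 1):
            inv = float(rng.choice(config.investor_grid))
            rep = None if inv == 0 else float(rng.choice(config.trustee_grid))
            st = advance_state(st, inv, rep, config)
            for arr in _state_arrays(st):
                assert np.all(arr >= -1e-12)
                assert arr.sum() == pytest.approx(1.0, abs=1e-9)


def test_last_round_values_are_immediate_only(config):
    """In the final round the future term vanishes: the Q table equals the
    expected single-round utility under the believed partner policy."""
    eng = get_engine(config, 1.0)
    for level in (0, 1, 2):
        st = initial_state("investor", level, config, 1.0, guilt=0.4)
        st.round_index = config.num_rounds
        node = st.partner_model
        while hasattr(node, "round_index"):
            node.round_index = config.num_rounds
            node = node.partner_model
        q = q_values(st, config)
        from tomtrust.model import _state_arrays

        arrays = _state_arrays(st)
        g_idx = config.guilt_grid.index(0.4)
        b = arrays[0]
        expected = []
        for i_idx, frac in enumerate(config.investor_grid):
            P = eng.investor_trustee_policy(level, arrays, i_idx, config.num_rounds)
            eu = b @ (P * eng.U_inv[g_idx, i_idx, :]).sum(axis=1)
            expected.append(eu)
        np.testing.assert_allclose(
            [q.values[f] for f in config.investor_grid], expected, atol=1e-9
        )


def test_q_values_rejects_rounds_beyond_game(config):
    st = initial_state("investor", 0, config, 1.0, guilt=0.0)
    st.round_index = config.num_rounds + 1
    with pytest.raises(IndexError):
        q_values(st, config)
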