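import numpy as np
import pytest

from tomtrust.game import GameConfig
from tomtrust.model import PlayerSpec, initial_state
from tomtrust.prediction_errors import (
    extract_pe_series,
    first_order_pe,
    high_low_contrast,
    membership_audit,
    quintile_split,
    second_order_pe,
)
from tomtrust.simulate import CohortSpec, generate_cohort, simulate_dyad


@pytest.fixture(scope="module")
def cfg():
    return GameConfig()


def test_pe_zero_when_expectation_matches_observation(cfg):
    """Playing exactly the modeled expectation yields a zero error, and the
    sign convention is observed-minus-expected."""
    from tomtrust.model import expected_investment_distribution
    from tomtrust.prediction_errors import expected_repayment_distribution

    st = initial_state("investor", 1, cfg, 1.0, guilt=0.4)
    gR = np.asarray(cfg.trustee_grid)
    gI = np.asarray(cfg.investor_grid)
    exp_r = float(expected_repayment_distribution(st, 0.5, cfg) @ gR)
    pe = first_order_pe(st, 0.5, exp_r if exp_r in gR else None, cfg)
    # use the exact expectation as a synthetic observation
    got = first_order_pe(st, 0.5, exp_r, cfg)
    assert got == pytest.approx(0.0, abs=1e-12)
    got_hi = first_order_pe(st, 0.5, exp_r + 0.1, cfg)
    assert got_hi == pytest.approx(0.1, abs=1e-12)

    exp_i = float(expected_investment_distribution(st, cfg) @ gI)
    assert second_order_pe(st, exp_i, cfg) == pytest.approx(0.0, abs=1e-12)
    assert second_order_pe(st, exp_i + 0.25, cfg) == pytest.approx(0.25, abs=1e-12)


def test_pe1_null_on_zero_investment(cfg):
    st = initial_state("investor", 0, cfg, 1.0, guilt=0.0)
    assert first_order_pe(st, 0.0, None, cfg) is None


def test_pe_antisymmetry(cfg):
    """Swapping observed and expected flips the error's sign."""
    st = initial_state("investor", 2, cfg, 1.0, guilt=0.4)
    a = first_order_pe(st, 0.75, 2.0 / 3.0, cfg)
    from tomtrust.prediction_errors import expected_repayment_distribution

    exp = float(
        expected_repayment_distribution(st, 0.75, cfg) @ np.asarray(cfg.trustee_grid)
    )
    assert a == pytest.approx((2.0 / 3.0) - exp)
    # reversing roles of observation and expectation negates the error
    assert -(exp - 2.0 / 3.0) == pytest.approx(a)


def test_pe_bounds_on_simulated_play(cfg):
    spec = CohortSpec(n_dyads=5, seed=3)
    hs, traces = generate_cohort(spec, cfg, return_details=True)
    for h, tr in zip(hs, traces):
        series = extract_pe_series(
            h, tr.investor_spec.level, tr.investor_spec.noise, cfg,
            tr.investor_spec.guilt,
        )
        for v in series.pe1:
            if v is not None:
                assert abs(v) <= max(cfg.trustee_grid) + 1e-9
        for v in series.pe2:
            assert abs(v) <= max(cfg.investor_grid) + 1e-9
        # the replayed series must match the generative trace exactly
        for t, rec in enumerate(tr.rounds):
            if rec["pe1"] is None:
                assert series.pe1[t] is None
            else:
                assert series.pe1[t] == pytest.approx(rec["pe1"], abs=1e-9)
            assert series.pe2[t] == pytest.approx(rec["pe2"], abs=1e-9)


def test_pe_series_percent_units(cfg):
    spec = CohortSpec(n_dyads=1, seed=8)
    (h,), (tr,) = generate_cohort(spec, cfg, return_details=True)
    s = extract_pe_series(h, tr.investor_spec.level, tr.investor_spec.noise, cfg,
                          tr.investor_spec.guilt)
    p = s.as_percent()
    assert p.units == "percent"
    for a, b in zip(s.pe2, p.pe2):
        assert b == pytest.approx(100 * a)


def test_quintile_split_distinct_values():
    labels = quintile_split(np.arange(1, 11))
    assert sorted(np.where(labels.group == "high")[0].tolist()) == [6, 7, 8, 9]
    assert sorted(np.where(labels.group == "low")[0].tolist()) == [0, 1, 2, 3]
    assert sorted(np.where(labels.group == "mid")[0].tolist()) == [4, 5]
    # exact 20% occupancy when n divisible by 5 and values distinct
    v = np.random.default_rng(0).permutation(100)
    q = quintile_split(v).quintile
    assert all((q == k).sum() == 20 for k in range(1, 6))


def test_quintile_split_tie_rules():
    # all equal: wholly mid
    labels = quintile_split(np.ones(10))
    assert set(labels.group) == {"mid"}
    # a tied block straddling the 40th percentile goes to the lower bin
    v = np.array([1, 2, 3, 4, 4, 4, 7, 8, 9, 10], dtype=float)
    labels = quintile_split(v)
    assert set(labels.group[3:6]) == {"low"}


def test_quintile_split_needs_five_values():
    with pytest.raises(ValueError):
        quintile_split([1.0, 2.0, 3.0])


def test_membership_audit_counts():
    v = np.arange(1, 11, dtype=float)
    # subject A contributes to both tails; subject B only to the high group
    sids = np.array(["A", "A", "A", "A", "A", "A", "B", "B", "A", "A"])
    labels = quintile_split(v, sids)
    audit = membership_audit(labels)
    assert audit["both"] == 1 and audit["only_high"] == 1
    assert audit["total"] == 2


def test_high_low_contrast_arithmetic():
    v = np.arange(1, 11, dtype=float)
    labels = quintile_split(v)
    diff, se = high_low_contrast(v, labels)
    assert diff == pytest.approx(8.5 - 2.5)
    assert se > 0
    same = np.array([5.0, 5.0, 5.0, 5.0])
    labels2 = quintile_split(np.arange(1, 9, dtype=float))
    d2, _ = high_low_contrast(np.ones(8), labels2)
    assert d2 == pytest.approx(0.0)


def test_converged_belief_pe1_centers_on_zero(cfg):
    """Against a fixed trustee type, the investor's average first-order error
    shrinks toward zero as beliefs converge (Monte-Carlo, 3*SE band)."""
    vals = []
    rng = np.random.default_rng(12)
    for k in range(40):
        inv = PlayerSpec("investor", 0, 0.4, 1.0)
        tr = PlayerSpec("trustee", 0, 1.0, 1.0)
        h, trace = simulate_dyad(inv, tr, cfg, rng, f"d{k}")
        for rec in trace.rounds[5:]:  # after beliefs have converged somewhat
            if rec["pe1"] is not None:
                vals.append(rec["pe1"])
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) <= 3 * se + 0.02
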