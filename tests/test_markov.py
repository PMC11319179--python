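"""Cohort engine against closed forms, trapezoid and matrix-geometric oracles,
plus microsimulation consistency."""

import numpy as np
import pytest

from screencea.markov import (
    arm_expected_outcome,
    discount_factor,
    evaluate_setting,
    half_cycle_correct,
    run_cohort,
    run_microsimulation,
    run_strategy,
)
from screencea.params import TransitionTable
from screencea.paths import set_param, set_params
from screencea.screening import classify
from screencea.states import STATE_INDEX, HealthState


# ---------------------------------------------------------------------------
# Discounting and half-cycle correction
# ---------------------------------------------------------------------------


def test_discount_factor_values():
    assert discount_factor(0.0, 7) == 1.0
    assert discount_factor(0.05, 1) == pytest.approx(0.952381, abs=1e-6)
    assert discount_factor(0.05, 10) == pytest.approx(1.05**-10, abs=1e-12)
    with pytest.raises(ValueError):
        discount_factor(-0.01, 1)
    with pytest.raises(ValueError):
        discount_factor(0.05, -1)


def test_half_cycle_constant_trace_unchanged():
    occ = np.tile([0.3, 0.7], (5, 1))
    assert np.allclose(half_cycle_correct(occ), occ[:-1])


def test_half_cycle_midpoint():
    occ = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert np.allclose(half_cycle_correct(occ), [[0.5, 0.5]])


def test_half_cycle_single_row_warns():
    occ = np.array([[1.0, 0.0]])
    with pytest.warns(UserWarning):
        out = half_cycle_correct(occ)
    assert np.allclose(out, occ)


def test_half_cycle_equals_trapezoid_oracle():
    rng = np.random.default_rng(7)
    occ = rng.dirichlet(np.ones(4), size=12)
    values = rng.uniform(0, 5, size=4)
    total = (half_cycle_correct(occ) @ values).sum()
    oracle = np.trapezoid(occ @ values)  # trapezoid rule over the trace
    assert total == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# Closed-form cohorts
# ---------------------------------------------------------------------------


def test_two_state_geometric_series(two_state):
    """Survival chain: undiscounted QALY over 5 cycles is sum of 0.9^t."""
    p = two_state.model_copy(update={"horizon_age": 23})
    out = run_cohort(p, "negative", half_cycle=False)
    assert out.total_qaly == pytest.approx(sum(0.9**t for t in range(5)), abs=1e-12)
    assert out.total_qaly == pytest.approx(4.0951, abs=1e-9)


def test_two_state_geometric_series_discounted(two_state):
    p = set_param(two_state, "discount.rate", 0.05).model_copy(update={"horizon_age": 23})
    out = run_cohort(p, "negative", half_cycle=False)
    expected = sum((0.9 / 1.05) ** t for t in range(5))
    assert out.total_qaly == pytest.approx(expected, abs=1e-12)


def test_immortal_cohort_accrues_horizon_exactly(two_state):
    table = TransitionTable(
        age_bands=[(18, 80)],
        entries={"NON_DM->NON_DM": (1.0,), "DEATH->DEATH": (1.0,)},
    )
    p = two_state.model_copy(update={"transitions": table})
    out = run_cohort(p, "negative", half_cycle=False)
    assert out.total_qaly == pytest.approx(62.0, abs=1e-12)
    # constant occupancy: half-cycle correction changes nothing
    assert run_cohort(p, "negative", half_cycle=True).total_qaly == pytest.approx(62.0)


def test_four_state_chain_matches_matrix_geometric_sum(four_state):
    """Engine totals equal an independently computed sum of v P^t over the
    horizon, for both accrual conventions, to 1e-9."""
    p = set_param(four_state, "discount.rate", 0.05)
    P = p.transitions.matrices()[0]
    u = p.utilities.utility_vector()
    c = p.costs.cost_vector()
    v = np.zeros(len(u))
    v[STATE_INDEX[HealthState.DM_NO_COMP]] = 1.0
    T, d = 62, 1 / 1.05
    occ = np.array([v @ np.linalg.matrix_power(P, t) for t in range(T + 1)])
    disc = d ** np.arange(T)
    for half_cycle in (False, True):
        eff = 0.5 * (occ[:-1] + occ[1:]) if half_cycle else occ[:-1]
        out = run_cohort(p, "diagnosed", half_cycle=half_cycle)
        assert out.total_qaly == pytest.approx(((eff @ u) * disc).sum(), abs=1e-9)
        assert out.total_cost == pytest.approx(((eff @ c) * disc).sum(), abs=1e-9)


def test_start_age_at_horizon_yields_zero_cycles(two_state):
    out = run_cohort(two_state, "negative", start_age_distribution={80: 1.0})
    assert out.total_qaly == 0.0 and out.total_cost == 0.0


# ---------------------------------------------------------------------------
# Forward/backward equivalence and trace invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("arm", ["diagnosed", "missed", "negative"])
def test_backward_sweep_matches_forward_recursion(urban_params, arm):
    fwd = run_cohort(urban_params, arm)
    bwd = arm_expected_outcome(urban_params, arm)
    assert bwd.total_cost == pytest.approx(fwd.total_cost, abs=1e-8)
    assert bwd.total_qaly == pytest.approx(fwd.total_qaly, abs=1e-10)


def test_trace_conservation_and_monotone_death(urban_params):
    tr = run_cohort(urban_params, "missed").trace
    assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)
    death = tr.occupancy[:, STATE_INDEX[HealthState.DEATH]]
    assert (np.diff(death) >= -1e-12).all()
    assert ((tr.occupancy >= -1e-12) & (tr.occupancy <= 1 + 1e-12)).all()


def test_discount_rate_monotonicity(urban_params):
    outs = [
        arm_expected_outcome(set_param(urban_params, "discount.rate", r), "diagnosed")
        for r in (0.0, 0.05, 0.08)
    ]
    assert outs[0].total_qaly >= outs[1].total_qaly >= outs[2].total_qaly
    assert outs[0].total_cost >= outs[1].total_cost >= outs[2].total_cost


def test_missed_arm_never_beats_diagnosed(urban_params):
    diag = arm_expected_outcome(urban_params, "diagnosed")
    missed = arm_expected_outcome(urban_params, "missed")
    assert missed.total_qaly <= diag.total_qaly


# ---------------------------------------------------------------------------
# Microsimulation
# ---------------------------------------------------------------------------


def test_microsim_is_seed_reproducible(urban_params):
    a = run_microsimulation(urban_params, "diagnosed", 2000, seed=42)
    b = run_microsimulation(urban_params, "diagnosed", 2000, seed=42)
    assert a.total_cost == b.total_cost and a.total_qaly == b.total_qaly
    c = run_microsimulation(urban_params, "diagnosed", 2000, seed=43)
    assert (c.total_cost, c.total_qaly) != (a.total_cost, a.total_qaly)


def test_microsim_single_immortal_walk(two_state):
    table = TransitionTable(
        age_bands=[(18, 80)],
        entries={"NON_DM->NON_DM": (1.0,), "DEATH->DEATH": (1.0,)},
    )
    p = two_state.model_copy(update={"transitions": table})
    out = run_microsimulation(p, "negative", 1, seed=0)
    assert out.total_qaly == pytest.approx(62.0, abs=1e-12)


def test_microsim_rejects_empty_cohort(urban_params):
    with pytest.raises(ValueError):
        run_microsimulation(urban_params, "diagnosed", 0, seed=0)


def test_microsim_mean_matches_cohort_expectation(urban_params):
    mc = run_microsimulation(urban_params, "missed", 30_000, seed=5)
    exact = arm_expected_outcome(urban_params, "missed")
    assert abs(mc.total_qaly - exact.total_qaly) < 3 * mc.mc_standard_error["qaly"]
    assert abs(mc.total_cost - exact.total_cost) < 3 * mc.mc_standard_error["cost"]


# ---------------------------------------------------------------------------
# Strategy mixture
# ---------------------------------------------------------------------------


def test_strategy_mixture_equals_reweighting_oracle(urban_params):
    strat = urban_params.strategy("POCT_HBA1C")
    cls = classify(urban_params.setting.prevalence, strat, urban_params.costs)
    arms = {a: arm_expected_outcome(urban_params, a) for a in ("diagnosed", "missed", "negative")}
    expected_cost = cls.screening_cost_per_capita + (
        cls.p_diagnosed * arms["diagnosed"].total_cost
        + cls.p_missed * arms["missed"].total_cost
        + (cls.p_misdiagnosed + cls.p_true_negative) * arms["negative"].total_cost
    )
    expected_qaly = (
        cls.p_diagnosed * arms["diagnosed"].total_qaly
        + cls.p_missed * arms["missed"].total_qaly
        + (cls.p_misdiagnosed + cls.p_true_negative) * arms["negative"].total_qaly
    )
    out = run_strategy(urban_params, strat)
    assert out.total_cost == pytest.approx(expected_cost, abs=1e-9)
    assert out.total_qaly == pytest.approx(expected_qaly, abs=1e-12)


def test_perfect_test_has_no_missed_or_misdiagnosed_weight(urban_params):
    p = set_params(
        urban_params,
        {
            "strategies.FCG.sensitivity": 1.0,
            "strategies.FCG.specificity": 1.0,
        },
    )
    strat = p.strategy("FCG")
    prev = p.setting.prevalence
    arms = {a: arm_expected_outcome(p, a) for a in ("diagnosed", "negative")}
    out = run_strategy(p, strat)
    expected_qaly = prev * arms["diagnosed"].total_qaly + (1 - prev) * arms["negative"].total_qaly
    assert out.total_qaly == pytest.approx(expected_qaly, abs=1e-12)


def test_vanishing_prevalence_converges_to_negative_arm(urban_params):
    p = set_param(urban_params, "setting.prevalence", 1e-9)
    strat = p.strategy("POCT_HBA1C")
    out = run_strategy(p, strat)
    neg = arm_expected_outcome(p, "negative")
    cls = classify(1e-9, strat, p.costs)
    # residual is O(prevalence x diseased-arm totals)
    assert out.total_qaly == pytest.approx(neg.total_qaly, rel=1e-6)
    assert out.total_cost == pytest.approx(
        neg.total_cost + cls.screening_cost_per_capita, abs=1e-4
    )


def test_higher_sensitivity_never_lowers_strategy_qaly(urban_params):
    base = run_strategy(urban_params, urban_params.strategy("FCG"))
    better = set_param(
        urban_params,
        "strategies.FCG.sensitivity",
        min(1.0, urban_params.strategy("FCG").sensitivity + 0.2),
    )
    improved = run_strategy(better, better.strategy("FCG"))
    assert improved.total_qaly >= base.total_qaly


def test_evaluate_setting_covers_all_strategies(urban_params):
    out = evaluate_setting(urban_params)
    assert set(out) == {"POCT_HBA1C", "VENOUS_HBA1C", "FCG"}
    for o in out.values():
        assert o.total_cost > 0 and 0 < o.total_qaly < 62
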