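"""Distribution fitting, OWSA endpoints, PSA reproducibility and the CEAC."""

import math

import numpy as np
import pytest

from screencea.cea import compute_icur
from screencea.markov import evaluate_setting
from screencea.paths import get_param, is_probability_path, set_param
from screencea.sensitivity import (
    LOGNORMAL_SIGMA_10PCT,
    ParamRange,
    PSADistribution,
    PSASample,
    ceac,
    default_lambda_grid,
    default_owsa_ranges,
    default_psa_distributions,
    fit_beta,
    fit_lognormal,
    owsa,
    pm20_range,
    psa,
)


# ---------------------------------------------------------------------------
# Parameter paths
# ---------------------------------------------------------------------------


def test_get_set_roundtrip_scalar(urban_params):
    assert get_param(urban_params, "discount.rate") == 0.05
    p2 = set_param(urban_params, "costs.ogtt_cost", 12.5)
    assert get_param(p2, "costs.ogtt_cost") == 12.5
    assert get_param(urban_params, "costs.ogtt_cost") == 8.0  # original untouched


def test_set_transition_rescales_and_recloses(urban_params):
    path = "transitions.DM_NO_COMP->DM_STROKE"
    base = get_param(urban_params, path)
    p2 = set_param(urban_params, path, base * 1.2)
    assert get_param(p2, path) == pytest.approx(base * 1.2)
    sums = p2.transitions.matrices().sum(axis=2)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_unknown_path_raises(urban_params):
    with pytest.raises(KeyError):
        get_param(urban_params, "strategies.FCG.nonsense")
    with pytest.raises(KeyError):
        set_param(urban_params, "transitions.NON_DM->DM_CVD", 0.1)


def test_probability_path_classification():
    assert is_probability_path("setting.prevalence")
    assert is_probability_path("strategies.FCG.sensitivity")
    assert is_probability_path("transitions.DM_NO_COMP->DM_CVD")
    assert is_probability_path("utilities.state_utility.DM_CVD")
    assert not is_probability_path("costs.ogtt_cost")
    assert not is_probability_path("missed_hr.hr_micro")


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


def test_fit_beta_mean_and_bounds():
    d = fit_beta(90, 10)
    assert d.mean == pytest.approx(0.9)
    assert fit_beta(1, 1).mean == pytest.approx(0.5)
    with pytest.raises(ValueError):
        fit_beta(0, 0)
    assert fit_beta(0, 10).alpha == 0.5  # continuity correction


def test_beta_draw_moments_match_analytic():
    a, b = 90.0, 10.0
    rng = np.random.default_rng(123)
    x = fit_beta(a, b).sample(rng, size=100_000)
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    se_mean = math.sqrt(var / x.size)
    assert abs(x.mean() - mean) < 3 * se_mean
    # variance of the sample variance via the 4th central moment
    m4 = np.mean((x - x.mean()) ** 4)
    se_var = math.sqrt(max(m4 - var**2, 0.0) / x.size)
    assert abs(x.var() - var) < 3 * se_var


def test_fit_lognormal_median_is_point_estimate():
    d = fit_lognormal(1000.0)
    assert d.mu == pytest.approx(math.log(1000.0), abs=1e-9)
    assert d.mu == pytest.approx(6.907755, abs=1e-6)
    assert d.sigma == pytest.approx(LOGNORMAL_SIGMA_10PCT)
    with pytest.raises(ValueError):
        fit_lognormal(0.0)


@pytest.mark.parametrize("point", [37.0, 1000.0])
def test_lognormal_draws_median_and_cv(point):
    rng = np.random.default_rng(99)
    x = fit_lognormal(point).sample(rng, size=100_000)
    assert abs(np.median(x) / point - 1.0) < 0.01
    assert 0.09 < x.std() / x.mean() < 0.11


# ---------------------------------------------------------------------------
# OWSA
# ---------------------------------------------------------------------------


def test_pm20_range_brackets_base(urban_params):
    r = pm20_range(urban_params, "costs.state_annual_cost.DM_CVD")
    base = get_param(urban_params, "costs.state_annual_cost.DM_CVD")
    assert r.low == pytest.approx(0.8 * base) and r.high == pytest.approx(1.2 * base)
    rs = pm20_range(urban_params, "strategies.POCT_HBA1C.sensitivity")
    assert rs.high <= 1.0  # probability clipped


def test_owsa_inert_parameter_has_zero_width(urban_params):
    # NON_DM annual cost is 0 and not enumerated; use a state cost that has
    # no causal path: BLINDNESS cost influences costs, so instead vary an
    # unused strategy's cost component, which cannot move POCT-vs-FCG ICUR
    ranges = [pm20_range(urban_params, "strategies.VENOUS_HBA1C.cost_direct_medical")]
    entries = owsa(urban_params, ranges, ("FCG", "POCT_HBA1C"))
    assert entries[0].bar_width == pytest.approx(0.0, abs=1e-9)


def test_owsa_discount_endpoints_match_direct_reruns(urban_params):
    ranges = [ParamRange("discount.rate", 0.0, 0.08, source="reported_95CI")]
    entries = owsa(urban_params, ranges, ("FCG", "POCT_HBA1C"))
    for rate, got in zip((0.0, 0.08), (entries[0].icur_at_low, entries[0].icur_at_high)):
        p2 = set_param(urban_params, "discount.rate", rate)
        outs = evaluate_setting(p2)
        expected = compute_icur(outs["FCG"], outs["POCT_HBA1C"], p2.wtp).icur
        assert got == pytest.approx(expected, abs=1e-9)


def test_owsa_sorted_by_width_desc(urban_params):
    ranges = default_owsa_ranges(urban_params)[:12]
    entries = owsa(urban_params, ranges, ("FCG", "POCT_HBA1C"))
    widths = [e.bar_width for e in entries]
    assert widths == sorted(widths, reverse=True)


def test_owsa_cost_linearity_symmetric_endpoints(urban_params):
    """A +-20% range on a pure cost parameter moves the ICUR linearly, so the
    endpoints are symmetric about the base ICUR."""
    outs = evaluate_setting(urban_params)
    base = compute_icur(outs["FCG"], outs["POCT_HBA1C"], urban_params.wtp).icur
    ranges = [pm20_range(urban_params, "strategies.POCT_HBA1C.cost_direct_medical")]
    e = owsa(urban_params, ranges, ("FCG", "POCT_HBA1C"))[0]
    assert (e.icur_at_high - base) == pytest.approx(base - e.icur_at_low, abs=1e-6)


# ---------------------------------------------------------------------------
# PSA and CEAC
# ---------------------------------------------------------------------------


def test_psa_reproducible_and_draws_indexed_by_seed(urban_params):
    dists = default_psa_distributions(urban_params)
    a = psa(urban_params, dists, n_iter=5, seed=7)
    b = psa(urban_params, dists, n_iter=5, seed=7)
    assert [s.parameters for s in a] == [s.parameters for s in b]
    assert [s.deltas for s in a] == [s.deltas for s in b]
    c = psa(urban_params, dists, n_iter=5, seed=8)
    assert [s.parameters for s in c] != [s.parameters for s in a]


def test_psa_probability_draws_stay_in_unit_interval(urban_params):
    dists = default_psa_distributions(urban_params)
    for s in psa(urban_params, dists, n_iter=5, seed=1):
        for path, v in s.parameters.items():
            if is_probability_path(path):
                assert 0.0 <= v <= 1.0


def test_psa_degenerate_distributions_recover_base_case(urban_params):
    """Near-zero-variance draws reproduce the deterministic base result."""
    paths = ["costs.ogtt_cost", "setting.prevalence"]
    dists = {
        p: PSADistribution(
            kind="uniform",
            low=get_param(urban_params, p) * (1 - 1e-12),
            high=get_param(urban_params, p) * (1 + 1e-12),
        )
        for p in paths
    }
    samples = psa(urban_params, dists, n_iter=3, seed=0)
    outs = evaluate_setting(urban_params)
    for s in samples:
        for name, (cost, qaly) in s.strategy_outcomes.items():
            assert cost == pytest.approx(outs[name].total_cost, rel=1e-9)
            assert qaly == pytest.approx(outs[name].total_qaly, rel=1e-9)


def _samples_from_deltas(deltas):
    return [
        PSASample(
            draw_index=i,
            parameters={},
            strategy_outcomes={},
            deltas={("FCG", "POCT_HBA1C"): d},
        )
        for i, d in enumerate(deltas)
    ]


def test_ceac_equals_counting_oracle():
    rng = np.random.default_rng(42)
    deltas = list(zip(rng.normal(50, 200, 400), rng.normal(0.02, 0.05, 400)))
    samples = _samples_from_deltas(deltas)
    grid = [0.0, 1000.0, 37_653.0]
    curve = ceac(samples, grid)
    col = curve["p_ce_POCT_HBA1C_vs_FCG"]
    for lam, got in zip(grid, col):
        count = sum(1 for dc, de in deltas if lam * de - dc > 0)
        assert got == pytest.approx(count / len(deltas), abs=1e-12)
    # lambda = 0 reduces NMB to -dC
    assert col.iloc[0] == pytest.approx(
        sum(1 for dc, _ in deltas if dc < 0) / len(deltas)
    )


def test_ceac_uniform_dominance_is_one_everywhere():
    deltas = [(-10.0, 0.1)] * 50
    curve = ceac(_samples_from_deltas(deltas), default_lambda_grid(37_653.0, 11))
    assert (curve["p_ce_POCT_HBA1C_vs_FCG"] == 1.0).all()


def test_ceac_limit_is_probability_of_positive_gain():
    rng = np.random.default_rng(3)
    deltas = list(zip(rng.normal(0, 1, 300), rng.normal(0.0, 0.05, 300)))
    curve = ceac(_samples_from_deltas(deltas), [1e12])
    p_gain = sum(1 for _, de in deltas if de > 0) / len(deltas)
    assert curve.iloc[0, 1] == pytest.approx(p_gain, abs=0.01)


def test_ceac_requires_samples_and_grid():
    with pytest.raises(ValueError):
        ceac([], [0.0])
    with pytest.raises(ValueError):
        ceac(_samples_from_deltas([(1.0, 1.0)]), [])
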