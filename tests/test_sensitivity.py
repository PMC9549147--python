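"""Distribution fitting, DSA, PSA, CE-plane and CEAC tests."""

import numpy as np
import pytest
from scipy import stats

from oacea import (
    beta_from_moments,
    ce_plane,
    ceac,
    gamma_from_moments,
    lognormal_from_moments,
    one_way_dsa,
    run_cea,
    run_dsa,
    run_psa,
)
from oacea.economics import icer, nmb
from oacea.parameters import ParamUncertainty, ValidationError
from oacea.sensitivity import (
    build_uncertain_parameters,
    sample_parameter,
    sample_parameter_table,
)
from oacea.synthetic import infeasible_beta_model, toy_model_2state


# ---------------------------------------------------------------------------
# method-of-moments fits


@pytest.mark.parametrize("mean, se", [(436.0, 11.0), (1.0, 1.0), (78925.0, 500.0)])
def test_gamma_moments_round_trip(mean, se):
    shape, scale = gamma_from_moments(mean, se)
    assert shape * scale == pytest.approx(mean, rel=1e-9)
    assert np.sqrt(shape) * scale == pytest.approx(se, rel=1e-9)


def test_gamma_fit_of_published_gi_cost_row():
    shape, scale = gamma_from_moments(436.0, 11.0)
    assert shape == pytest.approx((436 / 11) ** 2, rel=1e-12)
    assert scale == pytest.approx(121 / 436, rel=1e-12)
    # mean 1, se 1 is the unit exponential
    assert gamma_from_moments(1.0, 1.0) == pytest.approx((1.0, 1.0))


@pytest.mark.parametrize("mean, se", [(0.56, 0.0152), (0.62, 0.0036), (0.1, 0.02)])
def test_beta_moments_round_trip(mean, se):
    a, b = beta_from_moments(mean, se)
    assert a / (a + b) == pytest.approx(mean, rel=1e-9)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert np.sqrt(var) == pytest.approx(se, rel=1e-9)


def test_beta_fit_of_published_moderate_pain_utility():
    a, b = beta_from_moments(0.56, 0.0152)
    nu = 0.56 * 0.44 / 0.0152**2 - 1
    assert a == pytest.approx(0.56 * nu, rel=1e-12)
    assert b == pytest.approx(0.44 * nu, rel=1e-12)
    assert a == pytest.approx(596.7, abs=0.1)
    assert b == pytest.approx(468.8, abs=0.1)


def test_beta_infeasible_moments_error():
    with pytest.raises(ValidationError, match="infeasible"):
        beta_from_moments(0.5, 0.6)


@pytest.mark.parametrize("mean, se", [(0.8647, 0.08), (1.0, 0.5), (436.0, 11.0)])
def test_lognormal_moments_round_trip(mean, se):
    mu, sigma = lognormal_from_moments(mean, se)
    analytic_mean = np.exp(mu + sigma**2 / 2)
    analytic_var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
    assert analytic_mean == pytest.approx(mean, rel=1e-9)
    assert np.sqrt(analytic_var) == pytest.approx(se, rel=1e-9)


@pytest.mark.parametrize(
    "family, mean, se",
    [("gamma", 436.0, 11.0), ("beta", 0.56, 0.0152), ("lognormal", 0.3857, 0.07714)],
)
def test_sampled_means_within_three_mc_standard_errors(family, mean, se):
    p = ParamUncertainty(name="x", mean=mean, se=se, dist_family=family)
    n = 100_000
    draws = sample_parameter(p, np.random.default_rng(12345), n)
    mc_se = draws.std(ddof=1) / np.sqrt(n)
    assert abs(draws.mean() - mean) < 3 * mc_se
    # cross-check second moment against scipy's analytic distribution mean
    if family == "gamma":
        shape, scale = gamma_from_moments(mean, se)
        assert stats.gamma(shape, scale=scale).mean() == pytest.approx(mean)
    elif family == "beta":
        a, b = beta_from_moments(mean, se)
        assert stats.beta(a, b).mean() == pytest.approx(mean)


def test_zero_se_and_negative_mean_handling():
    fixed = ParamUncertainty(name="x", mean=0.5, se=0.0, dist_family="fixed")
    assert np.all(sample_parameter(fixed, np.random.default_rng(0), 10) == 0.5)
    disutility = ParamUncertainty(name="d", mean=-0.0524, se=0.0001,
                                  dist_family="beta")
    draws = sample_parameter(disutility, np.random.default_rng(0), 1000)
    assert np.all(draws < 0)
    assert draws.mean() == pytest.approx(-0.0524, abs=3 * 0.0001)


def test_lognormal_probability_draws_are_truncated_to_unit_interval():
    p = ParamUncertainty(name="p", mean=0.8647, se=0.4, dist_family="lognormal")
    draws = sample_parameter(p, np.random.default_rng(0), 10_000)
    assert draws.max() <= 1.0 and draws.min() >= 0.0
    assert (draws == 1.0).any()  # clamping actually occurs at this spread


def test_infeasible_distribution_error_names_the_parameter():
    model = infeasible_beta_model(seed=3)
    with pytest.raises(ValidationError, match="utilities.moderate_pain"):
        sample_parameter_table(model, 5, seed=0)


# ---------------------------------------------------------------------------
# deterministic sensitivity


@pytest.fixture(scope="module")
def headline_pair():
    return (
        "standard_plus_etoricoxib_plus_glucosamine_before_diclofenac_ppi",
        "standard_plus_glucosamine_before_diclofenac_ppi",
    )


def test_degenerate_range_gives_zero_bar(fixture_model, headline_pair):
    base = fixture_model.utilities.moderate_pain
    entry = one_way_dsa(fixture_model, "utilities.moderate_pain", base, base,
                        headline_pair)
    assert entry.bar_width == 0.0


def test_pinning_invalid_value_errors(fixture_model, headline_pair):
    with pytest.raises(ValidationError):
        one_way_dsa(
            fixture_model, "states.tka.pain_relief_prob", 0.5, 1.2, headline_pair
        )


def test_tornado_ordering_of_published_ranges(fixture_model, headline_pair):
    """Of the two published one-way ranges, the moderate-pain utility
    (0.35-0.77) moves the headline comparison by orders of magnitude more
    than the TKA cost (a 783 THB range paid in both arms), matching the
    published most/least-sensitive parameters.  The remaining four ranges
    are package defaults (+/-20%), so only the published pair is compared;
    bars come back sorted by width."""
    entries = run_dsa(fixture_model, headline_pair)
    assert len(entries) == 6
    widths = {e.param: e.bar_width for e in entries}
    assert widths["utilities.moderate_pain"] > 100 * widths["states.tka.one_time_cost"]
    # TKA cost and glucosamine cost (paid identically in both arms) are the
    # narrowest bars
    assert sorted(widths, key=widths.get)[:2] == [
        "states.crystalline_glucosamine_sulfate.cycle_cost",
        "states.tka.one_time_cost",
    ]
    bars = [e.bar_width for e in entries]
    assert bars == sorted(bars, reverse=True)


def test_dsa_accepts_published_utility_range_above_no_pain(fixture_model,
                                                           headline_pair):
    """The published upper bound for the moderate-pain utility (0.77) lies
    above the no-pain utility (0.62); pinning must honour it rather than
    clip, and the bar endpoints must both be finite."""
    entry = one_way_dsa(fixture_model, "utilities.moderate_pain", 0.35, 0.77,
                        headline_pair)
    assert np.isfinite(entry.output_at_low) and np.isfinite(entry.output_at_high)
    assert entry.bar_width > 0


# ---------------------------------------------------------------------------
# probabilistic sensitivity


def test_psa_is_deterministic_given_seed(toy2):
    a = run_psa(toy2, n_iter=20, seed=11)
    b = run_psa(toy2, n_iter=20, seed=11)
    assert np.array_equal(a.costs, b.costs)
    assert np.array_equal(a.qalys, b.qalys)
    assert a.parameters.equals(b.parameters)
    c = run_psa(toy2, n_iter=20, seed=12)
    assert not np.array_equal(a.costs, c.costs)


def test_degenerate_psa_equals_base_case(toy2):
    toy2.uncertainty.default_se_fraction = 0.0
    toy2.utilities.no_pain_se = 0.0
    toy2.utilities.moderate_pain_se = 0.0
    psa = run_psa(toy2, n_iter=5, seed=0)
    base = run_cea(toy2)[0]
    assert np.allclose(psa.costs, base.total_cost, rtol=0, atol=1e-9)
    assert np.allclose(psa.qalys, base.total_qaly, rtol=0, atol=1e-9)


def test_parameter_substreams_are_stable_under_extension(fixture_model):
    """Adding an uncertain parameter must not perturb the other draws."""
    table = sample_parameter_table(fixture_model, 50, seed=5)
    extended = fixture_model.copy()
    extended.uncertainty.overrides["states.acetaminophen.cycle_cost"] = {
        "se": 20.0, "family": "gamma",
    }
    table2 = sample_parameter_table(extended, 50, seed=5)
    for col in table.columns:
        assert np.array_equal(table[col].values, table2[col].values)
    assert "states.acetaminophen.cycle_cost" in table2.columns


def test_psa_sample_means_recover_base_means(fixture_model):
    table = sample_parameter_table(fixture_model, 1000, seed=9)
    for p in build_uncertain_parameters(fixture_model):
        if p.dist_family == "fixed":
            continue
        draws = table[p.name].values
        if p.dist_family == "lognormal" and (np.abs(draws) >= 1.0).any():
            continue  # clamped at 1: the truncated mean sits below the fit
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - p.mean) < 3 * mc_se


def test_ce_plane_quadrants_and_tie_rule(toy2):
    psa = run_psa(toy2, n_iter=30, seed=2, strategies=["two_state", "two_state"])
    plane = ce_plane(psa, ("two_state", "two_state"))
    # identical strategies: all deltas zero -> favourable quadrant by tie rule
    assert plane["proportions"]["lower_right"] == 1.0
    assert sum(plane["proportions"].values()) == pytest.approx(1.0)


def test_ceac_multiway_probabilities_partition(fixture_model):
    psa = run_psa(fixture_model, n_iter=30, seed=4)
    curve = ceac(psa, wtp_grid=np.array([0.0, 80_000.0, 160_000.0, 320_000.0]))
    sums = curve.probabilities.sum(axis=1).values
    assert np.allclose(sums, 1.0, atol=1e-12)
    assert ((curve.probabilities.values >= 0) & (curve.probabilities.values <= 1)).all()


def test_degenerate_ceac_steps_at_deterministic_icer(toy2):
    toy2.uncertainty.default_se_fraction = 0.0
    toy2.utilities.no_pain_se = 0.0
    toy2.utilities.moderate_pain_se = 0.0
    # build a comparison by pricing the same care path at two cost levels
    import oacea.parameters as P

    toy2.states["state_a2"] = P.TreatmentState(
        "state_a2", 0.5, cycle_cost=200.0
    )
    toy2.states["state_b2"] = P.TreatmentState(
        "state_b2", 0.9, cycle_cost=50.0, is_terminal_treatment=True
    )
    toy2.strategies.append(P.StrategyDef("pricier", ["state_a2", "state_b2"]))
    toy2.validate()
    psa = run_psa(toy2, n_iter=8, seed=0)
    res = run_cea(toy2)
    pair_icer = icer(res[1], res[0])  # pricier but more effective
    assert pair_icer > 0
    grid = np.array([0.0, pair_icer * 0.99, pair_icer * 1.01, 1e7])
    curve = ceac(psa, wtp_grid=grid, comparison=("pricier", "two_state"))
    probs = curve.probabilities["pairwise"].values
    assert list(probs) == [0.0, 0.0, 1.0, 1.0]


def test_pairwise_ceac_is_one_when_strategy_dominates_in_every_draw(toy2):
    # same care path priced higher: with transition probabilities held fixed
    # the QALYs agree draw by draw while the copy always costs more
    import oacea.parameters as P

    toy2.uncertainty.default_se_fraction = 0.0
    toy2.states["state_a2"] = P.TreatmentState("state_a2", 0.5, cycle_cost=500.0)
    toy2.states["state_b2"] = P.TreatmentState(
        "state_b2", 0.8, cycle_cost=500.0, is_terminal_treatment=True
    )
    toy2.strategies.append(P.StrategyDef("pricier", ["state_a2", "state_b2"]))
    toy2.validate()
    psa = run_psa(toy2, n_iter=15, seed=1)
    ja, jb = psa.column("two_state"), psa.column("pricier")
    assert np.all(psa.costs[:, ja] < psa.costs[:, jb])
    assert np.allclose(psa.qalys[:, ja], psa.qalys[:, jb])
    curve = ceac(psa, wtp_grid=np.linspace(0, 3e5, 7),
                 comparison=("two_state", "pricier"))
    assert np.all(curve.probabilities["pairwise"].values == 1.0)
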