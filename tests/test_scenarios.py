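import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from woodocc.inference import CommunityPosterior
from woodocc.model import ModelConfig
from woodocc.predictors import StandardizationTransform
from woodocc.scenarios import (
    AssemblageEnsemble,
    ScenarioSpec,
    build_scenario_grid,
    expected_richness,
    marginal_response_curve,
    probability_of_direction,
    simulate_assemblages,
    species_richness,
)


def make_posterior(b0_values, n_draws=2000, slope=None):
    """Degenerate posterior: every draw identical; intercept-only model
    unless a slope on 'area' is requested."""
    mains = ["area"] if slope is not None else []
    model = ModelConfig(
        occupancy_mains=mains, occupancy_interactions=[], include_country=False,
        detection_covariates=["day"], detection_quadratic=[], perfect_detection=True,
    )
    S = len(b0_values)
    P = 1 + len(mains)
    beta = np.zeros((1, n_draws, S, P))
    beta[:, :, :, 0] = np.asarray(b0_values)
    if slope is not None:
        beta[:, :, :, 1] = slope
    transform = StandardizationTransform(
        means={"area": 0.0} if slope is not None else {},
        sds={"area": 1.0} if slope is not None else {},
        ranges={"area": (-3.0, 3.0)} if slope is not None else {},
    )
    return CommunityPosterior(
        beta=beta,
        mu_beta=beta[:, :, 0, :],
        tau_beta=np.ones_like(beta[:, :, 0, :]),
        occ_terms=model.occupancy_terms,
        model=model,
        transform=transform,
    )


@pytest.fixture
def marginals():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {"area": rng.uniform(-3, 3, 50), "country": rng.integers(0, 2, 50)}
    )


class TestScenarioGrid:
    def test_three_drivers_full_factorial_plus_background(self, marginals):
        levels = {"a": (0.0, 1.0), "b": (0.0, 1.0), "c": (0.0, 1.0)}
        specs = build_scenario_grid(levels, area_ha=3.5)
        assert len(specs) == 2**3 + 1
        assert specs[-1].label == "background"
        assert specs[-1].fixed_values == {}

    def test_single_driver(self):
        specs = build_scenario_grid({"a": (0.1, 0.9)})
        assert len(specs) == 3
        assert specs[0].all_fixed == {"a": 0.1, "area": 3.5}

    def test_duplicate_predictor_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_scenario_grid([("a", (0.0, 1.0)), ("a", (0.2, 0.8))])

    def test_level_outside_observed_range_rejected(self, marginals):
        with pytest.raises(ValueError, match="outside the observed"):
            build_scenario_grid({"area": (-10.0, 1.0)}, observed=marginals)

    def test_default_patch_area_is_mean_patch_size(self):
        assert ScenarioSpec().area_ha == 3.5
        assert ScenarioSpec().n_draws == 20_000


class TestSimulateAssemblages:
    def test_intercept_only_presence_rate(self, marginals):
        post = make_posterior([1.0] * 4, n_draws=5000)
        spec = ScenarioSpec(area_ha=None, n_draws=5000)
        ens = simulate_assemblages(post, spec, marginals, seed=3)
        rate = ens.presence.mean(axis=0)
        assert np.allclose(rate, expit(1.0), atol=0.025)  # ~ 0.731

    def test_certain_occupancy_gives_full_species_list(self, marginals):
        post = make_posterior([40.0] * 6, n_draws=500)
        ens = simulate_assemblages(
            post, ScenarioSpec(area_ha=None, n_draws=500), marginals, seed=0
        )
        assert np.all(ens.presence == 1)

    def test_fixed_seed_identical_ensemble(self, marginals):
        post = make_posterior([0.0] * 3, n_draws=800)
        spec = ScenarioSpec(area_ha=None, n_draws=800)
        e1 = simulate_assemblages(post, spec, marginals, seed=9)
        e2 = simulate_assemblages(post, spec, marginals, seed=9)
        assert np.array_equal(e1.presence, e2.presence)

    def test_more_draws_than_posterior_rejected(self, marginals):
        post = make_posterior([0.0], n_draws=100)
        with pytest.raises(ValueError, match="draws"):
            simulate_assemblages(
                post, ScenarioSpec(area_ha=None, n_draws=101), marginals
            )

    def test_unknown_fixed_predictor_rejected(self, marginals):
        post = make_posterior([0.0], n_draws=100)
        spec = ScenarioSpec(fixed_values={"arable": 0.5}, area_ha=None, n_draws=10)
        with pytest.raises(KeyError, match="arable"):
            simulate_assemblages(post, spec, marginals)

    def test_background_equals_empty_fixed_scenario(self, marginals):
        post = make_posterior([0.3] * 3, n_draws=400, slope=0.5)
        grid = build_scenario_grid({"area": (-1.0, 1.0)}, area_ha=None, n_draws=400)
        background = grid[-1]
        manual = ScenarioSpec(fixed_values={}, area_ha=None, n_draws=400)
        e1 = simulate_assemblages(post, background, marginals, seed=5)
        e2 = simulate_assemblages(post, manual, marginals, seed=5)
        assert np.array_equal(e1.presence, e2.presence)


class TestRichness:
    def test_all_ones_ensemble(self):
        ens = AssemblageEnsemble(np.ones((50, 8), dtype=int), "x", 0)
        richness, mode = species_richness(ens)
        assert np.all(richness == 8)
        assert mode == 8

    def test_empty_assemblages_mode_zero(self):
        ens = AssemblageEnsemble(np.zeros((50, 8), dtype=int), "x", 0)
        _, mode = species_richness(ens)
        assert mode == 0

    def test_tie_breaks_to_smallest_value(self):
        presence = np.array([[1, 0], [1, 0], [1, 1], [1, 1]])
        _, mode = species_richness(AssemblageEnsemble(presence, "x", 0))
        assert mode == 1

    def test_binomial_mean(self, marginals):
        post = make_posterior([0.0] * 10, n_draws=20_000)
        spec = ScenarioSpec(area_ha=None, n_draws=20_000)
        ens = simulate_assemblages(post, spec, marginals, seed=2)
        richness, _ = species_richness(ens)
        se = np.sqrt(10 * 0.25 / 20_000)
        assert abs(richness.mean() - 5.0) < 3 * se

    def test_non_binary_presence_rejected(self):
        with pytest.raises(ValueError):
            AssemblageEnsemble(np.array([[0, 2]]), "x", 0)


class TestExpectedRichness:
    def test_certain_species(self, marginals):
        post = make_posterior([60.0] * 7, n_draws=200)
        spec = ScenarioSpec(area_ha=None, n_draws=200)
        assert expected_richness(post, spec, marginals) == pytest.approx(7.0)

    def test_impossible_species(self, marginals):
        post = make_posterior([-60.0] * 7, n_draws=200)
        spec = ScenarioSpec(area_ha=None, n_draws=200)
        assert expected_richness(post, spec, marginals) == pytest.approx(0.0)

    def test_mixed_probabilities_sum(self, marginals):
        post = make_posterior([logit(0.2), logit(0.7)], n_draws=100)
        spec = ScenarioSpec(area_ha=None, n_draws=100)
        assert expected_richness(post, spec, marginals) == pytest.approx(0.9, abs=1e-9)

    def test_unanimous_positive_slope_high_dominates_low(self, marginals):
        post = make_posterior([0.0] * 5, n_draws=4000, slope=0.8)
        high = ScenarioSpec(fixed_values={"area": 2.0}, area_ha=None, n_draws=4000)
        low = ScenarioSpec(fixed_values={"area": -2.0}, area_ha=None, n_draws=4000)
        assert expected_richness(post, high, marginals) > expected_richness(
            post, low, marginals
        )

    def test_monte_carlo_agreement_within_three_se(self, marginals):
        post = make_posterior(
            np.linspace(-1, 1, 12), n_draws=20_000, slope=0.4
        )
        for spec in build_scenario_grid(
            {"area": (-1.0, 1.0)}, area_ha=None, n_draws=20_000
        ):
            ens = simulate_assemblages(post, spec, marginals, seed=21)
            richness, _ = species_richness(ens)
            analytic = expected_richness(post, spec, marginals, seed=21)
            se = richness.std(ddof=1) / np.sqrt(len(richness))
            assert abs(richness.mean() - analytic) < 3 * se


class TestMarginalResponse:
    def test_zero_slope_flat_curve(self, marginals):
        post = make_posterior([0.4], n_draws=100, slope=0.0)
        curve = marginal_response_curve(post, 0, "area", np.linspace(-2, 2, 9), marginals)
        assert np.allclose(curve["psi"], expit(0.4))

    def test_positive_slope_strictly_increasing(self, marginals):
        post = make_posterior([0.0], n_draws=100, slope=0.7)
        curve = marginal_response_curve(post, 0, "area", np.linspace(-2, 2, 9), marginals)
        assert np.all(np.diff(curve["psi"]) > 0)

    def test_logistic_table_value(self, marginals):
        post = make_posterior([0.0], n_draws=100, slope=1.0)
        curve = marginal_response_curve(post, 0, "area", np.array([2.0]), marginals)
        assert curve["psi"].iloc[0] == pytest.approx(0.8808, abs=1e-4)

    def test_out_of_range_grid_rejected(self, marginals):
        post = make_posterior([0.0], n_draws=100, slope=1.0)
        with pytest.raises(ValueError, match="range"):
            marginal_response_curve(post, 0, "area", np.array([5.0]), marginals)


class TestProbabilityOfDirection:
    @pytest.mark.parametrize(
        "draws,expected",
        [
            ([0.2, 0.5, 1.3], 1.0),
            ([-1.0, 1.0], 0.5),
            ([1.0, 1.0, 1.0, -1.0], 0.75),
            ([-2.0, -3.0, 1.0], 2 / 3),
            ([0.0, 0.0], 0.5),
        ],
    )
    def test_enumerable_draws(self, draws, expected):
        assert probability_of_direction(np.array(draws)) == pytest.approx(expected)

    def test_bounds(self, rng):
        for _ in range(20):
            draws = rng.normal(size=rng.integers(1, 50))
            pd_ = probability_of_direction(draws)
            assert 0.5 <= pd_ <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            probability_of_direction(np.array([]))
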