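import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

from woodocc.model import ModelConfig
from woodocc.synthetic import (
    DetectionHistory,
    SimulationConfig,
    TrueParameters,
    generate_community_parameters,
    generate_dataset,
    generate_detection_histories,
    generate_occupancy_states,
    generate_site_covariates,
    generate_spatial_factors,
)

PROPORTION_COLS = [
    "current_woodland", "old_woodland", "lost_woodland", "trees_outside", "arable",
]


def _config(**kw):
    kw.setdefault("n_species", 5)
    kw.setdefault("n_sites", 30)
    kw.setdefault("n_visits", 3)
    return SimulationConfig(**kw)


class TestSiteCovariates:
    def test_deterministic_under_fixed_seed(self):
        t1 = generate_site_covariates(_config(seed=1))
        t2 = generate_site_covariates(_config(seed=1))
        assert t1.equals(t2)

    def test_published_ranges(self):
        table = generate_site_covariates(_config(n_sites=400, seed=3))
        assert table["area"].between(0.5, 31.9).all()
        for col in PROPORTION_COLS:
            assert table[col].between(0.0, 1.0).all(), col
        assert (table["shape"] >= 1.0).all()
        assert (table["age"] >= 10.0).all()

    def test_two_sites_distinct_coordinates(self):
        table = generate_site_covariates(_config(n_sites=2, seed=0))
        assert len(table) == 2
        assert not np.allclose(
            table.loc[0, ["x", "y"]].to_numpy(), table.loc[1, ["x", "y"]].to_numpy()
        )

    def test_two_disjoint_regions(self):
        table = generate_site_covariates(_config(n_sites=60, seed=5))
        x0 = table.loc[table.country == 0, "x"]
        x1 = table.loc[table.country == 1, "x"]
        assert x0.max() < x1.min()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            _config(n_sites=0)
        with pytest.raises(ValueError):
            _config(n_visits=-1)
        with pytest.raises(ValueError):
            _config(missing_visit_rate=1.0)


class TestCommunityParameters:
    def test_zero_sds_collapse_to_means(self):
        cfg = _config(seed=4)
        cfg.occupancy_sds = np.zeros_like(cfg.occupancy_sds)
        params = generate_community_parameters(cfg)
        assert np.allclose(params.occupancy_coeffs, cfg.occupancy_means)

    def test_column_mean_obeys_clt_bound(self):
        model = ModelConfig(
            occupancy_mains=["area"], occupancy_interactions=[],
            include_country=False, detection_covariates=["day"],
            detection_quadratic=[],
        )
        cfg = SimulationConfig(
            n_species=2000, n_sites=5, model=model, seed=8,
            occupancy_means=np.array([0.7, 0.7]),
            occupancy_sds=np.array([0.5, 0.5]),
        )
        params = generate_community_parameters(cfg)
        bound = 4 * 0.5 / np.sqrt(2000)
        assert np.all(np.abs(params.occupancy_coeffs.mean(axis=0) - 0.7) < bound)

    def test_reproducible_under_seed(self):
        p1 = generate_community_parameters(_config(seed=6))
        p2 = generate_community_parameters(_config(seed=6))
        assert np.array_equal(p1.occupancy_coeffs, p2.occupancy_coeffs)

    def test_negative_sds_rejected(self):
        cfg = _config(seed=0)
        with pytest.raises(ValueError):
            SimulationConfig(
                n_species=3, n_sites=10, n_visits=2,
                occupancy_sds=-np.ones_like(cfg.occupancy_sds),
            )

    def test_loading_constraint(self):
        cfg = _config(seed=1, model=ModelConfig(n_factors=3))
        lam = generate_community_parameters(cfg).factor_loadings
        assert np.allclose(np.diag(lam[:3, :3]), 1.0)
        assert np.allclose(np.triu(lam[:3, :3], k=1), 0.0)


class TestSpatialFactors:
    def test_high_decay_decorrelates_sites(self):
        coords = np.array([[0.0, 0.0], [5.0, 0.0]])
        draws = np.array(
            [
                generate_spatial_factors(coords, 1, 1e6, seed)[0]
                for seed in range(2500)
            ]
        )
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(corr) < 0.06

    def test_coincident_sites_share_scores(self):
        coords = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 2.0]])
        scores = generate_spatial_factors(coords, 2, 0.3, seed=2, jitter=0.0)
        assert np.allclose(scores[:, 0], scores[:, 1])

    def test_unit_marginal_variance(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        draws = np.array(
            [generate_spatial_factors(coords, 1, 0.2, s)[0, 0] for s in range(3000)]
        )
        assert abs(draws.var() - 1.0) < 0.08
        assert abs(draws.mean()) < 0.06

    def test_invalid_inputs(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            generate_spatial_factors(coords, 1, -1.0, seed=0)
        with pytest.raises(ValueError):
            generate_spatial_factors(coords[:1], 1, 1.0, seed=0)


class TestOccupancyStates:
    def _params(self, coeffs):
        coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
        return TrueParameters(
            occupancy_coeffs=coeffs,
            detection_coeffs=None,
            factor_loadings=np.zeros((coeffs.shape[0], 0)),
            factor_scores=np.zeros((0, 1)),
        )

    def test_huge_intercept_forces_presence(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        z = generate_occupancy_states(self._params([500.0, 0.0]), X, rng=rng)
        assert np.all(z == 1)

    def test_zero_coefficients_give_half_occupancy(self, rng):
        X = np.column_stack([np.ones(10_000), rng.normal(size=10_000)])
        z = generate_occupancy_states(self._params([0.0, 0.0]), X, rng=rng)
        assert abs(z.mean() - 0.5) < 0.02

    def test_unit_intercept_rate(self, rng):
        X = np.ones((10_000, 1))
        z = generate_occupancy_states(self._params([[1.0]]), X, rng=rng)
        assert abs(z.mean() - expit(1.0)) < 0.02  # expit(1) ~ 0.731

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_occupancy_states(self._params([0.0, 0.0]), np.ones((5, 3)), rng=rng)


class TestDetectionHistories:
    def test_no_false_positives(self):
        cfg = _config(seed=9)
        ds = generate_dataset(cfg)
        absent = ds.truth.latent_z == 0
        assert ds.detections.y[absent].sum() == 0

    def test_certain_detection_of_occupied_sites(self, rng):
        model = ModelConfig(
            occupancy_mains=[], occupancy_interactions=[], include_country=False,
            detection_covariates=["day"], detection_quadratic=[],
        )
        cfg = SimulationConfig(
            n_species=3, n_sites=20, n_visits=2, model=model, seed=0,
            detection_means=np.array([500.0, 0.0]),
            detection_sds=np.zeros(2),
            missing_visit_rate=0.0,
        )
        z = np.ones((3, 20), dtype=np.int8)
        params = generate_community_parameters(cfg)
        V = np.stack([np.ones((20, 2)), np.zeros((20, 2))], axis=-1)
        det = generate_detection_histories(z, V, params, cfg, {}, rng=rng)
        assert np.all(det.y == 1)

    def test_fixed_detection_probability_frequency(self, rng):
        from scipy.special import logit

        model = ModelConfig(
            occupancy_mains=[], occupancy_interactions=[], include_country=False,
            detection_covariates=["day"], detection_quadratic=[],
        )
        cfg = SimulationConfig(
            n_species=1, n_sites=10_000, n_visits=1, model=model, seed=0,
            detection_means=np.array([logit(0.3), 0.0]),
            detection_sds=np.zeros(2),
            missing_visit_rate=0.0,
        )
        z = np.ones((1, 10_000), dtype=np.int8)
        params = generate_community_parameters(cfg)
        V = np.stack([np.ones((10_000, 1)), np.zeros((10_000, 1))], axis=-1)
        det = generate_detection_histories(z, V, params, cfg, {}, rng=rng)
        assert abs(det.y.mean() - 0.3) < 0.02

    def test_masked_visits_are_not_zero_filled_detections(self):
        ds = generate_dataset(_config(seed=12, missing_visit_rate=0.4))
        assert not ds.detections.observed.all()
        assert ds.detections.y[:, ~ds.detections.observed].sum() == 0


class TestDatasetInvariants:
    def test_full_generation_reproducible(self):
        d1 = generate_dataset(_config(seed=21))
        d2 = generate_dataset(_config(seed=21))
        assert d1.site_covariates.equals(d2.site_covariates)
        assert np.array_equal(d1.detections.y, d2.detections.y)
        assert np.array_equal(d1.detections.observed, d2.detections.observed)
        assert np.array_equal(d1.truth.occupancy_coeffs, d2.truth.occupancy_coeffs)
        assert np.array_equal(d1.truth.latent_z, d2.truth.latent_z)

    def test_naive_occupancy_below_true_occupancy(self):
        ds = generate_dataset(_config(n_species=20, n_sites=80, seed=30))
        naive = ds.detections.naive_occupancy()
        true = ds.truth.latent_z.mean(axis=1)
        assert np.all(naive <= true + 1e-12)

    def test_perfect_detection_records_the_true_state(self):
        model = ModelConfig(perfect_detection=True)
        ds = generate_dataset(_config(seed=3, model=model))
        assert ds.detections.n_visits == 1
        assert np.array_equal(ds.detections.y[:, :, 0], ds.truth.latent_z)

    def test_sites_independent_without_spatial_term(self):
        """With no latent factors, occupancy states at two sites are
        independent given covariates (chi-square test not rejected)."""
        model = ModelConfig(
            occupancy_mains=[], occupancy_interactions=[], include_country=False,
            detection_covariates=["day"], detection_quadratic=[], n_factors=0,
        )
        rng = np.random.default_rng(77)
        params = TrueParameters(
            occupancy_coeffs=np.array([[0.3]]),
            detection_coeffs=None,
            factor_loadings=np.zeros((1, 0)),
            factor_scores=np.zeros((0, 2)),
        )
        X = np.ones((2, 1))
        draws = np.array(
            [generate_occupancy_states(params, X, rng=rng)[0] for _ in range(4000)]
        )
        contingency = np.array(
            [
                [(draws[:, 0] == a).__and__(draws[:, 1] == b).sum() for b in (0, 1)]
                for a in (0, 1)
            ]
        )
        _, p, _, _ = chi2_contingency(contingency)
        assert p > 0.01

    def test_mask_shape_validation(self):
        with pytest.raises(ValueError):
            DetectionHistory(
                y=np.zeros((2, 3, 4)), observed=np.ones((2, 4), bool),
                visit_covariates={},
            )
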