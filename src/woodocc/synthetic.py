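"""Synthetic woodland-survey data with the statistical structure the
occupancy analysis assumes.

The generator emulates a two-region chronosequence of small woodland patches
in agricultural landscapes: 0.5-31.9 ha patches, site ages from recent
plantings to ancient woodland, landscape proportions (current/old/lost
woodland, trees outside woodlands, arable fraction) within their published
ranges, repeat visits with imperfect detection, hierarchical
(community-level) species coefficients and a zero-mean spatial
Gaussian-process residual shared across species through factor loadings.
Ground-truth parameters are returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.spatial.distance import cdist
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .model import ModelConfig

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "DetectionHistory",
    "SyntheticDataset",
    "generate_site_covariates",
    "generate_community_parameters",
    "generate_spatial_factors",
    "generate_occupancy_states",
    "generate_detection_histories",
    "generate_visit_covariates",
    "generate_dataset",
]

#: scaled-Beta specifications (lo, hi, a, b) for the proportion covariates
_PROPORTION_SPECS = {
    "current_woodland": (0.005, 0.50, 1.2, 2.5),
    "old_woodland": (0.0, 0.90, 0.8, 1.5),
    "lost_woodland": (0.0, 0.20, 1.0, 3.0),
    "trees_outside": (0.0, 0.15, 1.5, 4.0),
    "arable": (0.0, 0.95, 1.5, 1.5),
}

# Gaussian-copula correlation among (current, old, lost, trees, arable):
# old/lost/trees track current woodland; arable landscapes have less of all
# of them. Gives the VIF screen something real to measure without
# approaching the <2.5 ceiling.
_COPULA_CORR = np.array(
    [
        [1.00, 0.45, 0.30, 0.30, -0.35],
        [0.45, 1.00, 0.20, 0.15, -0.20],
        [0.30, 0.20, 1.00, 0.10, -0.10],
        [0.30, 0.15, 0.10, 1.00, -0.20],
        [-0.35, -0.20, -0.10, -0.20, 1.00],
    ]
)


def _default_occupancy_means(model: ModelConfig) -> np.ndarray:
    means = {"intercept": -0.5}
    out = [means.get(t, 0.3 if ":" not in t and t != "country" else 0.0)
           for t in model.occupancy_terms]
    return np.asarray(out, dtype=float)


def _default_detection_means(model: ModelConfig) -> np.ndarray:
    defaults = {"intercept": 0.4, "day": 0.3, "day^2": -0.3, "year": 0.2, "var4": 0.3}
    return np.asarray([defaults.get(t, 0.2) for t in model.detection_terms], dtype=float)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a mid-sized taxon in the study design: 50 species at 100
    sites split over two regions, 3 visits, ~10% of visits missing, three
    latent spatial factors. ``spatial_decay`` is in 1/km: 0.05/km puts the
    effective GP range (3/decay) at 60 km, i.e. genuine correlation between
    neighbouring sites but independence across regions.
    """

    n_species: int = 50
    n_sites: int = 100
    n_visits: int = 3
    model: ModelConfig = field(default_factory=ModelConfig)
    occupancy_means: np.ndarray | None = None
    occupancy_sds: np.ndarray | None = None
    detection_means: np.ndarray | None = None
    detection_sds: np.ndarray | None = None
    spatial_decay: float = 0.05
    factor_loading_scale: float = 0.5
    missing_visit_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_sites, self.n_visits) <= 0:
            raise ValueError("n_species, n_sites and n_visits must be positive")
        if not (0.0 <= self.missing_visit_rate < 1.0):
            raise ValueError("missing_visit_rate must be in [0, 1)")
        if self.spatial_decay <= 0:
            raise ValueError("spatial_decay must be positive")
        if self.model.n_factors > self.n_species:
            raise ValueError("n_factors cannot exceed n_species")
        self.model.validate()
        if self.occupancy_means is None:
            self.occupancy_means = _default_occupancy_means(self.model)
        if self.occupancy_sds is None:
            self.occupancy_sds = np.full(self.model.n_occupancy_coeffs, 0.5)
            self.occupancy_sds[0] = 1.0
        if self.detection_means is None:
            self.detection_means = _default_detection_means(self.model)
        if self.detection_sds is None:
            self.detection_sds = np.full(self.model.n_detection_coeffs, 0.5)
        self.occupancy_means = np.asarray(self.occupancy_means, dtype=float)
        self.occupancy_sds = np.asarray(self.occupancy_sds, dtype=float)
        self.detection_means = np.asarray(self.detection_means, dtype=float)
        self.detection_sds = np.asarray(self.detection_sds, dtype=float)
        if self.occupancy_means.shape != (self.model.n_occupancy_coeffs,):
            raise ValueError("occupancy_means length must match the model's terms")
        if self.occupancy_sds.shape != (self.model.n_occupancy_coeffs,):
            raise ValueError("occupancy_sds length must match the model's terms")
        if np.any(self.occupancy_sds < 0) or np.any(self.detection_sds < 0):
            raise ValueError("community sds must be non-negative")
        if not self.model.perfect_detection:
            if self.detection_means.shape != (self.model.n_detection_coeffs,):
                raise ValueError("detection_means length must match the model's terms")
            if self.detection_sds.shape != (self.model.n_detection_coeffs,):
                raise ValueError("detection_sds length must match the model's terms")


@dataclass
class TrueParameters:
    """Ground truth behind one synthetic dataset."""

    occupancy_coeffs: np.ndarray  # (S, P_occ)
    detection_coeffs: np.ndarray | None  # (S, P_det) or None if perfect detection
    factor_loadings: np.ndarray  # (S, F)
    factor_scores: np.ndarray  # (F, J)
    latent_z: np.ndarray | None = None  # (S, J) in {0, 1}

    @property
    def spatial_effects(self) -> np.ndarray:
        if self.factor_loadings.size == 0:
            return np.zeros((self.occupancy_coeffs.shape[0], self.factor_scores.shape[-1]))
        return self.factor_loadings @ self.factor_scores


@dataclass
class DetectionHistory:
    """Binary detections y[species, site, visit] with a missing-visit mask.

    ``observed[j, k]`` is False for visits that did not happen; such cells
    carry no information (never coded as zero detections).
    """

    y: np.ndarray  # (S, J, K) int8
    observed: np.ndarray  # (J, K) bool
    visit_covariates: dict[str, np.ndarray]  # raw scale, each (J, K)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.y.ndim != 3:
            raise ValueError("y must be (species, site, visit)")
        if self.observed.shape != self.y.shape[1:]:
            raise ValueError("observed mask must be (site, visit)")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_visits(self) -> int:
        return self.y.shape[2]

    def naive_occupancy(self) -> np.ndarray:
        """Fraction of sites with at least one detection, per species."""
        det = (self.y * self.observed[None, :, :]).max(axis=2)
        return det.mean(axis=1)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    site_covariates: pd.DataFrame  # raw scale
    detections: DetectionHistory
    truth: TrueParameters


def generate_site_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw raw-scale site and landscape covariates for two disjoint regions.

    Areas are log-uniform on [0.5, 31.9] ha (the published patch-size range);
    landscape proportions are scaled Beta draws tied together by a Gaussian
    copula; vegetation structure (sd of tree DBH, cm) grows with site age.
    Deterministic under a fixed seed.
    """
    if config.n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    J = config.n_sites

    n_south = J // 2
    country = np.array([0] * (J - n_south) + [1] * n_south)
    # two disjoint rectangles, km; regions ~150 km apart
    x = np.where(
        country == 0,
        rng.uniform(0.0, 85.0, J),
        rng.uniform(230.0, 320.0, J),
    )
    y = np.where(country == 0, rng.uniform(0.0, 90.0, J), rng.uniform(0.0, 95.0, J))

    age = np.exp(rng.uniform(np.log(10.0), np.log(250.0), J))
    area = np.exp(rng.uniform(np.log(0.5), np.log(31.9), J))
    shape = 1.0 + rng.gamma(2.0, 0.25, J)
    # structure develops with age (site development + management), noisily
    structure = np.clip(
        4.0 + 4.5 * np.log(age / 10.0) + rng.normal(0.0, 2.0, J), 0.5, None
    )

    L = np.linalg.cholesky(_COPULA_CORR)
    latent = rng.standard_normal((J, len(_PROPORTION_SPECS))) @ L.T
    u = norm.cdf(latent)
    props = {}
    for col_idx, (name, (lo, hi, a, b)) in enumerate(_PROPORTION_SPECS.items()):
        props[name] = lo + (hi - lo) * beta_dist.ppf(u[:, col_idx], a, b)

    livestock = rng.gamma(2.0, 0.5, J)  # livestock units per ha of grassland

    table = pd.DataFrame(
        {
            "site_id": np.arange(J),
            "x": x,
            "y": y,
            "country": country,
            "age": age,
            "area": area,
            "shape": shape,
            "structure": structure,
            **props,
            "livestock": livestock,
        }
    )
    return table


def generate_community_parameters(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TrueParameters:
    """Draw species coefficients from the community distributions and factor
    loadings under the lower-triangular unit-diagonal constraint."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    S = config.n_species
    occ = rng.normal(
        config.occupancy_means, config.occupancy_sds, size=(S, config.occupancy_means.size)
    )
    det = None
    if not config.model.perfect_detection:
        det = rng.normal(
            config.detection_means, config.detection_sds, size=(S, config.detection_means.size)
        )
    F = config.model.n_factors
    loadings = rng.normal(0.0, config.factor_loading_scale, size=(S, F))
    for f in range(F):
        loadings[f, f] = 1.0
        loadings[f, f + 1 :] = 0.0
    return TrueParameters(
        occupancy_coeffs=occ,
        detection_coeffs=det,
        factor_loadings=loadings,
        factor_scores=np.zeros((F, config.n_sites)),
    )


def generate_spatial_factors(
    coordinates: np.ndarray,
    n_factors: int,
    spatial_decay: float,
    seed: int | np.random.Generator,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Draw latent factors from a zero-mean GP with exponential correlation
    exp(-decay * distance) and unit marginal variance.

    The covariance square root is taken by symmetric eigendecomposition, so
    coincident sites (a singular correlation matrix at ``jitter=0``) still
    yield draws — with identical scores at the coincident sites.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least two coordinate pairs")
    if spatial_decay <= 0:
        raise ValueError("spatial_decay must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    J = coords.shape[0]
    if n_factors == 0:
        return np.zeros((0, J))
    D = cdist(coords, coords)
    K = np.exp(-spatial_decay * D) + jitter * np.eye(J)
    evals, evecs = np.linalg.eigh(K)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return (root @ rng.standard_normal((J, n_factors))).T


def generate_occupancy_states(
    params: TrueParameters,
    design: np.ndarray,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw the latent presence matrix z ~ Bernoulli(expit(X b' + w))."""
    if rng is None:
        rng = np.random.default_rng(seed)
    B = params.occupancy_coeffs
    X = np.asarray(design, dtype=float)
    if B.shape[1] != X.shape[1]:
        raise ValueError(
            f"coefficient width {B.shape[1]} does not match design width {X.shape[1]}"
        )
    eta = B @ X.T  # (S, J)
    if params.factor_loadings.size:
        eta = eta + params.factor_loadings @ params.factor_scores
    psi = expit(eta)
    return (rng.random(psi.shape) < psi).astype(np.int8)


def generate_visit_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Raw-scale visit covariates: ordinal day uniform over a survey season
    (days 120-200), survey year in {0, 1} per site, and a taxon-specific
    per-site covariate (trap count, 3-15)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    J, K = config.n_sites, config.n_visits
    out: dict[str, np.ndarray] = {}
    for name in config.model.detection_covariates:
        if name == "day":
            out["day"] = np.sort(rng.integers(120, 201, size=(J, K)), axis=1).astype(float)
        elif name == "year":
            out["year"] = np.repeat(rng.integers(0, 2, size=(J, 1)), K, axis=1).astype(float)
        elif name == "var4":
            out["var4"] = np.repeat(rng.integers(3, 16, size=(J, 1)), K, axis=1).astype(float)
        else:
            out[name] = rng.standard_normal((J, K))
    return out


def generate_detection_histories(
    latent_z: np.ndarray,
    detection_design: np.ndarray,
    params: TrueParameters,
    config: SimulationConfig,
    visit_covariates: dict[str, np.ndarray],
    rng: np.random.Generator | None = None,
) -> DetectionHistory:
    """Observe the latent states: y ~ Bernoulli(z * p) per visit, with visits
    dropped at ``missing_visit_rate``. Under perfect detection the single
    'visit' records the true state itself."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 19]))
    z = np.asarray(latent_z)
    S, J = z.shape
    if config.model.perfect_detection:
        y = z[:, :, None].astype(np.int8)
        observed = np.ones((J, 1), dtype=bool)
        return DetectionHistory(y=y, observed=observed, visit_covariates={})
    V = np.asarray(detection_design, dtype=float)  # (J, K, P)
    A = params.detection_coeffs  # (S, P)
    if A is None or A.shape[1] != V.shape[2]:
        raise ValueError("detection coefficients do not match the detection design")
    K = V.shape[1]
    p = expit(np.einsum("sp,jkp->sjk", A, V))
    y = (rng.random((S, J, K)) < p * z[:, :, None]).astype(np.int8)
    observed = rng.random((J, K)) >= config.missing_visit_rate
    y[:, ~observed] = 0
    return DetectionHistory(y=y, observed=observed, visit_covariates=visit_covariates)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full pipeline: covariates -> truth -> latent states -> detections.

    Byte-identical across runs for a fixed ``config.seed``.
    """
    from . import predictors
    from .model import detection_design as build_det_design
    from .model import occupancy_design as build_occ_design

    table = generate_site_covariates(config)
    params = generate_community_parameters(config)
    scaled, transform = predictors.center_scale(
        table, columns=[c for c in table.columns if c not in
                        ("site_id", "x", "y", "country")]
    )
    X, _ = build_occ_design(scaled, config.model)
    if config.model.n_factors > 0:
        coords = table[["x", "y"]].to_numpy()
        params.factor_scores = generate_spatial_factors(
            coords,
            config.model.n_factors,
            config.spatial_decay,
            np.random.default_rng(np.random.SeedSequence([config.seed, 23])),
        )
    z = generate_occupancy_states(
        params, X, rng=np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    )
    params.latent_z = z
    if config.model.perfect_detection:
        detections = generate_detection_histories(z, np.zeros(0), params, config, {})
    else:
        visit_cov = generate_visit_covariates(config)
        V, _ = build_det_design(predictors.scale_visit_covariates(visit_cov), config.model)
        detections = generate_detection_histories(
            z, V, params, config, visit_cov,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 31])),
        )
    return SyntheticDataset(
        config=config, site_covariates=table, detections=detections, truth=params
    )
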