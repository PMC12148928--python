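"""The joint multispecies occupancy model: design matrices, logit-scale
linear predictors, priors, and the observed-data likelihood.

Model structure
---------------
For species i, site j with coordinates s_j, visit k:

    z_ij        ~ Bernoulli(psi_ij)                    latent true occupancy
    logit psi_ij = x_j' b_i + w_i(s_j)
    y_ijk | z   ~ Bernoulli(z_ij * p_ijk)              no false positives
    logit p_ijk  = v_jk' a_i

The occupancy design x_j holds an intercept, the standardized site- and
landscape-scale predictors, products of standardized mains (interactions) and
an unscaled 0/1 country indicator. w_i(s_j) is a low-rank spatial residual,
w_i(s_j) = sum_f lambda_if u_f(s_j), with each latent factor u_f a zero-mean
spatial Gaussian process and loadings lambda constrained lower-triangular
with unit diagonal for identifiability.

Species coefficients are exchangeable draws from community (taxon-level)
normal distributions; community means get Normal(0, 2.7) hyperpriors and
community variances inverse-gamma(0.1, 0.1), the minimally informative
convention for this model family.

With ``perfect_detection`` the detection layer is dropped and the presence
record itself is the Bernoulli outcome (the joint species distribution model
variant used for exhaustively surveyed taxa such as plants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "PriorSpec",
    "occupancy_design",
    "detection_design",
    "occupancy_linear_predictor",
    "detection_linear_predictor",
    "site_likelihood",
    "perfect_detection_likelihood",
    "spatial_effect",
]

#: main-effect predictors of the full occupancy model, in coefficient order
FULL_OCCUPANCY_MAINS = [
    "age",
    "area",
    "shape",
    "structure",
    "current_woodland",
    "old_woodland",
    "lost_woodland",
    "trees_outside",
    "arable",
    "livestock",
]

#: interaction pairs of the full model (products of standardized mains)
FULL_OCCUPANCY_INTERACTIONS = [
    ("area", "shape"),
    ("area", "current_woodland"),
    ("area", "arable"),
    ("shape", "arable"),
    ("age", "current_woodland"),
    ("trees_outside", "current_woodland"),
]


@dataclass
class ModelConfig:
    """Structured model specification; reduced models are first-class.

    ``detection_covariates`` are visit-level column names; any listed in
    ``detection_quadratic`` also contribute a squared term (the square of the
    standardized value), placed immediately after the linear term.
    """

    occupancy_mains: list[str] = field(default_factory=lambda: list(FULL_OCCUPANCY_MAINS))
    occupancy_interactions: list[tuple[str, str]] = field(
        default_factory=lambda: list(FULL_OCCUPANCY_INTERACTIONS)
    )
    include_country: bool = True
    detection_covariates: list[str] = field(default_factory=lambda: ["day", "year", "var4"])
    detection_quadratic: list[str] = field(default_factory=lambda: ["day"])
    n_factors: int = 0
    perfect_detection: bool = False

    @property
    def occupancy_terms(self) -> list[str]:
        terms = ["intercept"] + list(self.occupancy_mains)
        terms += [f"{a}:{b}" for a, b in self.occupancy_interactions]
        if self.include_country:
            terms.append("country")
        return terms

    @property
    def detection_terms(self) -> list[str]:
        terms = ["intercept"]
        for c in self.detection_covariates:
            terms.append(c)
            if c in self.detection_quadratic:
                terms.append(f"{c}^2")
        return terms

    @property
    def n_occupancy_coeffs(self) -> int:
        return len(self.occupancy_terms)

    @property
    def n_detection_coeffs(self) -> int:
        return 0 if self.perfect_detection else len(self.detection_terms)

    def validate(self) -> None:
        for a, b in self.occupancy_interactions:
            for name in (a, b):
                if name not in self.occupancy_mains:
                    raise ValueError(
                        f"interaction term {a}:{b} references {name!r}, "
                        "which is not among the occupancy mains"
                    )
        if self.n_factors < 0:
            raise ValueError("n_factors must be non-negative")


@dataclass
class PriorSpec:
    """Priors for the community (taxon) level.

    ``hyper_mean_sd`` is the sd of the Normal(0, .) hyperprior on community
    coefficient means — 2.7 puts ~95% of intercept mass on occupancy
    probabilities between roughly 0.005 and 0.995, i.e. minimally
    informative on the logit scale. Community variances get
    inverse-gamma(``ig_shape``, ``ig_scale``).
    """

    hyper_mean_sd: float = 2.7
    ig_shape: float = 0.1
    ig_scale: float = 0.1
    loading_sd: float = 1.0

    def validate(self) -> None:
        if min(self.hyper_mean_sd, self.ig_shape, self.ig_scale, self.loading_sd) <= 0:
            raise ValueError("prior scale parameters must be positive")


def occupancy_design(table, config: ModelConfig) -> tuple[np.ndarray, list[str]]:
    """Build the site-level occupancy design matrix (J x P) from a table of
    *already standardized* covariates.

    Interaction columns are products of the standardized mains; the country
    indicator enters unscaled.
    """
    J = len(table)
    cols = [np.ones(J)]
    for name in config.occupancy_mains:
        if name not in table:
            raise KeyError(f"occupancy predictor {name!r} missing from covariates")
        cols.append(table[name].to_numpy(dtype=float))
    for a, b in config.occupancy_interactions:
        cols.append(table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float))
    if config.include_country:
        if "country" not in table:
            raise KeyError("country indicator missing from covariates")
        cols.append(table["country"].to_numpy(dtype=float))
    return np.column_stack(cols), config.occupancy_terms


def detection_design(
    visit_covariates: dict[str, np.ndarray], config: ModelConfig
) -> tuple[np.ndarray, list[str]]:
    """Build the visit-level detection design (J x K x P) from standardized
    visit covariate arrays, each of shape (J, K)."""
    if config.perfect_detection:
        raise ValueError("perfect-detection models have no detection design")
    first = next(iter(visit_covariates.values()))
    J, K = first.shape
    cols = [np.ones((J, K))]
    for name in config.detection_covariates:
        if name not in visit_covariates:
            raise KeyError(f"detection covariate {name!r} missing")
        v = np.asarray(visit_covariates[name], dtype=float)
        cols.append(v)
        if name in config.detection_quadratic:
            cols.append(v**2)
    return np.stack(cols, axis=-1), config.detection_terms


def occupancy_linear_predictor(
    b: np.ndarray, x: np.ndarray, w: float | np.ndarray = 0.0
) -> np.ndarray:
    """eta = x'b + w on the logit scale. ``b`` may be a vector (one species)
    or a (species x P) matrix; ``x`` a design row or (J x P) matrix."""
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    if b.shape[-1] != x.shape[-1]:
        raise ValueError(
            f"coefficient length {b.shape[-1]} does not match design width {x.shape[-1]}"
        )
    eta = x @ b.T if b.ndim > 1 else x @ b
    return eta + w


def detection_linear_predictor(a: np.ndarray, v: np.ndarray) -> np.ndarray:
    """logit(p) = v'a for one or more visit design rows."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    if a.shape[-1] != v.shape[-1]:
        raise ValueError(
            f"coefficient length {a.shape[-1]} does not match design width {v.shape[-1]}"
        )
    return v @ a.T if a.ndim > 1 else v @ a


def spatial_effect(loadings: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """w[i, j] = sum_f loadings[i, f] * scores[f, j]."""
    return np.asarray(loadings) @ np.asarray(scores)


def site_likelihood(
    y: np.ndarray,
    p: np.ndarray,
    psi: float,
    observed: np.ndarray | None = None,
) -> float:
    """Marginal likelihood of one species-site detection history, summing
    over the latent occupancy state.

    If any visit detected the species the site must be occupied:
    L = psi * prod_k p^y (1-p)^(1-y). With no detections the site may be
    occupied-but-missed or unoccupied: L = psi * prod_k (1-p) + (1 - psi).
    Visits with ``observed == False`` contribute a factor of 1.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if observed is None:
        observed = np.ones(y.shape, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    y_o, p_o = y[observed], p[observed]
    if np.any(y_o > 0):
        return float(psi * np.prod(np.where(y_o > 0, p_o, 1.0 - p_o)))
    return float(psi * np.prod(1.0 - p_o) + (1.0 - psi))


def perfect_detection_likelihood(y: int, psi: float) -> float:
    """Bernoulli likelihood psi^y (1-psi)^(1-y) for an exhaustive survey."""
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    return float(psi if y == 1 else 1.0 - psi)
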