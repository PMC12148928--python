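"""Posterior counterfactual assemblage simulation.

Each scenario fixes a small set of landscape drivers at chosen raw-scale
levels (e.g. proportion of woodland cover 0.01 vs 0.3) in a hypothetical
woodland patch of fixed area (default 3.5 ha, the mean patch size), draws
every remaining predictor fresh from its empirical marginal distribution in
the covariate table, computes each species' occupancy probability from one
posterior draw per assemblage, and converts probabilities to
presence/absence by Bernoulli trials. Comparing fixed-driver ensembles to a
'background' ensemble (everything marginal-sampled) shows how much the focal
drivers move richness and composition.

The spatial residual is set to zero in prediction: the hypothetical patch
sits at no particular location. (Switchable to a fresh GP-prior draw.)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import CommunityPosterior
from .model import ModelConfig
from .predictors import StandardizationTransform

__all__ = [
    "ScenarioSpec",
    "AssemblageEnsemble",
    "build_scenario_grid",
    "simulate_assemblages",
    "species_richness",
    "expected_richness",
    "marginal_response_curve",
    "probability_of_direction",
]


@dataclass
class ScenarioSpec:
    """One driver combination. ``fixed_values`` are raw-scale; predictors not
    fixed are drawn from their empirical marginals per assemblage."""

    fixed_values: dict[str, float] = field(default_factory=dict)
    area_ha: float | None = 3.5
    n_draws: int = 20_000
    label: str = "background"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.area_ha is not None and "area" in self.fixed_values:
            raise ValueError("area fixed twice (area_ha and fixed_values)")

    @property
    def all_fixed(self) -> dict[str, float]:
        out = dict(self.fixed_values)
        if self.area_ha is not None:
            out["area"] = self.area_ha
        return out


@dataclass
class AssemblageEnsemble:
    """Binary draw x species presence matrix simulated under one scenario."""

    presence: np.ndarray  # (n_draws, S) in {0, 1}
    label: str
    seed: int

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        uniq = np.unique(self.presence)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("presence matrix must be binary")

    @property
    def n_draws(self) -> int:
        return self.presence.shape[0]


def build_scenario_grid(
    driver_levels: dict[str, tuple[float, float]],
    observed: pd.DataFrame | None = None,
    area_ha: float | None = 3.5,
    n_draws: int = 20_000,
) -> list[ScenarioSpec]:
    """Full factorial over {low, high} levels of 2-3 focal drivers, plus the
    background scenario (empty fixed set) as the last element.

    If ``observed`` is given, any level outside the observed range of its
    covariate is rejected (the counterfactual must stay inside the data).
    """
    if not isinstance(driver_levels, dict):
        pairs = list(driver_levels)
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor in driver grid")
        driver_levels = dict(pairs)
    names = list(driver_levels)
    for name, levels in driver_levels.items():
        if len(levels) != 2:
            raise ValueError(f"driver {name!r} needs exactly (low, high) levels")
        if observed is not None:
            if name not in observed.columns:
                raise KeyError(f"driver {name!r} not in the covariate table")
            lo, hi = observed[name].min(), observed[name].max()
            for lv in levels:
                if not (lo <= lv <= hi):
                    raise ValueError(
                        f"level {lv} of {name!r} is outside the observed "
                        f"range [{lo:.4g}, {hi:.4g}]"
                    )
    scenarios = []
    for combo in itertools.product(*(driver_levels[n] for n in names)):
        fixed = dict(zip(names, combo))
        tags = [
            f"{n}={'high' if v == driver_levels[n][1] else 'low'}"
            for n, v in fixed.items()
        ]
        scenarios.append(
            ScenarioSpec(
                fixed_values=fixed, area_ha=area_ha, n_draws=n_draws,
                label=",".join(tags),
            )
        )
    scenarios.append(
        ScenarioSpec(fixed_values={}, area_ha=area_ha, n_draws=n_draws,
                     label="background")
    )
    return scenarios


def _psi_matrix(
    posterior: CommunityPosterior,
    scenario: ScenarioSpec,
    marginals: pd.DataFrame,
    seed: int,
    transform: StandardizationTransform | None = None,
    model: ModelConfig | None = None,
) -> np.ndarray:
    """Occupancy probabilities (n_draws, S): one posterior draw per row, with
    non-fixed predictors marginal-sampled fresh for each row."""
    model = model or posterior.model
    transform = transform or posterior.transform
    if model is None or transform is None:
        raise ValueError("posterior carries no model/transform; pass them explicitly")
    beta = posterior.beta_flat  # (total, S, P)
    n = scenario.n_draws
    if n > beta.shape[0]:
        raise ValueError(
            f"scenario wants {n} draws but the posterior has only {beta.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    fixed = scenario.all_fixed
    for name in fixed:
        if name not in model.occupancy_mains:
            raise KeyError(f"fixed predictor {name!r} is not in the model")

    # raw-scale main-effect values per assemblage draw
    raw: dict[str, np.ndarray] = {}
    for name in model.occupancy_mains:
        if name in fixed:
            raw[name] = np.full(n, float(fixed[name]))
        else:
            obs_vals = marginals[name].to_numpy(dtype=float)
            raw[name] = obs_vals[rng.integers(0, obs_vals.size, n)]
    scaled = {k: np.asarray(transform.apply_value(k, v), float) for k, v in raw.items()}

    cols = [np.ones(n)]
    for name in model.occupancy_mains:
        cols.append(scaled[name])
    for a, b in model.occupancy_interactions:
        cols.append(scaled[a] * scaled[b])  # recomputed from mains, never sampled
    if model.include_country:
        cvals = marginals["country"].to_numpy(dtype=float)
        cols.append(cvals[rng.integers(0, cvals.size, n)])
    Xs = np.column_stack(cols)  # (n, P)

    # one posterior draw per assemblage, consumed in posterior order
    eta = np.einsum("np,nsp->ns", Xs, beta[:n])
    return expit(eta)


def simulate_assemblages(
    posterior: CommunityPosterior,
    scenario: ScenarioSpec,
    marginals: pd.DataFrame,
    seed: int = 0,
    transform: StandardizationTransform | None = None,
    model: ModelConfig | None = None,
) -> AssemblageEnsemble:
    """Simulate one binary assemblage per posterior draw under a scenario."""
    psi = _psi_matrix(posterior, scenario, marginals, seed, transform, model)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    presence = (rng.random(psi.shape) < psi).astype(np.int8)
    return AssemblageEnsemble(presence=presence, label=scenario.label, seed=seed)


def species_richness(ensemble: AssemblageEnsemble) -> tuple[np.ndarray, int]:
    """Per-assemblage richness (row sums) and the modal value.

    Ties in the richness histogram break to the smallest value.
    """
    if ensemble.presence.size == 0:
        raise ValueError("empty ensemble")
    richness = ensemble.presence.sum(axis=1).astype(int)
    counts = np.bincount(richness)
    mode = int(np.argmax(counts))  # argmax takes the first (smallest) maximum
    return richness, mode


def expected_richness(
    posterior: CommunityPosterior,
    scenario: ScenarioSpec,
    marginals: pd.DataFrame,
    seed: int = 0,
    transform: StandardizationTransform | None = None,
    model: ModelConfig | None = None,
) -> float:
    """Analytic expectation of richness: mean over draws of sum_i psi_i.

    Uses the same covariate stream as :func:`simulate_assemblages` for the
    same seed, so the Monte-Carlo richness mean differs from this value only
    by Bernoulli noise.
    """
    psi = _psi_matrix(posterior, scenario, marginals, seed, transform, model)
    return float(psi.sum(axis=1).mean())


def marginal_response_curve(
    posterior: CommunityPosterior,
    species: int,
    predictor: str,
    grid: np.ndarray,
    marginals: pd.DataFrame,
) -> pd.DataFrame:
    """Marginal occupancy response of one species to one predictor.

    psi(x) = expit(posterior-mean intercept + posterior-mean slope * x_scaled)
    with every other predictor held at its mean (0 on the model scale). The
    grid must stay within the observed range of the predictor. The returned
    frame carries the raw grid, psi, and the slope's probability of
    direction.
    """
    model, transform = posterior.model, posterior.transform
    if predictor not in model.occupancy_mains:
        raise KeyError(f"predictor {predictor!r} is not in the model")
    grid = np.asarray(grid, dtype=float)
    lo, hi = marginals[predictor].min(), marginals[predictor].max()
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid exceeds the observed range [{lo:.4g}, {hi:.4g}] of {predictor!r}"
        )
    terms = model.occupancy_terms
    k = terms.index(predictor)
    b0 = posterior.beta_flat[:, species, 0]
    bk = posterior.beta_flat[:, species, k]
    x_scaled = np.asarray(transform.apply_value(predictor, grid), dtype=float)
    psi = expit(b0.mean() + bk.mean() * x_scaled)
    return pd.DataFrame(
        {
            "x": grid,
            "x_scaled": x_scaled,
            "psi": psi,
            "probability_of_direction": probability_of_direction(bk),
        }
    )


def probability_of_direction(draws: np.ndarray) -> float:
    """Fraction of the posterior sharing the dominant sign, in [0.5, 1].

    Exact zeros are split evenly between the signs; 0.5 means perfectly
    balanced evidence, 1.0 a sign-unanimous posterior.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one draw")
    pos = np.sum(draws > 0) + 0.5 * np.sum(draws == 0)
    frac = pos / draws.size
    return float(max(frac, 1.0 - frac))
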