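# woodocc

Hierarchical Bayesian multispecies occupancy modelling for woodland
biodiversity surveys, with posterior counterfactual assemblage simulation.

`woodocc` is aimed at community ecologists who survey many species across a
network of habitat patches (here: small woodlands embedded in agricultural
landscapes) with repeat visits, and who want to separate the effects of the
**contemporary landscape** (woodland cover around a patch, trees outside
woodlands, agricultural intensity — spatial spillovers) from **historical
legacies** (site age, old and lost woodland in the landscape) on where
species actually occur, while accounting for the fact that a species present
at a site is not always detected.

## The model

Detection (1) or non-detection (0) of species *i* at site *j* on visit *k*
combines a detection process and a latent occupancy process:

```
y_ijk | z_ij ~ Bernoulli(z_ij · p_ijk)
logit(p_ijk) = a0_i + a1_i·day_jk + a2_i·day²_jk + a3_i·year_jk + a4_i·var4_jk

z_ij ~ Bernoulli(ψ_ij)
logit(ψ_i(s_j)) = b0_i + Σ_m b_m,i·x_m,j + Σ interactions + b_country,i·country_j + w_i(s_j)
```

The occupancy design holds four site-scale predictors (age, area, shape
index, vegetation structure), six landscape-scale predictors (proportions of
current / old / lost woodland, trees outside woodlands, arable fraction,
livestock density), six interactions and a country indicator. `w_i(s_j)` is
a low-rank spatial residual shared across species: latent zero-mean spatial
Gaussian-process factors (exponential correlation) with species-specific
loadings, so the model captures residual spatial autocorrelation *and*
among-species correlation at once. Species coefficients are exchangeable
draws from community-level normal distributions (hyperprior mean
Normal(0, 2.7), variances inverse-gamma(0.1, 0.1)). Exhaustively surveyed
taxa (e.g. plants) use a perfect-detection variant in which the single
survey records the occupancy outcome directly.

Fitting is by blocked Gibbs sampling with Pólya-Gamma augmentation of both
logit layers, giving exact full conditionals for every block (see
`docs/methods.md`). Convergence is assessed with rank-normalized split R-hat
(< 1.1), effective sample sizes, and Freeman–Tukey posterior predictive
checks.

Downstream, the package simulates species assemblages from posterior draws
under counterfactual landscape scenarios (focal drivers fixed at low/high
levels, everything else resampled from its empirical marginal), summarises
species richness, and ordinates assemblage composition by 3-axis NMDS on
binary Bray–Curtis dissimilarities with 89% group ellipses.

## Worked example

```python
from woodocc import SimulationConfig, ModelConfig, McmcConfig, generate_dataset, fit_dataset
from woodocc.inference import max_rhat, posterior_predictive_check
from woodocc import scenarios as sc

model = ModelConfig(
    occupancy_mains=["age", "area", "current_woodland", "arable"],
    occupancy_interactions=[("area", "arable")],
    include_country=False,
    detection_covariates=["day", "year"], detection_quadratic=[],
)
config = SimulationConfig(n_species=15, n_sites=60, n_visits=3, model=model, seed=11)
dataset = generate_dataset(config)

posterior = fit_dataset(dataset, McmcConfig(n_chains=4, n_burnin=2000,
                                            n_samples=500, thin=2, seed=5))
print(f"max split R-hat: {max_rhat(posterior):.3f}")
p = posterior_predictive_check(dataset.detections, dataset.site_covariates,
                               posterior, seed=0)
print(f"posterior predictive p-value: {p:.2f}")

table = dataset.site_covariates
levels = {"current_woodland": tuple(table["current_woodland"].quantile([0.1, 0.9]))}
for spec in sc.build_scenario_grid(levels, observed=table, area_ha=3.5, n_draws=2000):
    ens = sc.simulate_assemblages(posterior, spec, table, seed=1)
    richness, mode = sc.species_richness(ens)
    print(f"{spec.label:25s} mean richness {richness.mean():5.2f}  mode {mode}")
```

Output:

```
max split R-hat: 1.013
posterior predictive p-value: 0.31
current_woodland=low      mean richness  5.07  mode 5
current_woodland=high     mean richness  6.04  mode 6
background                mean richness  5.46  mode 5
```

All four chains mix (R-hat well below the 1.1 criterion) and the model fits
its own simulated data (p-value far from 0 and 1). In a hypothetical 3.5-ha
patch, landscapes with high woodland cover support about one extra species
on average relative to low-cover landscapes, with the background (all
drivers at their empirical marginals) in between — the community-mean slope
on woodland cover in this synthetic community is positive, so this is the
expected direction. Ordinating a representative 10% of background
assemblages (`woodocc.composition`) gives a 3-axis NMDS stress of 0.223 on
this small community.

A command-line interface wraps the same stages:

```sh
woodocc simulate --config sim.yaml --out data/ --seed 1
woodocc fit --data data/ --model model.yaml --mcmc mcmc.yaml --out post/
woodocc diagnose --posterior post/ --data data/
woodocc scenario --posterior post/ --data data/ --grid grid.yaml --n 20000 --out ens/
woodocc ordinate --ensembles ens/ --fraction 0.1 --k 3 --out ord/
```

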