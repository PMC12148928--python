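# Methods

## Model

`woodocc` implements a spatial-factor multispecies occupancy model. For
species *i* = 1…S, site *j* = 1…J with coordinates *s_j*, visit *k*:

* latent occupancy `z_ij ~ Bernoulli(ψ_ij)` with
  `logit ψ_ij = x_j' b_i + w_i(s_j)`;
* observation `y_ijk | z ~ Bernoulli(z_ij p_ijk)` with
  `logit p_ijk = v_jk' a_i` (no false positives: a detection implies
  presence);
* spatial residual `w_i(s_j) = Σ_f λ_if u_f(s_j)`, each latent factor
  `u_f ~ GP(0, exp(-φ·d))` with unit marginal variance. The GP amplitude is
  deliberately not a free parameter — it is absorbed into the loadings,
  which carry a N(0, 1) prior and the standard lower-triangular,
  unit-diagonal identifiability constraint on the leading F × F block;
* hierarchy: `b_im ~ N(μ_m, τ_m)` and `a_im ~ N(μ'_m, τ'_m)` per
  coefficient, with `μ ~ N(0, 2.7²)` and `τ ~ InvGamma(0.1, 0.1)`. The
  sd-2.7 hyperprior is stated for intercepts in the source model family and
  is applied here to all coefficient blocks as the minimally informative
  default; every prior scale is overridable through `PriorSpec`.

With `perfect_detection` (exhaustive surveys, e.g. a single botanical
walkover) the detection layer is removed and the recorded presence is the
Bernoulli outcome itself — a joint species distribution model sharing the
occupancy structure.

Missing visits are carried as an explicit boolean mask and contribute a
likelihood factor of 1; they are never coded as zeros.

## Sampler

All conditionals are exact (blocked Gibbs):

1. `z_ij` from its Bernoulli full conditional; forced to 1 where the
   species was detected. With no observed visits the conditional reduces to
   ψ, so unsurveyed sites revert to the occupancy prior.
2. Both logit layers are augmented with Pólya-Gamma variables
   `ω ~ PG(1, η)`, making b, a, λ and u jointly Gaussian given ω. Species
   coefficient blocks are sampled batched (one P×P solve per species);
   factor scores are sampled per factor with a dense J×J GP-precision solve
   (dense is the right tool at ≤ ~150 sites; sparse/NNGP approximations are
   out of scope).
3. Community means and variances from conjugate normal / inverse-gamma
   updates.
4. The spatial decay φ is fixed (default 0.05 km⁻¹, effective range
   3/φ = 60 km), not sampled.

No external Pólya-Gamma sampler is used: `polya_gamma.sample_pg` draws
PG(1, c) from its infinite convolution-of-exponentials representation,
truncated at 64 terms with the omitted tail replaced by its analytic mean
(tail variance decays as K⁻³; the replacement error is ~1e-9). The sampler
is vectorized, chunked to bound memory, and validated in the test suite
against the closed-form PG mean `tanh(c/2)/(2c)` and variance.

Numerical notes: coefficient updates use the precision formulation
(`A = X'ΩX + T⁻¹`, right-hand side `X'(κ − Ω·offset) + T⁻¹μ`) and never
divide by ω, so extreme linear predictors (ω → 0) stay finite. Inverse-gamma
draws are taken as rate/Gamma(shape).

## Diagnostics

Split R-hat is the rank-normalized variant (Vehtari, Gelman, Simpson,
Carpenter & Bürkner 2021), computed through arviz; constant-across-chains
series are reported as 1.0 rather than NaN (a degenerate but converged
chain). ESS is arviz bulk ESS; a constant series returns NaN as a
documented sentinel. `fit` emits a structured `ConvergenceWarning` whenever
any monitored parameter reaches R-hat ≥ 1.1.

Posterior predictive checks simulate replicate detection histories at
retained draws and compare a Freeman–Tukey discrepancy
`Σ (√c − √E[c])²` on species-by-site detection counts between observed and
replicated data (a chi-square discrepancy is also available); the Bayesian
p-value is the fraction of draws where the replicated discrepancy is at
least the observed one. Because the data enter both sides, the check is
mildly conservative — calibration is verified empirically in the test
suite (p ∈ [0.05, 0.95] in ≥ 90% of self-simulated experiments).

## Synthetic data

The generator emulates a two-region woodland chronosequence in agricultural
lowlands. Default study conditions: 50 species, 100 sites split between two
disjoint rectangular regions ~150 km apart, 3 visits, 10% of visits
missing, three latent spatial factors.

* **Patch area**: log-uniform on 0.5–31.9 ha (the published range of the
  survey network). **Shape index**: 1 + Gamma(2, 0.25), ≥ 1 by
  construction. **Age**: log-uniform 10–250 years; **vegetation structure**
  (sd of tree DBH, cm) increases with log-age plus noise, reflecting stand
  development.
* **Landscape proportions** (current woodland, old woodland as a fraction
  of current woodland, lost woodland, trees outside woodlands, arable
  fraction) are scaled Beta draws coupled by a Gaussian copula: old/lost/
  trees-outside track current woodland positively, arable negatively.
  The induced collinearity is mild by design — the VIF screen has something
  real to measure while staying below the 2.5 ceiling.
* **Visit covariates**: ordinal day uniform on a 120–200 day survey
  season, survey year ∈ {0, 1} per site, trap count 3–15 per site (the
  taxon-specific fourth detection covariate). No distributions are
  published for these; the windows are realistic field values.
* **Community coefficients**: species draws around community means
  (default: occupancy intercept −0.5, main-effect means 0.3, interaction
  and country means 0, sds 0.5–1), giving taxa in which most species
  respond positively to woodland in the landscape — a typical, not
  pathological, community.

The generator returns the full ground truth (coefficients, loadings,
factor scores, latent z) for recovery testing, and is byte-identical across
runs at a fixed seed (independent substreams per stage).

What it does **not** emulate: real spatial arrangement of woodland polygons
(proportions are drawn, not measured from maps), species traits or
phylogenetic signal, multi-season dynamics, and observer-level structure
beyond the visit covariates. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to the misspecifications real surveys contain.

## Predictor preparation

The shape index is patch perimeter divided by the perimeter of the
equal-area circle (`P / 2√(πA)`): 1 for a circle, larger for less-compact
patches; sub-isoperimetric inputs are rejected as geometrically impossible.
Continuous predictors are centred and scaled with the sample (n−1) standard
deviation; binary indicators (country, year) keep their 0/1 coding. The
transform is stored (with observed ranges) and reapplied to raw-scale
scenario values, so prediction always uses training statistics.
Interaction columns are products of the *scaled* mains — formed after
scaling, a convention this package fixes because the source text does not
resolve it; likewise the squared ordinal-day term is the square of the
scaled day. VIF is 1/(1−R²) from an auxiliary least-squares regression of
each column on the others; the conventional screen passes below 2.5.

## Scenarios

A scenario fixes 2–3 focal drivers at raw-scale low/high levels in a
hypothetical patch of fixed area (default 3.5 ha, the mean patch size) and
draws every other predictor fresh from its empirical marginal (resampling
observed values — no density fit) for each simulated assemblage. One
posterior draw is consumed per assemblage, in posterior order, so posterior
uncertainty enters exactly once. Interactions are recomputed from the
fixed/sampled mains. The spatial residual is set to 0 — the hypothetical
site has no location; drawing w from the GP prior instead is a documented
switch away. The country indicator is marginal-sampled like other nuisance
predictors. Presence is a Bernoulli trial on ψ; richness is the row sum,
its mode taken with ties broken to the smallest value. Driver levels
outside the observed covariate range are rejected.
`expected_richness` shares the covariate stream with the simulator at equal
seeds, so the Monte-Carlo/analytic comparison isolates Bernoulli noise.

## Composition

Binary Bray–Curtis (Sørensen) dissimilarity `(b+c)/(2a+b+c)` via scipy's
Dice distance; the metric choice is an assumption (the community-standard
default), as the source does not name one. Richness-0 assemblages are
removed before dissimilarity (the index is undefined for a double-empty
pair) with the count logged. NMDS minimizes Kruskal stress-1 with monotone
regression (sklearn smacof), initialized from the classical (Torgerson)
metric-MDS configuration plus random restarts (default 20, tolerance 1e-6),
best solution kept and centred. Ordination runs on a representative random
10% subsample of the simulated assemblages. Group ellipses are
normal-theory contours on the first two axes at the chi-square(2 df) 0.89
quantile.

## Scaled-down protocols

The paper-scale chain protocol (4 chains, 50,000 burn-in, 20,000 posterior
samples at thinning 10) is available as `McmcConfig.paper_protocol()`. The
package's experiments and acceptance script use a desk-scale protocol —
15 species × 60 sites × 3 visits, 4 chains × (2,000 burn-in + 500 kept at
thinning 2) — chosen as the smallest experiment at which convergence,
coverage and calibration are meaningful; richness checks use a cheap
perfect-detection fit with 20,000 retained draws so that each of the
20,000 Bernoulli assemblages still consumes its own posterior draw.

## Limitations

* The spatial decay is fixed, not estimated; misspecifying it biases the
  factor term's range (the loadings partially compensate in amplitude).
* The number of latent factors is a user choice (default 3 in the
  generator); no model-selection machinery is provided.
* Single-season only; no colonization/extinction dynamics.
* PG draws are from a truncated series with tail-mean correction, exact to
  ~1e-9 in distributional moments but not a literal exact sampler.
* The NMDS engine is not bit-compatible with other implementations;
  agreement is at the level of stress values and Procrustes-aligned
  configurations.
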