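# Methods

## Model and conventions

The OU process is parameterized conditionally on the root state
("fixed-root" convention): given Y_r, tip traits are multivariate normal
with common mean `M_OU = θ(1−e^{−αt_H}) + Y_r e^{−αt_H}` and covariance
`Σ_ij = σ² (1−e^{−2αs_ij})/(2α) · e^{−αd_ij}`, where s_ij is the
root-to-MRCA time and d_ij the patristic distance. This convention (rather
than a stationary root) is forced by the mean equation's explicit Y_r
dependence and reproduces both limits exactly: Brownian motion
(Σ_ij → σ² s_ij as α → 0) and white noise (diagonal σ²/(2α) as α → ∞).
All likelihood code requires ultrametric trees (contemporaneous tips);
the θ–Y_r ridge results depend on that assumption.

The Hansen (multi-optimum) mean is the path integral of the piecewise-
constant optimum: each branch b on the root-to-tip path, spanning times
(t_start, t_end] and carrying optimum θ_b, contributes
`θ_b (e^{−α(t_H−t_end)} − e^{−α(t_H−t_start)})`. With a single regime this
telescopes to the OU mean; it is validated against numerical quadrature of
`α ∫ θ(s) e^{−α(t_H−s)} ds` in the tests. Regimes change exactly at nodes:
a branch belongs to one regime.

Numerical switchover: below α·t_H < 1e−8 every formula uses its analytic
BM limit; no 0/0 is ever evaluated. `rho` uses `expm1` and a small-u
series; `rho_inverse` is a Newton iteration on u = 2αt_H with the analytic
derivative (the map is increasing and concave), with a bracketing fallback,
accurate to ~1e−14 and ~2 µs per call — it sits in the samplers' hot path.

## ρ, scales and prior translation

`ρ = 1 − (1−e^{−2αt_H})/(2αt_H)` is the percent reduction of expected tip
variance relative to BM over the tree height; it depends only on α·t_H.
Priors specified on any of the α / t₁⁄₂ / ρ scales are translated with
analytic change-of-variables Jacobians (monotone maps; t₁⁄₂ is decreasing
in α, which flips tail masses). Induced densities are cross-checked in the
tests against Monte-Carlo histograms and against numeric integration to 1.

The two calibrated "extreme" priors are half-Cauchy distributions on α
whose scale is root-found, per tree height, so the induced ρ distribution
has 95% of its mass below 0.12 (Brownian-leaning) or above 0.98
(white-noise-leaning). Calibrating per height, rather than fixing a scale,
keeps the priors' operative content identical across tree sizes; since ρ
depends on α·t_H only, the calibrated scale is proportional to 1/t_H.
The remaining study priors are σ ~ Exponential(mean 10) and
θ, Y_r ~ Normal(0, 5) on scaled traits — deliberately wide, to expose
inter-parameter prior leakage, not to represent good practice.

## The identifiable (ρ, β, V) parameterization

β is the expected tip value (= M_OU) and V the **marginal** model variance
of a single tip (the Σ diagonal), not the expected sample variance; the two
coincide only in the WN limit. The inverse map is α = ρ⁻¹(ρ; t_H),
σ² = 2αV/(1−e^{−2αt_H}) (V/t_H at ρ = 0), mean = β; round trips are exact
to 1e−8 and likelihood equality with the canonical parameterization is
tested to 1e−10. Recovering θ or Y_r from β requires assuming the other
(linear solve); at α = 0 the optimum never enters the mean and is reported
as nonidentifiable.

Reference priors from the sample moments (mean μ, sd s, variance v):
ρ ~ Uniform(0,1); β ~ Normal(μ, 2s); V ~ LogNormal with **mode** v and
log-sd 0.5 (location = ln v + 0.25 — mode, not median; the distinction
moves the prior by a factor e^{0.25}). This V prior puts little mass above
3v. A caveat the study pipeline makes visible: for strongly Brownian data
the true marginal V exceeds v (covariances depress the sample variance),
so the mode-at-v prior pulls V down and ρ up somewhat; with 40 tips the ρ
posterior median for BM-generated data usually sits below ~0.35 but can
reach ~0.5–0.65 for data realizations whose phylogenetic signal happens to
be weak. This is a property of the data and prior, not of the sampler: the
MCMC medians were verified against a dense 3-D quadrature of the
(ρ, β, V) posterior.

## Samplers

`mh_sample` is random-walk Metropolis–Hastings with working transforms
(log for α, σ, V; logit for ρ; identity for θ, Y_r, β), one Gaussian
proposal per free parameter per sweep. Step sizes adapt every 25 proposals
during burn-in only (multiplicative update toward ~30% acceptance, clipped
to [1e−4, 50]) and are frozen afterwards, so the recorded chain is a
genuine Markov chain. Two optional correlated proposals slide along the
known ridges — (θ, Y_r) at constant tip mean, and (log α, log σ) at
constant stationary variance — which is what makes the strongly correlated
posteriors mix; both are symmetric, so they need no Hastings correction
beyond the transform Jacobians. Identical configuration and seed give
bit-identical traces. Degenerate runs fail loudly: a non-finite log
posterior raises immediately with the offending state, and a move type
with zero acceptances over ≥ 2000 post-tuning proposals raises a
diagnostic error.

`rj_hansen_sample` treats the Hansen model as a root regime plus a set of
optimum "shifts" on branches (a shift governs its subtree until a nested
shift). The shift count m has a flat prior on {0..B}, placement is uniform
over subsets, optima are i.i.d. under the θ prior. Birth draws the new
optimum from its prior and death removes a uniformly chosen shift; with
those choices the prior, placement-combinatorics and proposal terms cancel
exactly and the dimension-move acceptance is the bare likelihood ratio.
Birth/death are each attempted with probability 1/2 per sweep (invalid
boundary moves reject), so with the likelihood switched off m performs a
symmetric reflected random walk whose stationary law is exactly uniform —
the prior-recovery test checks this with a chi-square. A relocate move and
random-walk optimum updates complete the move set. m counts shifts; the
root regime always exists, so "m = 0" is the single-optimum OU model and
the sampler then matches `mh_sample` distributionally (KS-tested).

`grid_posterior` is the independent oracle: posterior ∝ likelihood × prior
evaluated on a 2-D rectangular grid, uniform on each parameter's working
scale (so log-spaced for positive parameters), covering 99.95% of each
prior marginal (≥ 99.9% jointly). Cell mass is center density × natural
cell width, normalized with log-sum-exp. Sampler-vs-grid agreement is
measured as total variation after aggregating both to 32×32 cells;
aggregation keeps the Monte-Carlo noise floor of a 50 000-draw histogram
well below the 0.05 agreement bound. When both free parameters only enter
the mean, the Gaussian quadratic form is expanded once and the grid is
vectorized; otherwise the α-keyed Cholesky cache keeps refactorizations to
one per grid row.

`diagnostics` reports autocorrelation-based ESS and split-chain R-hat
(via arviz) plus per-move acceptance rates. Bimodality of a marginal is a
reporting convention, not a model quantity: ≥ 2 local maxima of a
Silverman-bandwidth Gaussian KDE with prominence ≥ 5% of the global
maximum (α and σ are assessed on the log scale).

## Simulators and the synthetic data

Yule and birth–death trees grow by Gillespie simulation from two crown
lineages: exponential waits at rate k(λ+μ), uniform lineage choice, birth
with probability λ/(λ+μ). When the extant count first reaches n, one more
waiting time is drawn and the tree is cut at that moment — terminal
branches therefore have positive length; the mean crown height before
rescaling is exactly Σ_{k=2..n} 1/(kλ) for μ = 0, which the tests check
against 500 replicates. Trees are then rescaled to height 1 (topology and
relative node ages untouched) and, for the study, rejection-sampled until
both root-descendant clades hold at least 3/5/10 tips for n = 10/20/40.
The birth–death simulator shares the Yule code path and random stream
(turnover 0 reproduces the Yule tree seed-for-seed); extinct lineages are
pruned and the tree re-rooted at the extant MRCA. Trait simulation is the
exact branch-wise OU transition (BM transition below the α switchover).

The study design crosses n ∈ {10, 20, 40} with three generating models
sharing σ² = 1 and Y_r = 0 — BM (α = 0), WN-like OU (α = 5, θ = 1;
ρ ≈ 0.90 at height 1) and a two-regime Hansen model (optima −1/+1 painted
on the two root clades) — with replicate trees shared across trait models
within n, and traits normalized to mean 0 / unit variance before fitting
(sample sd with the n−1 denominator; location parameters unscale as
μ + s·x, sds as s·x, variances as s²·x, α/ρ/t₁⁄₂ unchanged). Defaults are
desk-scale: 3 replicates and 20 000 + 2 000 MCMC iterations per fit
(the full 20-replicate, 100 000-iteration protocol and the 300-tip,
birth–death-tree and flat-σ variants are configuration, not code). What
the synthetic data do **not** contain: measurement error, within-species
variation, multivariate traits, non-ultrametric sampling, or tree
misspecification — so passing tests demonstrate correctness of the
inference machinery under the model, not robustness of OU inference on
real data.

## Known limitations

* The σ–α ridge becomes flat only once α times the *shortest* pairwise
  tip distance is large; on Yule trees with short terminal branches the
  likelihood still drifts by a few log units between α·t_H = 10 and 100.
  The flatness property is therefore asserted in the regime
  α·d_min ≳ 20.
* Reversible-jump mixing over m slows on large trees (the shift count is
  a ±1 random walk); summaries thin accordingly.
* The ancestral-state module conditions on the fixed root, so the root's
  own "conditional" is (Y_r, 0) by construction; freeing the root is a
  different model.
* The grid oracle is 2-D by design; it checks marginalizable slices, not
  the full joint posterior.
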