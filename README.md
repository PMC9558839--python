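# ouprior

Bayesian inference for the Ornstein–Uhlenbeck (OU) and Hansen models of
continuous-trait evolution on time-calibrated phylogenies, with a focus on
**prior sensitivity**: tools for translating priors on the selection
strength across scales, for diagnosing the model's likelihood ridges, and
an identifiable reparameterization that behaves well when no prior
information is available.

The package is aimed at comparative biologists fitting OU-family models in
a Bayesian framework (and at methodologists studying why those fits can go
wrong). It is used from Python; `examples/` contains one short narrative
script per capability, and a thin `ouprior` command-line wrapper covers the
common simulate/translate/fit/study workflows.

## The model

On a rooted ultrametric tree of height *t_H*, tip traits **Y** are
multivariate normal. Every tip shares the mean

```
M_OU = θ (1 − e^{−α t_H}) + Y_r e^{−α t_H},
```

where θ is the selective optimum, Y_r the root trait and α ≥ 0 the
selection strength (1/time). The covariance is σ² **C**(T, α) with

```
C_ij = (1 − e^{−2 α s_ij}) / (2α) · e^{−α d_ij},
```

s_ij the root-to-MRCA time of tips i, j and d_ij their patristic distance.
α → 0 gives Brownian motion (BM, covariance σ² s_ij); α → ∞ gives white
noise (WN): independent tips around θ with stationary variance
η = σ²/(2α). The Hansen model lets θ vary across branches ("regime
painting"); only the mean changes.

Two quantities translate α into something interpretable:

* the phylogenetic half-life *t*₁⁄₂ = ln 2 / α, and
* the **realized effect of selection**
  `ρ = 1 − (1 − e^{−2 α t_H}) / (2 α t_H)`,
  the fractional reduction of expected tip variance relative to BM. ρ
  depends only on α·t_H, is 0 at BM and → 1 at WN.

Because θ and Y_r enter the likelihood only through M_OU, and because
σ and α degenerate along σ² = 2αη in the WN regime, the canonical
parameters sit on likelihood ridges. The identifiable triple
**(ρ, β, V)** — realized selection, expected tip value, marginal tip
variance — avoids both ridges and is exposed as a first-class
parameterization with reference priors built from the sample moments.

## Worked example

```python
import math, numpy as np
from ouprior import (OUParams, mh_sample, scale_traits, simulate_traits,
                     simulate_yule, rho)
from ouprior.priors import default_study_priors

tree = simulate_yule(40, math.log(40), seed=11, min_tips_per_root_side=10)
raw = simulate_traits(tree, OUParams(alpha=5.0, sigma2=1.0, theta=1.0,
                                     y_root=0.0), seed=21)
traits = scale_traits(raw)                      # mean 0, unit variance

for kind, priors in default_study_priors(t_H=1.0).items():
    trace = mh_sample(traits, tree, priors, n_iter=20_000, burnin=2_000,
                      seed=1)
    print(kind, np.median(trace["alpha"]))
```

prints

```
BM 4.357660327256791
WN 33.15167938351437
```

The data were generated with α = 5 (ρ ≈ 0.90: selection has removed ~90%
of the BM tip variance). The Brownian-leaning and white-noise-leaning
calibrated priors move the posterior median of α by an order of magnitude,
because at high ρ the likelihood is nearly flat in α and the prior decides.
Running `python examples/reparam_fit.py` fits the same data with the
identifiable (ρ, β, V) parameterization instead and recovers
ρ ≈ 0.91, β ≈ 0.99 and V ≈ 0.08 (truth: 0.90, 0.99, 0.10) under reference
priors.

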