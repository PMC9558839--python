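"""Fit a single-optimum OU model by MCMC and inspect prior sensitivity.

Simulates a 40-tip Yule tree and white-noise-like traits (alpha = 5), then
fits the OU model twice: once under the Brownian-leaning and once under the
white-noise-leaning calibrated alpha prior.  The posterior median of alpha
moves by orders of magnitude with the prior -- the data cannot pin alpha
down once selection has erased most of the phylogenetic signal.
"""

import math

import numpy as np

from ouprior import OUParams, diagnostics, mh_sample, rho, scale_traits, \
    simulate_traits, simulate_yule
from ouprior.priors import default_study_priors

tree = simulate_yule(40, math.log(40), seed=11, min_tips_per_root_side=10)
raw = simulate_traits(tree, OUParams(alpha=5.0, sigma2=1.0, theta=1.0,
                                     y_root=0.0), seed=21)
traits = scale_traits(raw)

for kind, priors in default_study_priors(t_H=1.0).items():
    trace = mh_sample(traits, tree, priors, n_iter=20_000, burnin=2_000,
                      seed=1)
    a = trace["alpha"]
    d = diagnostics(trace, params=["alpha"])
    print(f"{kind} prior: alpha median {np.median(a):8.2f} "
          f"(90% CI {np.quantile(a, 0.05):7.2f} .. {np.quantile(a, 0.95):8.2f}), "
          f"rho(median alpha) = {rho(float(np.median(a)), 1.0):.3f}, "
          f"ESS {d['ess']['alpha']:.0f}")

# True alpha is 5 (rho ~ 0.90). The two priors move the posterior median
# by an order of magnitude and the BM-prior chain mixes poorly (low ESS,
# a bimodal tug-of-war between prior and data): with rho near 1 the
# likelihood is nearly flat in alpha, so the prior decides.
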