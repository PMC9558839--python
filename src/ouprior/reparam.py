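"""Identifiable (rho, beta, V) parameterization of the OU model.

The canonical OU parameters (alpha, sigma^2, theta, Y_r) are plagued by two
likelihood ridges on ultrametric trees: theta and Y_r enter only through the
common tip mean, and sigma and alpha become jointly unidentifiable as the
process approaches white noise.  The triple

    rho   -- realized effect of selection (variance reduction vs BM),
    beta  -- expected tip trait value (the common mean M_OU),
    V     -- marginal variance of a tip trait,

is a bijective, fully identifiable summary of what the tip likelihood
actually depends on:

    alpha  = rho^{-1}(rho; t_H)
    sigma^2 = 2 alpha V / (1 - exp(-2 alpha t_H))   (V / t_H at rho = 0)
    mean   = beta.

theta and Y_r can only be recovered from beta by assuming one of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .oumodel import TraitData, ou_variance, rho, rho_inverse
from .priors import PriorSpec

__all__ = [
    "ReparamParams",
    "to_canonical",
    "from_canonical",
    "deduce_theta_or_root",
    "default_reparam_priors",
]

_ALPHA_T_EPS = 1e-8


@dataclass(frozen=True)
class ReparamParams:
    """Identifiable OU parameters: realized selection, tip mean, tip variance."""

    rho: float
    beta: float
    V: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.V <= 0:
            raise ValueError("V must be > 0")


def to_canonical(p: ReparamParams, t_H: float) -> tuple:
    """Map (rho, beta, V) to (alpha, sigma2, M_OU)."""
    if t_H <= 0:
        raise ValueError("t_H must be > 0")
    alpha = rho_inverse(p.rho, t_H)
    if alpha * t_H < _ALPHA_T_EPS:
        sigma2 = p.V / t_H
    else:
        sigma2 = 2.0 * alpha * p.V / (-math.expm1(-2.0 * alpha * t_H))
    return alpha, sigma2, p.beta


def from_canonical(alpha: float, sigma2: float, theta: float, y_root: float,
                   t_H: float) -> ReparamParams:
    """Map canonical OU parameters to the identifiable triple."""
    if t_H <= 0:
        raise ValueError("t_H must be > 0")
    w = math.exp(-alpha * t_H)
    beta = theta * (1.0 - w) + y_root * w
    return ReparamParams(rho=rho(alpha, t_H), beta=beta,
                         V=ou_variance(alpha, sigma2, t_H))


def deduce_theta_or_root(beta: float, alpha: float, t_H: float,
                         known: tuple) -> float:
    """Solve the tip-mean identity for theta or Y_r given the other.

    `known` is ("theta", value) or ("y_root", value).  At alpha = 0 the
    optimum does not enter the mean at all, so theta cannot be deduced.
    """
    name, value = known
    w = math.exp(-alpha * t_H)
    if name == "theta":
        if w < 1e-300:
            return value  # immediate attraction: beta = theta, Y_r = beta
        return (beta - value * (1.0 - w)) / w
    if name == "y_root":
        if alpha == 0:
            raise ValueError("nonidentifiable at BM limit: theta does not "
                             "affect the mean when alpha = 0")
        return (beta - value * w) / (1.0 - w)
    raise ValueError("known must name 'theta' or 'y_root'")


def default_reparam_priors(traits: TraitData) -> dict:
    """Reference priors for (rho, beta, V) built from the sample moments.

    rho ~ Uniform(0, 1) blends flat (BM-like) and steep (WN-like) trait
    trajectories; beta ~ Normal(sample mean, 2 * sample sd); V ~ LogNormal
    with its mode at the sample variance v and log-scale sd 0.5, which puts
    very little mass above 3v (tip variance exceeding three times the sample
    variance is implausible for any rho).
    """
    x = traits.values.to_numpy()
    if len(x) < 2 or float(np.std(x, ddof=1)) == 0.0:
        raise ValueError("need >= 2 distinct trait values")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    v = sd**2
    sdlog = 0.5
    # lognormal mode exp(loc - sdlog^2) = v  =>  loc = ln v + sdlog^2
    loc = math.log(v) + sdlog**2
    return {
        "rho": PriorSpec("uniform", (0.0, 1.0), scale="rho"),
        "beta": PriorSpec("normal", (mu, 2.0 * sd)),
        "V": PriorSpec("lognormal", (loc, sdlog)),
    }
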