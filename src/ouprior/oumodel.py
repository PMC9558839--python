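"""Ornstein-Uhlenbeck and Hansen trait models on a phylogeny.

The OU model describes a continuous trait attracted toward a selective
optimum theta at rate alpha (1/time), with Brownian noise of rate sigma^2
(trait^2/time), started from a root value Y_r.  Conditional on the root, the
tip traits are multivariate normal with a common mean

    M_OU = theta * (1 - exp(-alpha * t_H)) + Y_r * exp(-alpha * t_H)

and covariance sigma^2 * C(T, alpha), where

    C_ij = (1 - exp(-2 alpha s_ij)) / (2 alpha) * exp(-alpha * d_ij),

s_ij the root-to-MRCA time of tips i and j and d_ij the patristic distance
between them.  The alpha -> 0 limit is Brownian motion (covariance
sigma^2 * s_ij); the alpha -> infinity limit is white noise: independent
tips around theta with stationary variance eta = sigma^2 / (2 alpha).

The Hansen model lets the optimum vary across branches (a "regime
painting"); only the mean changes, the covariance is the OU one.

The realized effect of selection over the tree height is measured by

    rho = 1 - (1 - exp(-2 alpha t_H)) / (2 alpha t_H),

the fractional reduction of expected tip variance relative to Brownian
motion.  rho depends on the product alpha * t_H only, is 0 at the BM limit
and approaches 1 at the white-noise limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import brentq

from .phylo import Phylogeny, shared_times

__all__ = [
    "OUParams",
    "HansenParams",
    "RegimePainting",
    "TraitData",
    "ScalingRecord",
    "ou_mean",
    "ou_variance",
    "ou_covariance",
    "hansen_means",
    "log_likelihood",
    "rho",
    "rho_inverse",
    "half_life",
    "stationary_variance",
    "simulate_traits",
    "scale_traits",
    "unscale_params",
    "ancestral_conditional",
    "read_traits",
    "write_traits",
    "two_regime_painting",
]

# below this value of alpha * t the analytic BM limits are used everywhere
_ALPHA_T_EPS = 1e-8


@dataclass(frozen=True)
class OUParams:
    """Canonical single-optimum OU parameters."""

    alpha: float
    sigma2: float
    theta: float
    y_root: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


@dataclass
class RegimePainting:
    """Assignment of each branch to a selective regime with its optimum.

    ``branch_regime[v]`` is the regime index of the branch above node ``v``
    (the root entry is ignored); ``optima[r]`` is the optimum of regime r.
    """

    branch_regime: np.ndarray
    optima: np.ndarray
    root_regime: int = 0

    def __post_init__(self):
        self.branch_regime = np.asarray(self.branch_regime, dtype=int)
        self.optima = np.asarray(self.optima, dtype=float)

    @property
    def n_regimes(self) -> int:
        return len(self.optima)

    def validate(self, tree: Phylogeny) -> None:
        if len(self.branch_regime) != tree.n_nodes:
            raise ValueError("painting does not cover the tree")
        used = self.branch_regime[np.arange(tree.n_nodes) != tree.root]
        if used.min() < 0 or used.max() >= self.n_regimes:
            raise ValueError("regime index out of range")
        if len(set(used.tolist())) != self.n_regimes:
            raise ValueError("every regime must be realized on >= 1 branch")


@dataclass(frozen=True)
class HansenParams:
    """Multi-optimum OU (Hansen) parameters: painting replaces theta."""

    alpha: float
    sigma2: float
    y_root: float
    painting: RegimePainting


def two_regime_painting(tree: Phylogeny, theta1: float, theta2: float) -> RegimePainting:
    """Paint the two root-descendant clades with optima theta1 / theta2."""
    ch = tree.children[tree.root]
    if len(ch) != 2:
        raise ValueError("root must be bifurcating for a two-clade painting")
    regime = np.zeros(tree.n_nodes, dtype=int)
    stack = [ch[1]]
    while stack:
        v = stack.pop()
        regime[v] = 1
        stack.extend(tree.children[v])
    return RegimePainting(regime, np.array([theta1, theta2]), root_regime=0)


# ---------------------------------------------------------------------------
# Traits and scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingRecord:
    """Affine record of a trait normalization: x_scaled = (x - mu) / s."""

    mu: float
    s: float


@dataclass
class TraitData:
    """Tip trait values (one per species) plus an optional scaling record."""

    values: pd.Series
    scaling: ScalingRecord | None = None

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)

    def vector(self, tree: Phylogeny) -> np.ndarray:
        """Values ordered to match the tree's tip order."""
        labels = tree.tip_labels
        if set(labels) != set(self.values.index):
            raise ValueError("trait labels do not match tree tips")
        return self.values.loc[labels].to_numpy()


def scale_traits(traits: TraitData) -> TraitData:
    """Normalize traits to sample mean 0 and unit variance (n-1 denominator)."""
    x = traits.values
    if len(x) < 2 or float(x.std(ddof=1)) == 0.0:
        raise ValueError("need >= 2 distinct trait values to scale")
    mu, s = float(x.mean()), float(x.std(ddof=1))
    return TraitData((x - mu) / s, ScalingRecord(mu, s))


_LOCATION_PARAMS = {"theta", "y_root", "beta", "mu"}
_SD_PARAMS = {"sigma", "eta_sd"}
_VAR_PARAMS = {"sigma2", "V", "eta"}
_INVARIANT_PARAMS = {"alpha", "rho", "t_half", "m", "lp"}


def unscale_params(params: dict, record: ScalingRecord) -> dict:
    """Map parameters estimated on scaled traits back to the original units.

    Location parameters (theta, Y_r, beta) map as mu + s*x, standard
    deviations scale by s, variances by s^2, and time-scale parameters
    (alpha, rho, t_half) are invariant.
    """
    out = {}
    for k, v in params.items():
        base = k.split(".")[0]
        if base in _LOCATION_PARAMS or base.startswith("theta"):
            out[k] = record.mu + record.s * np.asarray(v)
        elif base in _SD_PARAMS:
            out[k] = record.s * np.asarray(v)
        elif base in _VAR_PARAMS:
            out[k] = record.s**2 * np.asarray(v)
        elif base in _INVARIANT_PARAMS:
            out[k] = v
        else:
            raise KeyError(f"unknown parameter kind: {k}")
    return out


def read_traits(path_or_buffer) -> TraitData:
    """Read a two-column TSV (species<TAB>trait, header required)."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("trait table needs columns: species, trait")
    return TraitData(pd.Series(df.iloc[:, 1].to_numpy(),
                               index=df.iloc[:, 0].astype(str)))


def write_traits(traits: TraitData, path_or_buffer) -> None:
    df = pd.DataFrame({"species": traits.values.index,
                       "trait": traits.values.to_numpy()})
    df.to_csv(path_or_buffer, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def ou_mean(params: OUParams, t_H: float) -> float:
    """Expected tip trait after time `t_H`: the weighted optimum/root blend."""
    if t_H < 0:
        raise ValueError("t_H must be >= 0")
    w = math.exp(-params.alpha * t_H)
    return params.theta * (1.0 - w) + params.y_root * w


def ou_variance(alpha: float, sigma2: float, t: float) -> float:
    """Marginal OU variance after time t, sigma2*(1-exp(-2 alpha t))/(2 alpha)."""
    u = alpha * t
    if u < _ALPHA_T_EPS:
        return sigma2 * t
    return sigma2 * (-math.expm1(-2.0 * u)) / (2.0 * alpha)


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """Tip covariance matrix sigma^2 * C(T, alpha) (fixed-root convention)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not tree.is_ultrametric:
        raise ValueError("ou_covariance requires an ultrametric tree "
                         "(contemporaneous tips)")
    S, _ = shared_times(tree)
    t_H = tree.height
    if alpha * t_H < _ALPHA_T_EPS:
        return sigma2 * S
    D = 2.0 * (t_H - S)
    return sigma2 * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha) * np.exp(-alpha * D)


def hansen_means(tree: Phylogeny, painting: RegimePainting, alpha: float,
                 y_root: float) -> np.ndarray:
    """Per-tip expected values under a regime painting.

    Along the root-to-tip path the optimum is piecewise constant; each branch
    b (from time a to time b above the root, regime optimum theta_b)
    contributes theta_b * (exp(-alpha (t_H - end)) - exp(-alpha (t_H - start)))
    to the tip mean, plus the decayed root term.  With a single regime this
    telescopes to the OU mean.
    """
    painting.validate(tree)
    t_H = tree.height
    t = tree.node_times
    if alpha * t_H < _ALPHA_T_EPS:
        return np.full(tree.n_tips, float(y_root))
    k = np.zeros(tree.n_nodes)
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        th = painting.optima[painting.branch_regime[v]]
        k[v] = k[p] + th * (math.exp(-alpha * (t_H - t[v]))
                            - math.exp(-alpha * (t_H - t[p])))
    return y_root * math.exp(-alpha * t_H) + k[tree.tips]


def _mean_vector(tree: Phylogeny, params) -> np.ndarray:
    if isinstance(params, HansenParams):
        return hansen_means(tree, params.painting, params.alpha, params.y_root)
    return np.full(tree.n_tips, ou_mean(params, tree.height))


def log_likelihood(traits: TraitData, tree: Phylogeny, params) -> float:
    """Multivariate-normal log density of tip traits under OU or Hansen.

    `params` is an :class:`OUParams` or :class:`HansenParams`.
    """
    y = traits.vector(tree)
    m = _mean_vector(tree, params)
    cov = ou_covariance(tree, params.alpha, params.sigma2)
    try:
        cho = sla.cho_factor(cov, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError("singular OU covariance (duplicate tips at "
                         "distance 0?)") from exc
    r = y - m
    quad = float(r @ sla.cho_solve(cho, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    n = len(y)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# rho and friends
# ---------------------------------------------------------------------------

def rho(alpha, t_H: float):
    """Realized effect of selection: fractional tip-variance reduction vs BM.

    Depends on the product alpha*t_H only; 0 at alpha=0, -> 1 as
    alpha*t_H -> infinity.  Vectorized over `alpha`.
    """
    if t_H <= 0:
        raise ValueError("t_H must be > 0")
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0):
        raise ValueError("alpha must be >= 0")
    u = 2.0 * a * t_H
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(u < 1e-12, u / 2.0, 1.0 + np.expm1(-u) / np.where(u == 0, 1.0, u))
    return float(out) if np.isscalar(alpha) else out


def drho_dalpha(alpha, t_H: float):
    """Analytic derivative of rho with respect to alpha (for prior Jacobians)."""
    a = np.asarray(alpha, dtype=float)
    u = 2.0 * a * t_H
    small = u < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        d_du = np.where(
            small,
            0.5 - u / 3.0,
            (-np.expm1(-u)) / np.where(small, 1.0, u**2) - np.exp(-u) / np.where(small, 1.0, u),
        )
    out = 2.0 * t_H * d_du
    return float(out) if np.isscalar(alpha) else out


def _rho_of_u(u: float) -> float:
    """rho as a scalar function of u = 2 alpha t_H."""
    return u / 2.0 if u < 1e-12 else 1.0 + math.expm1(-u) / u


def _drho_du(u: float) -> float:
    if u < 1e-6:
        return 0.5 - u / 3.0
    return (-math.expm1(-u)) / u**2 - math.exp(-u) / u


def rho_inverse(rho_value: float, t_H: float) -> float:
    """Selection strength alpha with the given realized effect on a tree of height t_H.

    Newton iteration on u = 2 alpha t_H with the analytic derivative (the
    map is increasing and concave, so iterates converge fast); a bracketing
    root-find is the fallback for the rare non-convergent corner.
    """
    if t_H <= 0:
        raise ValueError("t_H must be > 0")
    if not 0.0 <= rho_value < 1.0:
        raise ValueError("rho must be in [0, 1); the white-noise boundary "
                         "rho=1 is unreachable at finite alpha")
    if rho_value == 0.0:
        return 0.0
    # asymptotics: rho ~ u/2 for small u, rho ~ 1 - 1/u for large u
    u = 2.0 * rho_value if rho_value < 0.5 else 1.0 / (1.0 - rho_value)
    for _ in range(100):
        f = _rho_of_u(u) - rho_value
        if abs(f) < 1e-14:
            return u / (2.0 * t_H)
        step = f / _drho_du(u)
        u_new = u - step
        if u_new <= 0:
            u_new = u / 2.0
        u = u_new
    lo, hi = 1e-12, 1.0
    while _rho_of_u(hi) < rho_value:
        hi *= 2.0
        if hi > 1e14:
            raise ValueError("rho too close to 1 for a numeric inverse")
    u = float(brentq(lambda x: _rho_of_u(x) - rho_value, lo, hi,
                     xtol=1e-14, rtol=1e-13))
    return u / (2.0 * t_H)


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha; infinite at the BM limit."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return math.inf if alpha == 0 else math.log(2.0) / alpha


def stationary_variance(alpha: float, sigma2: float) -> float:
    """Equilibrium variance eta = sigma^2/(2 alpha); infinite at the BM limit."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return math.inf if alpha == 0 else sigma2 / (2.0 * alpha)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_traits(tree: Phylogeny, params, seed: int | None = None,
                    include_internal: bool = False):
    """Simulate traits branch-wise down the tree (exact OU transition).

    Child given parent is normal with mean
    ``parent*exp(-alpha b) + theta_branch*(1-exp(-alpha b))`` and variance
    ``sigma2*(1-exp(-2 alpha b))/(2 alpha)`` for branch length b; the BM
    transition (mean parent, variance sigma2*b) is used below the alpha
    switchover.  Returns unscaled :class:`TraitData` (and, when
    `include_internal` is set, a dict of internal-node values).
    """
    rng = np.random.default_rng(seed)
    alpha, sigma2 = params.alpha, params.sigma2
    if isinstance(params, HansenParams):
        params.painting.validate(tree)
        theta_of = lambda v: params.painting.optima[params.painting.branch_regime[v]]
    else:
        theta_of = lambda v: params.theta
    x = np.empty(tree.n_nodes)
    x[tree.root] = params.y_root
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        b = tree.blen[v]
        if alpha * b < _ALPHA_T_EPS:
            mean = x[p]
            var = sigma2 * b
        else:
            w = math.exp(-alpha * b)
            mean = x[p] * w + theta_of(v) * (1.0 - w)
            var = sigma2 * (-math.expm1(-2.0 * alpha * b)) / (2.0 * alpha)
        x[v] = mean + math.sqrt(var) * rng.standard_normal() if var > 0 else mean
    td = TraitData(pd.Series(x[tree.tips], index=tree.tip_labels))
    if include_internal:
        internal = {int(v): float(x[v]) for v in range(tree.n_nodes)
                    if tree.children[v]}
        return td, internal
    return td


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------

def _node_shared_times(tree: Phylogeny, nodes_a, nodes_b) -> np.ndarray:
    t = tree.node_times
    anc_cache = {}

    def ancestors(v):
        if v not in anc_cache:
            path = {}
            u = v
            while u != -1:
                path[u] = t[u]
                u = tree.parent[u]
            anc_cache[v] = path
        return anc_cache[v]

    S = np.zeros((len(nodes_a), len(nodes_b)))
    for i, u in enumerate(nodes_a):
        au = ancestors(u)
        for j, v in enumerate(nodes_b):
            w = v
            while w not in au:
                w = tree.parent[w]
            S[i, j] = t[w]
    return S


def _general_cov(tree: Phylogeny, nodes_a, nodes_b, alpha, sigma2) -> np.ndarray:
    """OU covariance between arbitrary (possibly non-contemporaneous) nodes."""
    t = tree.node_times
    S = _node_shared_times(tree, nodes_a, nodes_b)
    ta = t[np.asarray(nodes_a)][:, None]
    tb = t[np.asarray(nodes_b)][None, :]
    if alpha * max(tree.height, 1e-300) < _ALPHA_T_EPS:
        return sigma2 * S
    D = ta + tb - 2.0 * S
    return sigma2 * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha) * np.exp(-alpha * D)


def ancestral_conditional(tree: Phylogeny, params, traits: TraitData) -> pd.DataFrame:
    """Conditional mean and variance of each internal node given the tips.

    Standard Gaussian conditioning of the joint (tips + internal nodes) OU
    distribution, fixed root: the root itself has conditional mean Y_r and
    variance 0.  Returns a DataFrame indexed by node id with columns
    ``time``, ``mean``, ``var``.
    """
    y = traits.vector(tree)
    alpha, sigma2 = params.alpha, params.sigma2
    tips = list(tree.tips)
    internal = [v for v in tree.preorder() if tree.children[v]]
    t = tree.node_times
    t_H = tree.height

    # prior means at each node's own time
    if isinstance(params, HansenParams):
        m_all = np.array([
            _hansen_mean_at_node(tree, params.painting, alpha, params.y_root, v)
            for v in range(tree.n_nodes)
        ])
    elif alpha * t_H < _ALPHA_T_EPS:
        m_all = np.full(tree.n_nodes, params.y_root)
    else:
        w = np.exp(-alpha * t)
        m_all = params.theta * (1.0 - w) + params.y_root * w

    cov_tt = _general_cov(tree, tips, tips, alpha, sigma2)
    nonroot_internal = [v for v in internal if v != tree.root]
    out = {tree.root: (0.0, float(m_all[tree.root]), 0.0)}
    if nonroot_internal:
        cov_it = _general_cov(tree, nonroot_internal, tips, alpha, sigma2)
        cov_ii = _general_cov(tree, nonroot_internal, nonroot_internal, alpha, sigma2)
        cho = sla.cho_factor(cov_tt, lower=True)
        gain = sla.cho_solve(cho, cov_it.T).T  # Sigma_it Sigma_tt^{-1}
        cmean = m_all[nonroot_internal] + gain @ (y - m_all[tips])
        cvar = np.diag(cov_ii - gain @ cov_it.T)
        for idx, v in enumerate(nonroot_internal):
            out[v] = (float(t[v]), float(cmean[idx]), float(max(cvar[idx], 0.0)))
    df = pd.DataFrame.from_dict(out, orient="index", columns=["time", "mean", "var"])
    df.index.name = "node"
    return df.sort_index()


def _hansen_mean_at_node(tree: Phylogeny, painting: RegimePainting, alpha: float,
                         y_root: float, node: int) -> float:
    """Expected value at an internal node under a painting (path integral to the node)."""
    t = tree.node_times
    tv = t[node]
    if alpha * max(tv, 1e-300) < _ALPHA_T_EPS:
        return float(y_root)
    # collect the root->node path
    path = []
    v = node
    while tree.parent[v] != -1:
        path.append(v)
        v = tree.parent[v]
    k = 0.0
    for v in reversed(path):
        p = tree.parent[v]
        th = painting.optima[painting.branch_regime[v]]
        k += th * (math.exp(-alpha * (tv - t[v])) - math.exp(-alpha * (tv - t[p])))
    return y_root * math.exp(-alpha * tv) + k
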