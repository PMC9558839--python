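"""Samplers and posterior oracles for OU models.

Three routes to a posterior live here:

* :func:`mh_sample` -- random-walk Metropolis-Hastings over any subset of
  the canonical (alpha, sigma, theta, Y_r) or identifiable (rho, beta, V)
  parameters, with working transforms (log for positive scales, logit for
  rho) and adaptive step sizes during burn-in only.  Optional correlated
  "ridge" proposals slide along the two known likelihood ridges
  (theta-Y_r at fixed tip mean; log sigma-log alpha at fixed stationary
  variance), which is what makes the strongly correlated posteriors mix.
* :func:`rj_hansen_sample` -- reversible-jump sampler over the number and
  placement of optimum shifts of the Hansen model (birth / death /
  relocate moves with prior-drawn optima, so the dimension-move acceptance
  ratio reduces to the likelihood ratio under the flat shift-count prior).
* :func:`grid_posterior` -- brute-force numerical integration over a 2-D
  grid, used as the independent oracle the samplers are checked against.

:func:`diagnostics` reports autocorrelation-based effective sample sizes
and the split-chain convergence statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .oumodel import TraitData
from .phylo import Phylogeny, shared_times
from .reparam import ReparamParams, to_canonical

__all__ = [
    "Trace",
    "GridPosterior",
    "MCMCError",
    "mh_sample",
    "rj_hansen_sample",
    "grid_posterior",
    "histogram_on_grid",
    "diagnostics",
    "count_modes",
]

_ALPHA_T_EPS = 1e-8

CANONICAL_PARAMS = ("alpha", "sigma", "theta", "y_root")
REPARAM_PARAMS = ("rho", "beta", "V")
_TRANSFORMS = {"alpha": "log", "sigma": "log", "V": "log", "rho": "logit",
               "theta": "id", "y_root": "id", "beta": "id"}


class MCMCError(RuntimeError):
    pass


@dataclass
class Trace:
    """Ordered post-burn-in posterior samples plus run metadata."""

    samples: pd.DataFrame
    acceptance: dict
    seed: int
    n_iter: int
    burnin: int
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[name].to_numpy()


# ---------------------------------------------------------------------------
# Fast likelihood core
# ---------------------------------------------------------------------------

class _OUCore:
    """Caches tree geometry and the Cholesky factor of C(T, alpha)."""

    def __init__(self, tree: Phylogeny, y: np.ndarray):
        if not tree.is_ultrametric:
            raise ValueError("MCMC requires an ultrametric tree")
        S, _ = shared_times(tree)
        self.S = S
        self.tH = tree.height
        self.D = 2.0 * (self.tH - S)
        self.y = np.asarray(y, dtype=float)
        self.n = len(y)
        self._alpha = None
        self._cho = None
        self._logdetC = None

    def _factor(self, alpha: float):
        if self._alpha == alpha:
            return
        if alpha * self.tH < _ALPHA_T_EPS:
            C = self.S
        else:
            C = ((-np.expm1(-2.0 * alpha * self.S)) / (2.0 * alpha)
                 * np.exp(-alpha * self.D))
        try:
            cho = sla.cho_factor(C, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise MCMCError(f"singular covariance at alpha={alpha}") from exc
        self._alpha = alpha
        self._cho = cho
        self._logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

    def loglik(self, alpha: float, sigma2: float, mean) -> float:
        self._factor(alpha)
        r = self.y - mean
        quad = float(r @ sla.cho_solve(self._cho, r, check_finite=False)) / sigma2
        return -0.5 * (self.n * math.log(2.0 * math.pi)
                       + self.n * math.log(sigma2) + self._logdetC + quad)

    def mean_quadratics(self, alpha: float, sigma2: float) -> tuple:
        """(A, b, c, logdet) with loglik(M) = -0.5(n log 2pi + logdet + A - 2Mb + M^2 c)."""
        self._factor(alpha)
        yy = sla.cho_solve(self._cho, self.y, check_finite=False)
        ones = np.ones(self.n)
        oo = sla.cho_solve(self._cho, ones, check_finite=False)
        A = float(self.y @ yy) / sigma2
        b = float(ones @ yy) / sigma2
        c = float(ones @ oo) / sigma2
        logdet = self.n * math.log(sigma2) + self._logdetC
        return A, b, c, logdet


def _canonical_from_state(parameterization: str, x: dict, tH: float) -> tuple:
    """(alpha, sigma2, mean) from a natural-scale state dict."""
    if parameterization == "canonical":
        alpha = x["alpha"]
        sigma2 = x["sigma"] ** 2
        w = math.exp(-alpha * tH)
        mean = x["theta"] * (1.0 - w) + x["y_root"] * w
        return alpha, sigma2, mean
    alpha, sigma2, beta = to_canonical(
        ReparamParams(x["rho"], x["beta"], x["V"]), tH)
    return alpha, sigma2, beta


# ---------------------------------------------------------------------------
# Working transforms
# ---------------------------------------------------------------------------

def _to_working(name: str, x: float) -> float:
    t = _TRANSFORMS[name]
    if t == "log":
        return math.log(x)
    if t == "logit":
        return math.log(x) - math.log1p(-x)
    return x


def _from_working(name: str, z: float) -> float:
    t = _TRANSFORMS[name]
    if t == "log":
        return math.exp(z)
    if t == "logit":
        return 1.0 / (1.0 + math.exp(-z))
    return z


def _log_jacobian(name: str, x: float) -> float:
    """log |dx/dz| of the working transform, evaluated at natural x."""
    t = _TRANSFORMS[name]
    if t == "log":
        return math.log(x)
    if t == "logit":
        return math.log(x) + math.log1p(-x)
    return 0.0


# ---------------------------------------------------------------------------
# Metropolis-Hastings
# ---------------------------------------------------------------------------

_ADAPT_WINDOW = 25
_TARGET_ACC = 0.3


class _StepAdapter:
    def __init__(self, names, init=0.5):
        self.step = {k: init for k in names}
        self.n_prop = {k: 0 for k in names}
        self.n_acc = {k: 0 for k in names}
        self.total_prop = {k: 0 for k in names}
        self.total_acc = {k: 0 for k in names}
        self.frozen = False

    def record(self, name, accepted):
        self.n_prop[name] += 1
        self.n_acc[name] += accepted
        self.total_prop[name] += 1
        self.total_acc[name] += accepted

    def maybe_adapt(self):
        if self.frozen:
            return
        for k in self.step:
            if self.n_prop[k] >= _ADAPT_WINDOW:
                rate = self.n_acc[k] / self.n_prop[k]
                self.step[k] = float(np.clip(
                    self.step[k] * math.exp(rate - _TARGET_ACC), 1e-4, 50.0))
                self.n_prop[k] = self.n_acc[k] = 0

    def rates(self):
        return {k: (self.total_acc[k] / self.total_prop[k]
                    if self.total_prop[k] else math.nan)
                for k in self.step}


def mh_sample(
    traits: TraitData,
    tree: Phylogeny,
    priors: dict,
    *,
    parameterization: str = "canonical",
    fixed: dict | None = None,
    n_iter: int = 20_000,
    burnin: int = 2_000,
    seed: int = 0,
    likelihood: bool = True,
    ridge_moves: bool = True,
    init: dict | None = None,
) -> Trace:
    """Random-walk MH over the free OU parameters.

    `priors` maps each free parameter name to a :class:`~ouprior.priors.PriorSpec`;
    `fixed` pins parameters at constants.  Proposals are Gaussian on the
    working scale (log for alpha / sigma / V, logit for rho), tuned during
    burn-in toward ~30% acceptance and frozen afterwards.  With
    ``likelihood=False`` the sampler targets the prior (used for prior-
    recovery checks).  Runs are deterministic given the seed.
    """
    fixed = dict(fixed or {})
    all_params = CANONICAL_PARAMS if parameterization == "canonical" else REPARAM_PARAMS
    free = [p for p in all_params if p not in fixed]
    missing = [p for p in free if p not in priors]
    if missing:
        raise ValueError(f"missing priors for free parameters: {missing}")
    rng = np.random.default_rng(seed)
    core = _OUCore(tree, traits.vector(tree)) if likelihood else None
    tH = tree.height

    x = dict(fixed)
    for p in free:
        x[p] = float(init[p]) if init and p in init else float(priors[p].ppf(0.5))

    def logpost(state) -> float:
        lp = 0.0
        for p in free:
            lp += float(priors[p].logpdf(state[p]))
        if not math.isfinite(lp):
            return -math.inf
        if likelihood:
            alpha, sigma2, mean = _canonical_from_state(parameterization, state, tH)
            lp += core.loglik(alpha, sigma2, mean)
        return lp

    lp = logpost(x)
    if not math.isfinite(lp):
        raise MCMCError(f"invalid starting state {x}: log posterior {lp}")

    moves = list(free)
    do_ridge_mean = (ridge_moves and parameterization == "canonical"
                     and "theta" in free and "y_root" in free)
    do_ridge_scale = (ridge_moves and parameterization == "canonical"
                      and "alpha" in free and "sigma" in free)
    if do_ridge_mean:
        moves.append("_ridge_mean")
    if do_ridge_scale:
        moves.append("_ridge_scale")
    adapter = _StepAdapter(moves)

    out = {p: np.empty(n_iter) for p in all_params}
    out["lp"] = np.empty(n_iter)

    total = burnin + n_iter
    for it in range(total):
        for p in free:
            z = _to_working(p, x[p])
            z_new = z + adapter.step[p] * rng.standard_normal()
            x_new = dict(x)
            x_new[p] = _from_working(p, z_new)
            lp_new = logpost(x_new)
            log_r = (lp_new + _log_jacobian(p, x_new[p])
                     - lp - _log_jacobian(p, x[p]))
            acc = math.log(rng.random()) < log_r
            if acc:
                x, lp = x_new, lp_new
            adapter.record(p, acc)

        if do_ridge_mean:
            alpha = x.get("alpha", fixed.get("alpha"))
            w = math.exp(-alpha * tH)
            norm = math.hypot(w, 1.0 - w)
            eps = adapter.step["_ridge_mean"] * rng.standard_normal()
            x_new = dict(x)
            x_new["theta"] = x["theta"] + eps * w / norm
            x_new["y_root"] = x["y_root"] - eps * (1.0 - w) / norm
            lp_new = logpost(x_new)
            acc = math.log(rng.random()) < lp_new - lp
            if acc:
                x, lp = x_new, lp_new
            adapter.record("_ridge_mean", acc)

        if do_ridge_scale:
            # slide along log sigma = const + 0.5 log alpha (constant eta)
            eps = adapter.step["_ridge_scale"] * rng.standard_normal()
            x_new = dict(x)
            x_new["alpha"] = x["alpha"] * math.exp(eps)
            x_new["sigma"] = x["sigma"] * math.exp(0.5 * eps)
            lp_new = logpost(x_new)
            log_r = (lp_new + _log_jacobian("alpha", x_new["alpha"])
                     + _log_jacobian("sigma", x_new["sigma"])
                     - lp - _log_jacobian("alpha", x["alpha"])
                     - _log_jacobian("sigma", x["sigma"]))
            acc = math.log(rng.random()) < log_r
            if acc:
                x, lp = x_new, lp_new
            adapter.record("_ridge_scale", acc)

        if not math.isfinite(lp) or math.isnan(lp):
            raise MCMCError(f"non-finite log posterior at state {x}")

        if it < burnin:
            adapter.maybe_adapt()
        else:
            adapter.frozen = True
            k = it - burnin
            for p in all_params:
                out[p][k] = x[p]
            out["lp"][k] = lp

    rates = adapter.rates()
    for p, r in rates.items():
        if adapter.total_prop[p] >= 2000 and r == 0.0:
            raise MCMCError(f"zero acceptance for move {p!r} after tuning; "
                            "the proposal or prior is misconfigured")
    return Trace(pd.DataFrame(out), rates, seed, n_iter, burnin,
                 extras={"free": free, "fixed": fixed,
                         "parameterization": parameterization,
                         "steps": dict(adapter.step)})


# ---------------------------------------------------------------------------
# Reversible-jump Hansen sampler
# ---------------------------------------------------------------------------

def rj_hansen_sample(
    traits: TraitData,
    tree: Phylogeny,
    priors: dict,
    *,
    n_iter: int = 20_000,
    burnin: int = 2_000,
    seed: int = 0,
    likelihood: bool = True,
    fixed: dict | None = None,
    max_shifts: int | None = None,
) -> Trace:
    """Trans-dimensional sampler over optimum shifts of the Hansen model.

    The state is the root-regime optimum plus a set of "shifts": branches
    where a new optimum starts and applies to the subtree below until the
    next shift.  The shift count m has a flat prior on {0..B} (B branches),
    placement is uniform over subsets, and each optimum has the `theta`
    prior.  Birth draws the new optimum from its prior, so the birth/death
    acceptance ratio reduces to the likelihood ratio; with the likelihood
    switched off the m-marginal is exactly uniform.  `priors` needs entries
    alpha, sigma, y_root, theta.
    """
    fixed = dict(fixed or {})
    rng = np.random.default_rng(seed)
    tH = tree.height
    y = traits.vector(tree)
    core = _OUCore(tree, y)
    n_nodes = tree.n_nodes
    root = tree.root
    branches = [v for v in range(n_nodes) if v != root]
    B = len(branches) if max_shifts is None else min(max_shifts, len(branches))
    preorder = tree.preorder()
    parent = tree.parent
    t = tree.node_times
    tips = tree.tips

    cont_names = [p for p in ("alpha", "sigma", "y_root") if p not in fixed]
    for p in cont_names + ["theta"]:
        if p not in priors:
            raise ValueError(f"missing prior for {p!r}")
    theta_prior = priors["theta"]

    x = dict(fixed)
    for p in cont_names:
        x[p] = float(priors[p].ppf(0.5))
    theta0 = float(theta_prior.ppf(0.5))
    shifts: dict = {}

    def mean_vec(alpha, y_root, theta0, shifts) -> np.ndarray:
        if alpha * tH < _ALPHA_T_EPS:
            return np.full(len(tips), y_root)
        eff = np.empty(n_nodes)
        k = np.zeros(n_nodes)
        eff[root] = theta0
        for v in preorder:
            p = parent[v]
            if p < 0:
                continue
            eff[v] = shifts.get(v, eff[p])
            k[v] = k[p] + eff[v] * (math.exp(-alpha * (tH - t[v]))
                                    - math.exp(-alpha * (tH - t[p])))
        return y_root * math.exp(-alpha * tH) + k[tips]

    def loglik(alpha, sigma, y_root, theta0, shifts) -> float:
        if not likelihood:
            return 0.0
        return core.loglik(alpha, sigma**2, mean_vec(alpha, y_root, theta0, shifts))

    def logprior_cont(state) -> float:
        return sum(float(priors[p].logpdf(state[p])) for p in cont_names)

    ll = loglik(x["alpha"], x["sigma"], x["y_root"], theta0, shifts)
    moves = cont_names + ["theta", "birth", "death", "relocate"]
    adapter = _StepAdapter(moves)

    m_out = np.empty(n_iter, dtype=int)
    out = {p: np.empty(n_iter) for p in ("alpha", "sigma", "y_root", "theta0", "lp")}
    theta_draws: list = []

    total = burnin + n_iter
    for it in range(total):
        # continuous shared parameters
        for p in cont_names:
            z = _to_working(p, x[p]) if p in ("alpha", "sigma") else x[p]
            z_new = z + adapter.step[p] * rng.standard_normal()
            x_new = dict(x)
            x_new[p] = (_from_working(p, z_new) if p in ("alpha", "sigma")
                        else z_new)
            lpr_new = float(priors[p].logpdf(x_new[p]))
            if math.isfinite(lpr_new):
                ll_new = loglik(x_new["alpha"], x_new["sigma"], x_new["y_root"],
                                theta0, shifts)
                jac = (_log_jacobian(p, x_new[p]) - _log_jacobian(p, x[p])
                       if p in ("alpha", "sigma") else 0.0)
                log_r = (ll_new + lpr_new + jac
                         - ll - float(priors[p].logpdf(x[p])))
                acc = math.log(rng.random()) < log_r
            else:
                acc = False
            if acc:
                x, ll = x_new, ll_new
            adapter.record(p, acc)

        # optimum updates (root regime + every shift)
        for key in [None] + list(shifts.keys()):
            cur = theta0 if key is None else shifts[key]
            prop = cur + adapter.step["theta"] * rng.standard_normal()
            if key is None:
                ll_new = loglik(x["alpha"], x["sigma"], x["y_root"], prop, shifts)
            else:
                sh = dict(shifts)
                sh[key] = prop
                ll_new = loglik(x["alpha"], x["sigma"], x["y_root"], theta0, sh)
            log_r = (ll_new + float(theta_prior.logpdf(prop))
                     - ll - float(theta_prior.logpdf(cur)))
            acc = math.log(rng.random()) < log_r
            if acc:
                ll = ll_new
                if key is None:
                    theta0 = prop
                else:
                    shifts[key] = prop
            adapter.record("theta", acc)

        # dimension move: birth or death, each chosen with probability 1/2
        m = len(shifts)
        if rng.random() < 0.5:  # birth
            free_branches = [b for b in branches if b not in shifts]
            if free_branches and m < B:
                b_new = free_branches[int(rng.integers(len(free_branches)))]
                th_new = float(theta_prior.rvs(rng=rng))
                sh = dict(shifts)
                sh[b_new] = th_new
                ll_new = loglik(x["alpha"], x["sigma"], x["y_root"], theta0, sh)
                acc = math.log(rng.random()) < ll_new - ll
                if acc:
                    shifts, ll = sh, ll_new
                adapter.record("birth", acc)
        else:  # death
            if m > 0:
                b_del = list(shifts.keys())[int(rng.integers(m))]
                sh = dict(shifts)
                del sh[b_del]
                ll_new = loglik(x["alpha"], x["sigma"], x["y_root"], theta0, sh)
                acc = math.log(rng.random()) < ll_new - ll
                if acc:
                    shifts, ll = sh, ll_new
                adapter.record("death", acc)

        # relocate one shift to a random free branch (placement prior cancels)
        if shifts:
            b_from = list(shifts.keys())[int(rng.integers(len(shifts)))]
            free_branches = [b for b in branches if b not in shifts]
            if free_branches:
                b_to = free_branches[int(rng.integers(len(free_branches)))]
                sh = dict(shifts)
                sh[b_to] = sh.pop(b_from)
                ll_new = loglik(x["alpha"], x["sigma"], x["y_root"], theta0, sh)
                acc = math.log(rng.random()) < ll_new - ll
                if acc:
                    shifts, ll = sh, ll_new
                adapter.record("relocate", acc)

        if it < burnin:
            adapter.maybe_adapt()
        else:
            adapter.frozen = True
            k = it - burnin
            m_out[k] = len(shifts)
            out["alpha"][k] = x["alpha"]
            out["sigma"][k] = x["sigma"]
            out["y_root"][k] = x["y_root"]
            out["theta0"][k] = theta0
            out["lp"][k] = ll + logprior_cont(x)
            theta_draws.append(np.array([theta0] + list(shifts.values())))

    df = pd.DataFrame({"m": m_out, **out})
    return Trace(df, adapter.rates(), seed, n_iter, burnin,
                 extras={"theta_draws": theta_draws, "n_branches": B})


# ---------------------------------------------------------------------------
# Grid-integration posterior oracle
# ---------------------------------------------------------------------------

@dataclass
class GridPosterior:
    """Normalized posterior mass on a rectangular 2-D grid.

    The grid is uniform on each parameter's working scale (log for
    positive-scale parameters), so `edges` are natural-scale cell edges
    that may be log-spaced.
    """

    params: tuple
    centers: tuple
    edges: tuple
    mass: np.ndarray
    log_post: np.ndarray

    def marginal(self, name: str) -> tuple:
        i = self.params.index(name)
        m = self.mass.sum(axis=1 - i)
        return self.centers[i], m

    def mean(self, name: str) -> float:
        c, m = self.marginal(name)
        return float(np.sum(c * m))

    def coarsen(self, factor: int) -> np.ndarray:
        nx, ny = self.mass.shape
        fx, fy = nx // factor, ny // factor
        return (self.mass[: fx * factor, : fy * factor]
                .reshape(fx, factor, fy, factor).sum(axis=(1, 3)))

    def tv(self, other_mass: np.ndarray) -> float:
        if other_mass.shape != self.mass.shape:
            raise ValueError("shape mismatch")
        return 0.5 * float(np.abs(self.mass - other_mass).sum())


def _grid_axis(prior, name: str, n: int, coverage: float):
    tail = (1.0 - coverage) / 2.0
    lo, hi = float(prior.ppf(tail)), float(prior.ppf(1.0 - tail))
    transform = _TRANSFORMS[name]
    if transform in ("log", "logit"):
        lo = max(lo, 1e-12)
        if transform == "logit":
            hi = min(hi, 1.0 - 1e-12)
        z = np.linspace(_to_working(name, lo), _to_working(name, hi), n + 1)
        edges = np.array([_from_working(name, zz) for zz in z])
    else:
        edges = np.linspace(lo, hi, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    return centers, edges, widths


def grid_posterior(
    traits: TraitData,
    tree: Phylogeny,
    free: tuple,
    fixed: dict,
    priors: dict,
    *,
    parameterization: str = "canonical",
    n_grid: int = 128,
    coverage: float = 0.9995,
    likelihood: bool = True,
) -> GridPosterior:
    """Posterior ~ likelihood x prior integrated numerically on a 2-D grid.

    Exactly two parameters are free; the rest are fixed.  The per-axis grid
    covers `coverage` of each free parameter's prior mass (0.9995 each, so
    at least 99.9% jointly).
    """
    if len(free) != 2:
        raise ValueError("grid_posterior needs exactly two free parameters")
    p0, p1 = free
    c0, e0, w0 = _grid_axis(priors[p0], p0, n_grid, coverage)
    c1, e1, w1 = _grid_axis(priors[p1], p1, n_grid, coverage)
    tH = tree.height
    core = _OUCore(tree, traits.vector(tree)) if likelihood else None

    lp0 = np.array([float(priors[p0].logpdf(v)) for v in c0])
    lp1 = np.array([float(priors[p1].logpdf(v)) for v in c1])
    logpost = lp0[:, None] + lp1[None, :]

    if likelihood:
        mean_only = set(free) <= {"theta", "y_root", "beta"}
        if mean_only and parameterization == "canonical":
            alpha = fixed["alpha"]
            sigma2 = fixed["sigma"] ** 2
            A, b, c, logdet = core.mean_quadratics(alpha, sigma2)
            w = math.exp(-alpha * tH)
            G0, G1 = np.meshgrid(c0, c1, indexing="ij")
            vals = {p0: G0, p1: G1}
            th = vals.get("theta", fixed.get("theta"))
            yr = vals.get("y_root", fixed.get("y_root"))
            M = th * (1.0 - w) + yr * w
            logpost += -0.5 * (core.n * math.log(2.0 * math.pi) + logdet
                               + A - 2.0 * M * b + M * M * c)
        else:
            # loop; the alpha-keyed Cholesky cache keeps refactorizations to
            # one per outer row when the outer parameter is alpha-like
            for i in range(n_grid):
                for j in range(n_grid):
                    state = dict(fixed)
                    state[p0], state[p1] = float(c0[i]), float(c1[j])
                    a, s2, mean = _canonical_from_state(parameterization, state, tH)
                    logpost[i, j] += core.loglik(a, s2, mean)

    # cell mass = density at center x natural cell area
    logmass = logpost + np.log(w0)[:, None] + np.log(w1)[None, :]
    logmass -= logsumexp(logmass)
    return GridPosterior((p0, p1), (c0, c1), (e0, e1), np.exp(logmass), logpost)


def histogram_on_grid(trace_or_samples, gp: GridPosterior) -> np.ndarray:
    """Bin MCMC draws of the grid's two parameters onto its cells (normalized)."""
    if isinstance(trace_or_samples, Trace):
        xs = trace_or_samples[gp.params[0]]
        ys = trace_or_samples[gp.params[1]]
    else:
        xs, ys = trace_or_samples
    H, _, _ = np.histogram2d(xs, ys, bins=[gp.edges[0], gp.edges[1]])
    tot = H.sum()
    if tot == 0:
        raise ValueError("no draws fall inside the grid")
    return H / tot


# ---------------------------------------------------------------------------
# Diagnostics and reporting utilities
# ---------------------------------------------------------------------------

def diagnostics(trace: Trace, params: list | None = None) -> dict:
    """Effective sample size, split-chain R-hat and acceptance rates."""
    if len(trace) < 100:
        raise ValueError("trace too short for diagnostics (need >= 100)")
    cols = params or [c for c in trace.samples.columns if c != "lp"]
    ess, rhat = {}, {}
    for c in cols:
        x = trace[c].astype(float)
        n2 = len(x) // 2
        split = x[: 2 * n2].reshape(2, n2)
        ess[c] = float(az.ess(split))
        rhat[c] = float(az.rhat(split))
    return {"ess": ess, "rhat": rhat, "acceptance": trace.acceptance}


def count_modes(draws: np.ndarray, prominence: float = 0.05,
                n_grid: int = 512) -> int:
    """Number of modes of a kernel-density estimate of the draws.

    Gaussian KDE with Silverman's bandwidth; a local maximum counts as a
    mode when its density exceeds `prominence` times the global maximum.
    A reporting convention for flagging bimodal posteriors.
    """
    x = np.asarray(draws, dtype=float)
    if x.std() == 0:
        return 1
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), n_grid)
    d = kde(grid)
    peaks = [i for i in range(1, n_grid - 1)
             if d[i] >= d[i - 1] and d[i] > d[i + 1]]
    top = d.max()
    return sum(1 for i in peaks if d[i] >= prominence * top)
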