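"""Two-rate binary-character (Mk2) model.

The character evolves on a dated tree under a continuous-time Markov chain
with forward rate ``q01`` (state 0 → 1, Myr⁻¹) and backward rate ``q10``,
independently of diversification.  Provided here: the closed-form transition
probabilities, the exact pruning likelihood, a deterministic ML fit, a
Metropolis–Hastings sampler over the rates across a posterior tree sample
(with a hierarchical exponential prior whose mean is itself uniform on
(0, 30), emulating the BayesTraits-style hyperprior), and marginal
ancestral-state reconstruction by the standard up–down pass.

Tip data are a mapping ``species -> {0, 1, None}``; ``None`` marks a species
of unknown state, which contributes the uninformative partial likelihood
(1, 1) and is never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .asr import AncestralStates
from .errors import DataError, ParameterError
from .treeio import Tree

RootPrior = Union[str, Tuple[float, float]]


@dataclass(frozen=True)
class Mk2Params:
    q01: float
    q10: float

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ParameterError("Mk2 rates must be >= 0")


def mk2_transition_prob(q01: float, q10: float, t: float) -> np.ndarray:
    """2×2 transition probability matrix P[i, j] = P(j at time t | i at 0).

    With s = q01 + q10: P(0→0) = (q10 + q01·e^{−st})/s, etc.; s = 0 gives the
    identity.  Rows sum to 1.
    """
    if t < 0:
        raise ParameterError("elapsed time must be >= 0")
    if q01 < 0 or q10 < 0:
        raise ParameterError("rates must be >= 0")
    return _kernels.mk2_prob(q01, q10, t)


def _root_pi(root_prior: RootPrior, q01: float, q10: float) -> Tuple[float, float]:
    if isinstance(root_prior, (tuple, list, np.ndarray)):
        p0, p1 = float(root_prior[0]), float(root_prior[1])
        if p0 < 0 or p1 < 0 or abs(p0 + p1 - 1) > 1e-9:
            raise ParameterError("given root prior must be a distribution")
        return p0, p1
    if root_prior == "equal":
        return 0.5, 0.5
    if root_prior == "stationary":
        s = q01 + q10
        if s <= 0:
            return 0.5, 0.5
        return q10 / s, q01 / s
    raise ParameterError(f"unknown root prior {root_prior!r}")


def tip_partials(tree: Tree, tips: Dict[str, Optional[int]]) -> np.ndarray:
    """(n_nodes, 2) tip partial likelihoods; missing (None) tips get (1, 1).

    Raises :class:`DataError` for a tree tip absent from the table.
    """
    arr = tree.index_arrays()
    D = np.zeros((arr.n_nodes, 2))
    absent = [name for name in arr.tip_index if name not in tips]
    if absent:
        raise DataError(f"tips missing from the state table: {sorted(absent)}")
    for name, i in arr.tip_index.items():
        s = tips[name]
        if s is None:
            D[i] = (1.0, 1.0)
        elif s in (0, 1):
            D[i, int(s)] = 1.0
        else:
            raise DataError(f"state for {name!r} must be 0, 1 or None; got {s!r}")
    return D


def mk2_loglik(tree: Tree, tips: Dict[str, Optional[int]],
               params: Union[Mk2Params, Tuple[float, float]],
               root_prior: RootPrior = "equal") -> float:
    """Exact pruning log-likelihood of the tip data under Mk2."""
    q01, q10 = (params.q01, params.q10) if isinstance(params, Mk2Params) else params
    arr = tree.index_arrays()
    D = tip_partials(tree, tips)
    pi0, pi1 = _root_pi(root_prior, q01, q10)
    lnl, _ = _kernels.mk2_loglik_kernel(arr.left, arr.right, arr.blen, D,
                                        float(q01), float(q10), pi0, pi1)
    return float(lnl)


# --------------------------------------------------------------------- #
# ML fit
# --------------------------------------------------------------------- #

_LOG_LO, _LOG_HI = np.log(1e-9), np.log(1e3)

_STARTS = np.log(np.array([[0.1, 0.1], [1.0, 1.0], [0.01, 0.1],
                           [0.1, 0.01], [0.5, 0.05]]))


def mk2_fit_ml(tree: Tree, tips: Dict[str, Optional[int]],
               root_prior: RootPrior = "equal") -> Tuple[Mk2Params, float]:
    """Deterministic multi-start ML fit of (q01, q10) on log scale.

    Monomorphic data push one rate to the lower bound; a warning is emitted
    and the boundary fit returned.
    """
    arr = tree.index_arrays()
    D = tip_partials(tree, tips)
    observed = {s for s in tips.values() if s is not None}
    if len(observed) < 2:
        warnings.warn("tip states are monomorphic; Mk2 ML fit lies on the "
                      "rate boundary", stacklevel=2)

    def nll(x):
        q01, q10 = np.exp(x)
        pi0, pi1 = _root_pi(root_prior, q01, q10)
        lnl, _ = _kernels.mk2_loglik_kernel(arr.left, arr.right, arr.blen, D,
                                            q01, q10, pi0, pi1)
        return -lnl if np.isfinite(lnl) else 1e10

    best = None
    for x0 in _STARTS:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(_LOG_LO, _LOG_HI)] * 2,
                       options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    q01, q10 = np.exp(best.x)
    return Mk2Params(float(q01), float(q10)), float(-best.fun)


# --------------------------------------------------------------------- #
# MCMC over a tree sample
# --------------------------------------------------------------------- #

@dataclass
class Mk2McmcSettings:
    """Sampler settings.

    ``proposal_width`` is the half-width of the uniform sliding-window move
    on each rate (in rate units, Myr⁻¹) — the analogue of a BayesTraits
    ``ratedev`` tuned to Myr-scaled chronograms.  The prior on each rate is
    Exponential with mean ``m``, where ``m`` is itself a sampled
    hyperparameter with prior Uniform(0, ``hyper_mean_max``).
    """

    generations: int = 50_000
    burnin: int = 5_000
    proposal_width: float = 3.0
    hyper_mean_max: float = 30.0
    hyper_width: float = 3.0
    prior_refresh_prob: float = 0.1
    thin: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.burnin >= self.generations:
            raise ParameterError("burn-in must be smaller than generations")
        if self.proposal_width <= 0 or self.thin < 1:
            raise ParameterError("invalid proposal width or thinning")


@dataclass
class Mk2Posterior:
    """Thinned MCMC sample: one row per retained generation."""

    generation: np.ndarray
    q01: np.ndarray
    q10: np.ndarray
    hyper_mean: np.ndarray
    tree_index: np.ndarray
    loglik: np.ndarray
    burnin: int
    acceptance_rate: float          # sliding-window rate moves only
    refresh_acceptance_rate: float = float("nan")

    def post_burnin(self) -> "Mk2Posterior":
        keep = self.generation >= self.burnin
        return Mk2Posterior(self.generation[keep], self.q01[keep],
                            self.q10[keep], self.hyper_mean[keep],
                            self.tree_index[keep], self.loglik[keep],
                            self.burnin, self.acceptance_rate,
                            self.refresh_acceptance_rate)

    def summary(self) -> Dict[str, Dict[str, float]]:
        pb = self.post_burnin()
        out = {}
        for name, v in (("q01", pb.q01), ("q10", pb.q10)):
            out[name] = {
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "q5": float(np.percentile(v, 5)),
                "q95": float(np.percentile(v, 95)),
            }
        return out


def sample_rate_prior(n: int, rng: np.random.Generator,
                      hyper_mean_max: float = 30.0) -> np.ndarray:
    """Direct draws from the hierarchical prior: q ~ Exp(mean m), m ~ U(0, max)."""
    m = rng.uniform(0.0, hyper_mean_max, size=n)
    return rng.exponential(m)


def mk2_mcmc(trees: Sequence[Tree], tips: Dict[str, Optional[int]],
             settings: Mk2McmcSettings) -> Mk2Posterior:
    """Metropolis–Hastings over (q01, q10) across a tree sample.

    Each generation draws one tree uniformly from the sample and evaluates
    both current and proposed rates on it; rate moves are joint uniform
    sliding-window proposals (negative proposals rejected), and the
    exponential-prior mean is updated by its own window move.  Fully
    reproducible under ``settings.seed``.
    """
    if len(trees) == 0:
        raise ParameterError("need at least one tree")
    rng = np.random.default_rng(settings.seed)
    arrs = [t.index_arrays() for t in trees]
    Ds = [tip_partials(t, tips) for t in trees]
    informative = any(v is not None for v in tips.values())

    def lnl(q01, q10, ti):
        if not informative:
            return 0.0
        a = arrs[ti]
        v, _ = _kernels.mk2_loglik_kernel(a.left, a.right, a.blen, Ds[ti],
                                          q01, q10, 0.5, 0.5)
        return v

    def log_prior(q01, q10, m):
        if q01 < 0 or q10 < 0 or not (0.0 < m < settings.hyper_mean_max):
            return -np.inf
        return -2.0 * np.log(m) - (q01 + q10) / m

    w = settings.proposal_width
    m = rng.uniform(0.0, settings.hyper_mean_max)
    q01 = rng.exponential(m)
    q10 = rng.exponential(m)
    n_keep = settings.generations // settings.thin
    gen_out = np.empty(n_keep, dtype=np.int64)
    q01_out = np.empty(n_keep)
    q10_out = np.empty(n_keep)
    m_out = np.empty(n_keep)
    ti_out = np.empty(n_keep, dtype=np.int64)
    lnl_out = np.empty(n_keep)
    accepted = 0
    n_window = 0
    refreshed = 0
    n_refresh = 0
    kept = 0
    for g in range(settings.generations):
        ti = int(rng.integers(len(trees)))
        cur_lnl = lnl(q01, q10, ti)
        if rng.random() < settings.prior_refresh_prob:
            # independence move drawn from the conditional prior Exp(m);
            # the Hastings ratio then reduces to the likelihood ratio
            n_refresh += 1
            p01 = rng.exponential(m)
            p10 = rng.exponential(m)
            new_lnl = lnl(p01, p10, ti)
            if np.log(rng.random()) < new_lnl - cur_lnl:
                q01, q10, cur_lnl = p01, p10, new_lnl
                refreshed += 1
        else:
            n_window += 1
            p01 = q01 + rng.uniform(-w, w)
            p10 = q10 + rng.uniform(-w, w)
            lp_new = log_prior(p01, p10, m)
            if np.isfinite(lp_new):
                new_lnl = lnl(p01, p10, ti)
                lp_old = log_prior(q01, q10, m)
                if np.log(rng.random()) < (new_lnl + lp_new) - (cur_lnl + lp_old):
                    q01, q10, cur_lnl = p01, p10, new_lnl
                    accepted += 1
        # hyperparameter move (prior-only Metropolis step)
        pm = m + rng.uniform(-settings.hyper_width, settings.hyper_width)
        if np.isfinite(log_prior(q01, q10, pm)):
            if np.log(rng.random()) < (log_prior(q01, q10, pm)
                                       - log_prior(q01, q10, m)):
                m = pm
        if (g + 1) % settings.thin == 0 and kept < n_keep:
            gen_out[kept] = g + 1
            q01_out[kept] = q01
            q10_out[kept] = q10
            m_out[kept] = m
            ti_out[kept] = ti
            lnl_out[kept] = cur_lnl
            kept += 1
    return Mk2Posterior(gen_out[:kept], q01_out[:kept], q10_out[:kept],
                        m_out[:kept], ti_out[:kept], lnl_out[:kept],
                        burnin=settings.burnin,
                        acceptance_rate=accepted / max(n_window, 1),
                        refresh_acceptance_rate=refreshed / max(n_refresh, 1))


# --------------------------------------------------------------------- #
# marginal ancestral states
# --------------------------------------------------------------------- #

def mk2_asr_marginal(tree: Tree, tips: Dict[str, Optional[int]],
                     params: Union[Mk2Params, Tuple[float, float]],
                     root_prior: RootPrior = "equal") -> AncestralStates:
    """Marginal P(state) per internal node via the up–down (inside–outside)
    pass; probabilities renormalized per node.  The root is included (keyed by
    the full tip set)."""
    q01, q10 = (params.q01, params.q10) if isinstance(params, Mk2Params) else params
    arr = tree.index_arrays()
    D = tip_partials(tree, tips)
    pi = np.array(_root_pi(root_prior, q01, q10))
    lnl, partials = _kernels.mk2_loglik_kernel(
        arr.left, arr.right, arr.blen, D, float(q01), float(q10), pi[0], pi[1])
    if not np.isfinite(lnl):
        raise DataError("zero likelihood: data incompatible with the tree")
    n = arr.n_nodes
    parent = np.full(n, -1, dtype=int)
    sibling = np.full(n, -1, dtype=int)
    for i in range(n):
        if arr.left[i] >= 0:
            parent[arr.left[i]] = i
            parent[arr.right[i]] = i
            sibling[arr.left[i]] = arr.right[i]
            sibling[arr.right[i]] = arr.left[i]
    G = np.zeros((n, 2))
    root = n - 1
    G[root] = pi
    for i in range(n - 2, -1, -1):      # preorder = reverse postorder
        u, w = parent[i], sibling[i]
        Pw = mk2_transition_prob(q01, q10, float(arr.blen[w]))
        wsib = Pw @ partials[w]
        S = G[u] * wsib
        Pv = mk2_transition_prob(q01, q10, float(arr.blen[i]))
        G[i] = S @ Pv
    probs = {}
    for i, bp in arr.bipartitions.items():
        m = G[i] * partials[i]
        tot = m.sum()
        probs[bp] = m / tot
    return AncestralStates(probs=probs)
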