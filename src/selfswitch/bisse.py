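"""Binary State Speciation and Extinction (BiSSE) likelihood and model suite.

The BiSSE model couples a binary character (state O = 0, outcrossing;
S = 1, selfing) to diversification: each state carries its own speciation
rate λ, extinction rate μ, and transition rate q away from it.  The joint
likelihood of a dated tree and tip states is computed by integrating, along
each branch (time running rootward), the coupled ODEs

    dE_i/dt = μ_i − (λ_i + μ_i + q_i)·E_i + λ_i·E_i² + q_i·E_j
    dD_i/dt = −(λ_i + μ_i + q_i)·D_i + q_i·D_j + 2·λ_i·E_i·D_i

where E_i is the probability that a lineage in state i leaves no sampled
descendant and D_i the likelihood density of the observed subtree.  At an
internal node D_i ← λ_i·D_i(left)·D_i(right); at the root the two states are
combined by a weighting (default: proportional to the D values) and, when
conditioning on survival is on (default), divided by the weighted survival
term Σ w_i·λ_i·(1 − E_root,i)².

Model comparison follows a fixed 13-model suite: the full six-parameter
model, three equality constraints, six single zero-constraints, and three
nested multi-zero models culminating in the irreversible, extinction-free
two-parameter model (λ_S = 0, μ_O = μ_S = 0, q_SO = 0).  Fits run per tree
across a posterior sample and are summarized by medians; constrained models
are additionally tested against the full model by per-tree likelihood-ratio
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from . import _kernels
from .asr import AncestralStates
from .errors import ConvergenceError, DataError, ParameterError
from .params import PARAM_NAMES, BisseParams
from .treeio import BranchingTimes, Tree, branching_times

__all__ = [
    "BisseParams", "BisseConstraint", "BisseOptions", "MODEL_SUITE",
    "bisse_loglik", "bisse_fit", "bisse_fit_one", "bisse_model_suite",
    "bisse_asr_marginal",
    "bisse_param_distributions", "bisse_starting_point", "lrt",
]

_RATE_LO = 1e-9
_RATE_HI = 1e2
_LOG_LO, _LOG_HI = np.log(_RATE_LO), np.log(_RATE_HI)


@dataclass(frozen=True)
class BisseOptions:
    """Likelihood options.

    root
        "obs" (weights ∝ root D values, default), "flat" (0.5/0.5) or
        "given" (supply ``root_pi``).
    condition_on_survival
        Divide by the weighted probability that both root lineages survive.
    sampling_f
        Per-state sampling fractions (f_O, f_S); 1.0 means complete sampling.
    """

    root: str = "obs"
    condition_on_survival: bool = True
    sampling_f: Tuple[float, float] = (1.0, 1.0)
    root_pi: Optional[Tuple[float, float]] = None
    rtol: float = 1e-8
    atol: float = 1e-10

    def root_mode(self) -> Tuple[int, float, float]:
        if self.root == "obs":
            return _kernels.ROOT_OBS, 0.5, 0.5
        if self.root == "flat":
            return _kernels.ROOT_FLAT, 0.5, 0.5
        if self.root == "given":
            if self.root_pi is None:
                raise ParameterError("root='given' requires root_pi")
            return _kernels.ROOT_GIVEN, float(self.root_pi[0]), float(self.root_pi[1])
        raise ParameterError(f"unknown root weighting {self.root!r}")


DEFAULT_OPTIONS = BisseOptions()


def _tip_arrays(tree: Tree, tips: Dict[str, Optional[int]],
                sampling_f: Tuple[float, float]):
    arr = tree.index_arrays()
    f0, f1 = sampling_f
    if not (0 < f0 <= 1 and 0 < f1 <= 1):
        raise ParameterError("sampling fractions must be in (0, 1]")
    tipE = np.zeros((arr.n_nodes, 2))
    tipD = np.zeros((arr.n_nodes, 2))
    absent = [n for n in arr.tip_index if n not in tips]
    if absent:
        raise DataError(f"tips missing from the state table: {sorted(absent)}")
    for name, i in arr.tip_index.items():
        tipE[i] = (1.0 - f0, 1.0 - f1)
        s = tips[name]
        if s is None:
            tipD[i] = (f0, f1)
        elif s in (0, 1):
            tipD[i, int(s)] = (f0, f1)[int(s)]
        else:
            raise DataError(f"state for {name!r} must be 0, 1 or None; got {s!r}")
    return arr, tipE, tipD


def bisse_loglik(tree: Tree, tips: Dict[str, Optional[int]],
                 params: BisseParams,
                 options: BisseOptions = DEFAULT_OPTIONS) -> float:
    """BiSSE log-likelihood of (tree, tip states) under ``params``."""
    arr, tipE, tipD = _tip_arrays(tree, tips, options.sampling_f)
    mode, pi0, pi1 = options.root_mode()
    lnl, _ = _kernels.bisse_loglik_kernel(
        arr.left, arr.right, arr.blen, tipE, tipD, params.as_array(),
        mode, pi0, pi1, options.condition_on_survival,
        -1, 0, options.rtol, options.atol)
    return float(lnl)


# --------------------------------------------------------------------- #
# constraints and the Table-4 style suite
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class BisseConstraint:
    """Equality ties and zero-fixes on the six BiSSE rates.

    ``ties`` is a tuple of name-pairs forced equal (sharing one free
    parameter); ``zeros`` is a tuple of names fixed to exactly 0.  The free
    parameter count is 6 − #ties − #zeros (zero-fixes on tied parameters are
    rejected to keep the counting unambiguous).
    """

    name: str
    ties: Tuple[Tuple[str, str], ...] = ()
    zeros: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tied = [n for pair in self.ties for n in pair]
        for n in tied + list(self.zeros):
            if n not in PARAM_NAMES:
                raise ParameterError(f"unknown parameter {n!r}")
        if set(tied) & set(self.zeros):
            raise ParameterError("cannot tie and zero-fix the same parameter")
        if len(set(tied)) != len(tied):
            raise ParameterError("a parameter may appear in one tie only")

    @property
    def n_free(self) -> int:
        return 6 - len(self.ties) - len(self.zeros)

    def free_names(self) -> List[str]:
        drop = set(self.zeros) | {b for _, b in self.ties}
        return [n for n in PARAM_NAMES if n not in drop]

    def expand(self, free: np.ndarray) -> np.ndarray:
        """Map a free-parameter vector to the full six-rate vector."""
        vals = dict(zip(self.free_names(), free))
        for z in self.zeros:
            vals[z] = 0.0
        for a, b in self.ties:
            vals[b] = vals[a]
        return np.array([vals[n] for n in PARAM_NAMES])

    def reduce(self, full: np.ndarray) -> np.ndarray:
        d = dict(zip(PARAM_NAMES, full))
        return np.array([d[n] for n in self.free_names()])


def _c(name, ties=(), zeros=()):
    return BisseConstraint(name=name, ties=ties, zeros=zeros)


#: the 13 models of the study's suite: full; three equality constraints; six
#: single zero-fixes; three nested multi-zero models.
MODEL_SUITE: Tuple[BisseConstraint, ...] = (
    _c("full"),
    _c("lamO=lamS", ties=(("lam_o", "lam_s"),)),
    _c("muO=muS", ties=(("mu_o", "mu_s"),)),
    _c("qOS=qSO", ties=(("q_os", "q_so"),)),
    _c("lamO=0", zeros=("lam_o",)),
    _c("lamS=0", zeros=("lam_s",)),
    _c("muO=0", zeros=("mu_o",)),
    _c("muS=0", zeros=("mu_s",)),
    _c("qOS=0", zeros=("q_os",)),
    _c("qSO=0", zeros=("q_so",)),
    _c("lamS=0,muO=0", zeros=("lam_s", "mu_o")),
    _c("lamS=0,muO=0,qSO=0", zeros=("lam_s", "mu_o", "q_so")),
    _c("lamS=0,muO=0,muS=0,qSO=0", zeros=("lam_s", "mu_o", "mu_s", "q_so")),
)

SUITE_BY_NAME = {c.name: c for c in MODEL_SUITE}


# --------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------- #

def bisse_starting_point(tree: Tree, tips: Dict[str, Optional[int]]) -> BisseParams:
    """Heuristic start from the state-independent birth–death model.

    λ and μ come from a BD fit to the branching times (replicated to both
    states); the transition rates from a parsimony-style estimate, the
    minimal number of state changes divided by total tree length.
    """
    from .diversification import fit_bd

    fitbd = fit_bd(branching_times(tree))
    r, a = fitbd.params["r1"], fitbd.params["a"]
    lam = max(r / (1.0 - a), 1e-4)
    mu = max(a * lam, 1e-6)
    changes = _parsimony_changes(tree, tips)
    tl = float(sum(e.length or 0.0 for e in
                   tree.dendropy_tree.preorder_edge_iter()))
    q = max(changes / tl if tl > 0 else 0.1, 1e-3)
    return BisseParams(lam, lam, mu, mu, q, q)


def _parsimony_changes(tree: Tree, tips: Dict[str, Optional[int]]) -> int:
    """Fitch parsimony count of binary-state changes (missing tips = {0,1})."""
    arr = tree.index_arrays()
    sets: List[frozenset] = [frozenset()] * arr.n_nodes
    changes = 0
    inv = {i: n for n, i in arr.tip_index.items()}
    for i in range(arr.n_nodes):
        if arr.left[i] < 0:
            s = tips.get(inv[i])
            sets[i] = frozenset({0, 1}) if s is None else frozenset({int(s)})
        else:
            a, b = sets[arr.left[i]], sets[arr.right[i]]
            inter = a & b
            if inter:
                sets[i] = inter
            else:
                sets[i] = a | b
                changes += 1
    return changes


@dataclass
class BisseFit:
    """ML fit of one constrained model on one tree."""

    params: BisseParams
    lnl: float
    n_free: int
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.lnl


def bisse_fit_one(tree: Tree, tips: Dict[str, Optional[int]],
                  constraint: BisseConstraint = SUITE_BY_NAME["full"],
                  options: BisseOptions = DEFAULT_OPTIONS,
                  start: Optional[BisseParams] = None,
                  n_restarts: int = 3) -> BisseFit:
    """ML fit of one model on one tree (log-scale bounded quasi-Newton with
    deterministic jittered restarts around the BD-based heuristic start)."""
    arr, tipE, tipD = _tip_arrays(tree, tips, options.sampling_f)
    mode, pi0, pi1 = options.root_mode()
    cond = options.condition_on_survival
    p = params_buf = np.empty(6)

    def nll(x):
        full = constraint.expand(np.exp(x))
        lnl, _ = _kernels.bisse_loglik_kernel(
            arr.left, arr.right, arr.blen, tipE, tipD, full, mode, pi0, pi1,
            cond, -1, 0, options.rtol, options.atol)
        return -lnl if np.isfinite(lnl) else 1e10

    if start is None:
        start = bisse_starting_point(tree, tips)
    x0 = np.log(np.clip(constraint.reduce(start.as_array()),
                        _RATE_LO * 10, _RATE_HI / 10))
    jit = np.array([0.0, 0.7, -0.7])
    best = None
    for j in range(max(1, n_restarts)):
        res = minimize(nll, x0 + jit[j % 3], method="L-BFGS-B",
                       bounds=[(_LOG_LO, _LOG_HI)] * len(x0),
                       options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    full = constraint.expand(np.exp(best.x))
    ok = bool(best.success) and best.fun < 1e9
    return BisseFit(params=BisseParams.from_array(full), lnl=float(-best.fun),
                    n_free=constraint.n_free, converged=ok)


@dataclass
class BisseFitSummary:
    """Per-tree ML fits of one model across a tree sample, with medians."""

    constraint: BisseConstraint
    per_tree: pd.DataFrame        # columns: six rates, lnl, aic, converged
    n_failed: int

    @property
    def medians(self) -> Dict[str, float]:
        ok = self.per_tree[self.per_tree.converged]
        return {c: float(ok[c].median())
                for c in list(PARAM_NAMES) + ["lnl", "aic"]}

    def percentiles(self, qs=(2.5, 50, 97.5)) -> pd.DataFrame:
        ok = self.per_tree[self.per_tree.converged]
        rows = {c: np.percentile(ok[c], qs) for c in PARAM_NAMES}
        return pd.DataFrame(rows, index=[f"p{q}" for q in qs])


def bisse_fit(trees: Union[Tree, Sequence[Tree]], tips: Dict[str, Optional[int]],
              constraint: BisseConstraint = SUITE_BY_NAME["full"],
              options: BisseOptions = DEFAULT_OPTIONS,
              n_restarts: int = 3) -> BisseFitSummary:
    """Fit one constrained model by ML on every tree of a sample."""
    if isinstance(trees, Tree):
        trees = [trees]
    if len(trees) == 0:
        raise ParameterError("need at least one tree")
    rows = []
    n_failed = 0
    for ti, tree in enumerate(trees):
        fit = bisse_fit_one(tree, tips, constraint, options,
                            n_restarts=n_restarts)
        if not fit.converged:
            n_failed += 1
        row = dict(zip(PARAM_NAMES, fit.params.as_array()))
        row.update(tree_index=ti, lnl=fit.lnl, aic=fit.aic,
                   converged=fit.converged)
        rows.append(row)
    return BisseFitSummary(constraint=constraint,
                           per_tree=pd.DataFrame(rows), n_failed=n_failed)


# --------------------------------------------------------------------- #
# LRT and the ranked suite
# --------------------------------------------------------------------- #

def lrt(lnl_full: float, lnl_constrained: float, ddf: int,
        tol: float = 1e-6) -> Tuple[float, float]:
    """Likelihood-ratio test of a constrained model against the nesting one.

    statistic = 2·(lnL_full − lnL_constrained); p from the χ² upper tail with
    ``ddf`` degrees of freedom.  A statistic below −tol signals optimizer
    failure and raises; tiny negatives are clipped to 0.
    """
    if ddf < 1:
        raise ParameterError("need ddf >= 1")
    stat = 2.0 * (lnl_full - lnl_constrained)
    if stat < -tol:
        raise ConvergenceError(
            f"constrained lnL exceeds full lnL by {-stat / 2:g}: optimization failure")
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, ddf))


@dataclass
class BisseSuiteResult:
    """Ranked model table plus the underlying per-model fit summaries."""

    table: pd.DataFrame
    fits: Dict[str, BisseFitSummary]


def bisse_model_suite(trees: Union[Tree, Sequence[Tree]],
                      tips: Dict[str, Optional[int]],
                      models: Sequence[BisseConstraint] = MODEL_SUITE,
                      options: BisseOptions = DEFAULT_OPTIONS,
                      n_restarts: int = 3,
                      alpha: float = 0.05) -> BisseSuiteResult:
    """Fit the whole model suite across a tree sample and rank by median AIC.

    The table mirrors the study's layout: per model the degrees of freedom,
    median parameter estimates, median lnL and AIC, ΔAIC relative to the best
    (best − model, so entries are ≤ 0 with 0 for the best model), and the
    percentage of trees in which the LRT of the full model against this
    constrained model rejects at ``alpha``.  AIC is computed per tree and then
    medianed, so 2k − 2·lnL holds per tree rather than between the median
    columns.
    """
    if isinstance(trees, Tree):
        trees = [trees]
    fits: Dict[str, BisseFitSummary] = {}
    for c in models:
        fits[c.name] = bisse_fit(trees, tips, c, options, n_restarts)
    full = fits.get("full")
    rows = []
    for c in models:
        s = fits[c.name]
        med = s.medians
        row = {"model": c.name, "df": c.n_free}
        row.update({k: med[k] for k in PARAM_NAMES})
        row["lnl"] = med["lnl"]
        row["aic"] = med["aic"]
        if full is not None and c.name != "full" and c.n_free < 6:
            ddf = 6 - c.n_free
            rej = 0
            n_ok = 0
            for (lf, lc) in zip(full.per_tree.lnl, s.per_tree.lnl):
                try:
                    _, pv = lrt(lf, lc, ddf, tol=1e-3)
                except ConvergenceError:
                    continue
                n_ok += 1
                rej += pv < alpha
            row["pct_rejecting"] = 100.0 * rej / n_ok if n_ok else np.nan
        else:
            row["pct_rejecting"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    best = table.aic.min()
    table["delta_aic"] = best - table.aic
    table = table.sort_values("delta_aic", ascending=False,
                              kind="stable").reset_index(drop=True)
    return BisseSuiteResult(table=table, fits=fits)


# --------------------------------------------------------------------- #
# marginal ancestral states & parameter distributions
# --------------------------------------------------------------------- #

def bisse_asr_marginal(tree: Tree, tips: Dict[str, Optional[int]],
                       params: BisseParams,
                       options: BisseOptions = DEFAULT_OPTIONS) -> AncestralStates:
    """Marginal ancestral state probabilities per internal node.

    Each node is constrained to each state in turn, the full likelihood is
    recomputed, and the two constrained likelihoods are normalized.  The root
    is included (keyed by the full tip set).
    """
    arr, tipE, tipD = _tip_arrays(tree, tips, options.sampling_f)
    mode, pi0, pi1 = options.root_mode()
    cond = options.condition_on_survival
    p = params.as_array()
    probs: Dict[frozenset, np.ndarray] = {}
    for i, bp in arr.bipartitions.items():
        lnls = np.empty(2)
        for s in (0, 1):
            lnls[s], _ = _kernels.bisse_loglik_kernel(
                arr.left, arr.right, arr.blen, tipE, tipD, p, mode, pi0, pi1,
                cond, i, s, options.rtol, options.atol)
        if not np.any(np.isfinite(lnls)):
            raise ConvergenceError(f"zero likelihood at node {set(bp)}")
        m = np.nanmax(np.where(np.isfinite(lnls), lnls, -np.inf))
        w = np.where(np.isfinite(lnls), np.exp(lnls - m), 0.0)
        probs[bp] = w / w.sum()
    return AncestralStates(probs=probs)


def bisse_param_distributions(per_tree: pd.DataFrame,
                              ci: Tuple[float, float] = (2.5, 97.5)
                              ) -> pd.DataFrame:
    """Percentile summaries of per-tree full-model estimates.

    Returns one row per parameter (the six rates plus the derived net rates
    r_O, r_S) with the lower CI bound, median and upper bound, plus for each
    O/S pair an indicator of whether the two intervals overlap.
    """
    if len(per_tree) < 20:
        raise ParameterError("need >= 20 per-tree fits for interval summaries")
    df = per_tree[per_tree.converged] if "converged" in per_tree else per_tree
    work = df.copy()
    work["r_o"] = work.lam_o - work.mu_o
    work["r_s"] = work.lam_s - work.mu_s
    names = list(PARAM_NAMES) + ["r_o", "r_s"]
    lo, hi = ci
    rows = []
    for n in names:
        v = work[n].to_numpy()
        rows.append({"param": n, "lower": float(np.percentile(v, lo)),
                     "median": float(np.percentile(v, 50)),
                     "upper": float(np.percentile(v, hi))})
    out = pd.DataFrame(rows).set_index("param")
    pairs = [("lam_o", "lam_s"), ("mu_o", "mu_s"), ("q_os", "q_so"),
             ("r_o", "r_s")]
    overlap = {}
    for a, b in pairs:
        overlap[f"{a}|{b}"] = bool(out.loc[a, "lower"] <= out.loc[b, "upper"]
                                   and out.loc[b, "lower"] <= out.loc[a, "upper"])
    out.attrs["overlap"] = overlap
    return out
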