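"""Diversification-model likelihoods on branching times and model comparison.

Six models are fitted by ML to the branching times of a dated clade:

======  ==============================================  free parameters
PB      pure birth (Yule), constant net rate r          1 (r)
BD      constant birth–death, extinction fraction a=μ/λ 2 (r, a)
DDX     diversity-dependent, λ_k = λ0·k^(−x)            2 (λ0, x)
DDL     diversity-dependent, λ_k = λ0·(1 − k/K)         2 (λ0, K)
Y2R     Yule with 2 rates and one shift age             3
Y3R     Yule with 3 rates and two shift ages            5
======  ==============================================  =

All log-likelihoods share one additive-constant convention (no (N−1)! term)
so the models are directly comparable by AIC = 2k − 2lnL, and every nesting
route back to PB reproduces the PB value identically.

The rate-constant vs rate-variable comparison uses the statistic
ΔAIC_RC = AIC(best rate-constant) − AIC(best rate-variable), with its null
distribution obtained by simulating pure-birth branching times at the PB MLE
and refitting all six models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConvergenceError, ParameterError
from .treeio import BranchingTimes

BTLike = Union[BranchingTimes, np.ndarray, Sequence[float]]

RATE_CONSTANT = ("PB", "BD")
RATE_VARIABLE = ("DDX", "DDL", "Y2R", "Y3R")
ALL_MODELS = RATE_CONSTANT + RATE_VARIABLE


def _ages(bt: BTLike) -> np.ndarray:
    if isinstance(bt, BranchingTimes):
        return bt.ages
    return BranchingTimes(np.sort(np.asarray(bt, dtype=float))[::-1]).ages


def _sums(t: np.ndarray) -> Tuple[int, float, float]:
    """(N, G, S) with G = 2·t2 + Σ_{i≥3} t_i (total lineage-time exposure)
    and S = Σ_{i≥3} t_i."""
    n = t.size + 1
    s = float(t[1:].sum())
    return n, 2.0 * float(t[0]) + s, s


# --------------------------------------------------------------------- #
# likelihoods
# --------------------------------------------------------------------- #

def pb_loglik(bt: BTLike, lam: float, permissive: bool = False) -> float:
    """Pure-birth: lnL = (N−2)·ln λ − λ·G.  MLE is λ̂ = (N−2)/G."""
    t = _ages(bt)
    if lam <= 0:
        if permissive:
            return -np.inf
        raise ParameterError("lambda must be > 0")
    n, G, _ = _sums(t)
    return (n - 2) * np.log(lam) - lam * G


def pb_mle(bt: BTLike) -> Tuple[float, float]:
    """Closed-form PB fit: (λ̂, lnL at λ̂)."""
    t = _ages(bt)
    n, G, _ = _sums(t)
    lam = (n - 2) / G
    return lam, pb_loglik(t, lam)


def bd_loglik(bt: BTLike, r: float, a: float, permissive: bool = False) -> float:
    """Constant-rate birth–death (reconstructed process, conditioned on crown
    age and survival), parameterized by net rate r = λ−μ and extinction
    fraction a = μ/λ ∈ [0, 1)."""
    t = _ages(bt)
    if r <= 0 or not (0 <= a < 1):
        if permissive:
            return -np.inf
        raise ParameterError("need r > 0 and 0 <= a < 1")
    n, _, s = _sums(t)
    # ln(e^{rt} - a) written as rt + ln(1 - a e^{-rt}) for overflow safety
    return ((n - 2) * np.log(r) + n * np.log(1 - a) + r * s
            - 2.0 * float(np.sum(r * t + np.log1p(-a * np.exp(-r * t)))))


def _dd_loglik(t: np.ndarray, lam_k: np.ndarray, permissive: bool) -> float:
    """Shared diversity-dependent form: per-lineage rate λ_k while k lineages
    exist; lnL = Σ_{k=2}^{N−1} ln λ_k − Σ_{k=2}^{N} k·λ_k·τ_k."""
    n = t.size + 1
    if np.any(lam_k <= 0):
        if permissive:
            return -np.inf
        raise ParameterError("diversity-dependent rate non-positive in 2..N")
    tau = np.empty(n - 1)
    tau[:-1] = t[:-1] - t[1:]
    tau[-1] = t[-1]
    k = np.arange(2, n + 1)
    return float(np.sum(np.log(lam_k[:-1])) - np.sum(k * lam_k * tau))


def ddx_loglik(bt: BTLike, lam0: float, x: float,
               permissive: bool = False) -> float:
    """Exponential diversity dependence: λ_k = λ0·k^(−x); x = 0 is PB."""
    t = _ages(bt)
    if lam0 <= 0:
        if permissive:
            return -np.inf
        raise ParameterError("lambda0 must be > 0")
    k = np.arange(2, t.size + 2)
    return _dd_loglik(t, lam0 * k.astype(float) ** (-x), permissive)


def ddl_loglik(bt: BTLike, lam0: float, K: float,
               permissive: bool = False) -> float:
    """Linear diversity dependence: λ_k = λ0·(1 − k/K); K → ∞ is PB."""
    t = _ages(bt)
    if lam0 <= 0 or K <= t.size + 1:
        if permissive:
            return -np.inf
        raise ParameterError("need lambda0 > 0 and K > N")
    k = np.arange(2, t.size + 2)
    return _dd_loglik(t, lam0 * (1.0 - k / K), permissive)


def yule_multirate_loglik(bt: BTLike, rates: Sequence[float],
                          shifts: Sequence[float],
                          permissive: bool = False) -> float:
    """Piecewise pure-birth with rates[j] in force between shift ages.

    ``shifts`` are strictly decreasing ages inside (0, crown age); rates[0]
    applies from the crown down to shifts[0], etc.  An event exactly at a
    shift age belongs to the younger regime.
    """
    t = _ages(bt)
    rates = np.asarray(rates, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if rates.size != shifts.size + 1:
        raise ParameterError("need len(rates) == len(shifts) + 1")
    if shifts.size and (np.any(np.diff(shifts) >= 0)
                        or shifts[0] >= t[0] or shifts[-1] <= 0):
        raise ParameterError("shift ages must be strictly decreasing in (0, crown)")
    if np.any(rates <= 0):
        if permissive:
            return -np.inf
        raise ParameterError("rates must be > 0")
    nev, expo = _regime_sums(t, shifts)
    return float(np.sum(nev * np.log(rates)) - np.sum(expo * rates))


def _regime_sums(t: np.ndarray, shifts: np.ndarray):
    """Per-regime observed event counts and lineage-time exposures.

    Regime j covers ages (shifts[j], shifts[j−1]] with shifts[−1] = ∞ and a
    final lower bound of 0; an event exactly at a shift belongs to the
    younger regime.
    """
    bounds = np.concatenate([[np.inf], shifts, [0.0]])
    events = t[1:]                      # t3..tN (the crown event is conditioned on)
    # segment i spans ages (lo_i, hi_i) with k = i+2 lineages
    hi = t
    lo = np.concatenate([t[1:], [0.0]])
    k = np.arange(2, t.size + 2).astype(float)
    nev = np.empty(shifts.size + 1)
    expo = np.empty(shifts.size + 1)
    for j in range(shifts.size + 1):
        b_hi, b_lo = bounds[j], bounds[j + 1]
        nev[j] = np.sum((events > b_lo) & (events <= b_hi))
        ov = np.maximum(0.0, np.minimum(hi, b_hi) - np.maximum(lo, b_lo))
        expo[j] = float(np.sum(k * ov))
    return nev, expo


# --------------------------------------------------------------------- #
# fits
# --------------------------------------------------------------------- #

@dataclass
class DivModelFit:
    """One diversification model's ML fit."""

    model: str
    params: Dict[str, float]
    lnl: float
    n_free: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.lnl


def _opt(nll_grad, starts, bounds):
    best = None
    for x0 in starts:
        res = minimize(nll_grad, np.asarray(x0, dtype=float), method="L-BFGS-B",
                       jac=True, bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_pb(bt: BTLike) -> DivModelFit:
    lam, lnl = pb_mle(bt)
    return DivModelFit("PB", {"r1": lam}, lnl, 1)


def fit_bd(bt: BTLike) -> DivModelFit:
    t = _ages(bt)
    n = t.size + 1
    lam, _ = pb_mle(t)
    s = float(t[1:].sum())

    def nll(x):
        r, a = np.exp(x[0]), x[1]
        ert = np.exp(-r * t)
        den = 1.0 - a * ert
        lnl = ((n - 2) * np.log(r) + n * np.log1p(-a) + r * s
               - 2.0 * float(np.sum(r * t + np.log(den))))
        dr = ((n - 2) / r + s
              - 2.0 * float(np.sum(t + a * t * ert / den)))
        da = -n / (1.0 - a) + 2.0 * float(np.sum(ert / den))
        return -lnl, np.array([-dr * r, -da])

    starts = [(np.log(lam), 0.0), (np.log(lam), 0.5), (np.log(lam * 2), 0.9)]
    res = _opt(nll, starts, [(np.log(1e-8), np.log(1e3)), (0.0, 1.0 - 1e-9)])
    return DivModelFit("BD", {"r1": float(np.exp(res.x[0])), "a": float(res.x[1])},
                       -res.fun, 2, converged=bool(res.success))


def fit_ddx(bt: BTLike) -> DivModelFit:
    t = _ages(bt)
    n = t.size + 1
    tau = np.empty(n - 1)
    tau[:-1] = t[:-1] - t[1:]
    tau[-1] = t[-1]
    k = np.arange(2, n + 1).astype(float)
    lnk = np.log(k)

    def nll(x):
        lam0, xx = np.exp(x[0]), x[1]
        w = k ** (1.0 - xx) * tau
        lnl = ((n - 2) * x[0] - xx * float(lnk[:-1].sum())
               - lam0 * float(w.sum()))
        dln = (n - 2) - lam0 * float(w.sum())
        dx = -float(lnk[:-1].sum()) + lam0 * float((w * lnk).sum())
        return -lnl, np.array([-dln, -dx])

    lam, _ = pb_mle(t)
    starts = [(np.log(lam), 0.0), (np.log(lam), 1.0), (np.log(lam), -1.0)]
    res = _opt(nll, starts, [(np.log(1e-8), np.log(1e3)), (-10.0, 10.0)])
    return DivModelFit("DDX", {"r1": float(np.exp(res.x[0])), "x": float(res.x[1])},
                       -res.fun, 2, converged=bool(res.success))


def fit_ddl(bt: BTLike) -> DivModelFit:
    t = _ages(bt)
    n = t.size + 1
    tau = np.empty(n - 1)
    tau[:-1] = t[:-1] - t[1:]
    tau[-1] = t[-1]
    k = np.arange(2, n + 1).astype(float)

    def nll(x):
        lam0, eu = np.exp(x[0]), np.exp(x[1])
        K = n + eu
        frac = 1.0 - k / K
        w = k * frac * tau
        lnl = ((n - 2) * x[0] + float(np.log(frac[:-1]).sum())
               - lam0 * float(w.sum()))
        dln = (n - 2) - lam0 * float(w.sum())
        dK = (float((k[:-1] / K ** 2 / frac[:-1]).sum())
              - lam0 * float((k ** 2 / K ** 2 * tau).sum()))
        return -lnl, np.array([-dln, -dK * eu])

    lam, _ = pb_mle(t)
    starts = [(np.log(lam), np.log(n)), (np.log(lam), np.log(2.0)),
              (np.log(lam), np.log(1e4))]
    res = _opt(nll, starts, [(np.log(1e-8), np.log(1e3)),
                             (np.log(1e-6), np.log(1e9))])
    return DivModelFit("DDL", {"r1": float(np.exp(res.x[0])),
                               "k": float(n + np.exp(res.x[1]))},
                       -res.fun, 2, converged=bool(res.success))


def _candidate_sums(t: np.ndarray):
    """For each candidate shift age (the unique branching times t3..tN):
    the number of events strictly older and the exposure accrued above it."""
    cands = np.unique(t[1:])[::-1]
    cands = cands[(cands > 0) & (cands < t[0])]
    events = t[1:]
    hi = t
    lo = np.concatenate([t[1:], [0.0]])
    k = np.arange(2, t.size + 2).astype(float)
    n_above = (events[None, :] > cands[:, None]).sum(axis=1).astype(float)
    ov = np.maximum(0.0, hi[None, :] - np.maximum(lo[None, :], cands[:, None]))
    e_above = (k[None, :] * ov).sum(axis=1)
    return cands, n_above, e_above


def _profile_lnl(nev: np.ndarray, expo: np.ndarray) -> np.ndarray:
    """Closed-form profile lnL per regime: n ln(n/E) − n, with 0·ln 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(nev > 0, nev * (np.log(nev) - np.log(expo)) - nev, 0.0)
    return np.where(expo > 0, term, -np.inf)


def _fit_multirate(t: np.ndarray, n_rates: int) -> DivModelFit:
    """Profile the piecewise-Yule likelihood over shift ages drawn from the
    observed branching times (the likelihood is constant in the shift between
    events), with closed-form per-regime rate MLEs λ̂_j = n_j / E_j."""
    name = "Y2R" if n_rates == 2 else "Y3R"
    n = t.size + 1
    G = 2.0 * t[0] + float(t[1:].sum())
    cands, n_ab, e_ab = _candidate_sums(t)
    if cands.size < n_rates - 1:
        raise ParameterError("too few branching times for this many regimes")
    ntot = float(n - 2)
    if n_rates == 2:
        lnl = (_profile_lnl(n_ab, e_ab)
               + _profile_lnl(ntot - n_ab, G - e_ab))
        i = int(np.argmax(lnl))
        shifts = [float(cands[i])]
        nev = np.array([n_ab[i], ntot - n_ab[i]])
        expo = np.array([e_ab[i], G - e_ab[i]])
    else:
        # pairs (i, j): shift ages cands[i] > cands[j]
        n1 = n_ab[:, None]
        e1 = e_ab[:, None]
        n2 = n_ab[None, :] - n_ab[:, None]
        e2 = e_ab[None, :] - e_ab[:, None]
        n3 = ntot - n_ab[None, :]
        e3 = G - e_ab[None, :]
        lnl = (_profile_lnl(n1, e1) + _profile_lnl(n2, e2)
               + _profile_lnl(n3, e3))
        lnl[~(cands[:, None] > cands[None, :])] = -np.inf
        i, j = np.unravel_index(int(np.argmax(lnl)), lnl.shape)
        shifts = [float(cands[i]), float(cands[j])]
        nev = np.array([n_ab[i], n_ab[j] - n_ab[i], ntot - n_ab[j]])
        expo = np.array([e_ab[i], e_ab[j] - e_ab[i], G - e_ab[j]])
    rates = np.where(nev > 0, nev / np.where(expo > 0, expo, 1.0), 0.0)
    best_lnl = float(np.sum(_profile_lnl(nev, expo)))
    params = {f"r{j + 1}": float(rates[j]) for j in range(n_rates)}
    params.update({f"st{j + 1}": float(shifts[j]) for j in range(n_rates - 1)})
    return DivModelFit(name, params, best_lnl, 2 * n_rates - 1)


def fit_y2r(bt: BTLike) -> DivModelFit:
    return _fit_multirate(_ages(bt), 2)


def fit_y3r(bt: BTLike) -> DivModelFit:
    return _fit_multirate(_ages(bt), 3)


_FITTERS = {"PB": fit_pb, "BD": fit_bd, "DDX": fit_ddx, "DDL": fit_ddl,
            "Y2R": fit_y2r, "Y3R": fit_y3r}


def fit_all(bt: BTLike, models: Sequence[str] = ALL_MODELS) -> List[DivModelFit]:
    """Fit the requested models; deterministic given the branching times."""
    t = _ages(bt)
    if t.size + 1 < 4:
        raise ParameterError("need at least 4 tips")
    return [_FITTERS[m](t) for m in models]


def fits_to_frame(fits: List[DivModelFit]) -> pd.DataFrame:
    cols = ["r1", "r2", "r3", "st1", "st2", "a", "x", "k"]
    rows = []
    best = min(f.aic for f in fits)
    for f in fits:
        row = {"model": f.model}
        row.update({c: f.params.get(c, np.nan) for c in cols})
        row["lnl"] = f.lnl
        row["aic"] = f.aic
        row["delta_aic"] = f.aic - best
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# rate-constant vs rate-variable test
# --------------------------------------------------------------------- #

def daicrc_statistic(fits: List[DivModelFit]) -> float:
    """ΔAIC_RC = AIC(best rate-constant) − AIC(best rate-variable)."""
    rc = min(f.aic for f in fits if f.model in RATE_CONSTANT)
    rv = min(f.aic for f in fits if f.model in RATE_VARIABLE)
    return rc - rv


@dataclass
class DaicrcResult:
    observed: float
    null: np.ndarray
    lam_null: float
    seed: Optional[int]

    @property
    def p_value(self) -> float:
        return float(np.mean(self.null >= self.observed))

    def critical_value(self, q: float = 0.95) -> float:
        return float(np.quantile(self.null, q))


def daicrc_null(n_tips: int, lam: float, reps: int, seed=None, rng=None) -> np.ndarray:
    """Null sample of ΔAIC_RC from pure-birth simulations at rate ``lam``."""
    from .simulators import yule_branching_times
    g = rng if rng is not None else np.random.default_rng(seed)
    out = np.empty(reps)
    for i in range(reps):
        bt = yule_branching_times(n_tips, lam, rng=g)
        out[i] = daicrc_statistic(fit_all(bt))
    return out


def daicrc_test(bt: BTLike, reps: int = 1000, seed=None,
                null: Optional[np.ndarray] = None) -> DaicrcResult:
    """Test the best rate-constant against the best rate-variable model.

    The null distribution simulates ``reps`` pure-birth clades of the same
    size at the PB MLE of the data and refits all six models per replicate;
    p = Pr(null ΔAIC_RC ≥ observed).  A precomputed ``null`` sample may be
    supplied (the statistic's null law does not depend on the rate, only on
    N, because branching times enter all six likelihood families
    scale-equivariantly).
    """
    if null is None and reps < 100:
        raise ParameterError("need reps >= 100")
    t = _ages(bt)
    fits = fit_all(t)
    obs = daicrc_statistic(fits)
    lam, _ = pb_mle(t)
    if null is None:
        null = daicrc_null(t.size + 1, lam, reps, seed=seed)
    return DaicrcResult(observed=obs, null=np.asarray(null, dtype=float),
                        lam_null=lam, seed=seed)
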