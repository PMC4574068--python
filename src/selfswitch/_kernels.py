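"""Numba-compiled likelihood kernels.

Trees arrive as flat postorder arrays (children precede parents, root last;
``left``/``right`` are −1 for tips) produced by ``Tree.index_arrays()``.

The BiSSE kernel integrates the coupled extinction/likelihood ODE system
branch-by-branch with an embedded Dormand–Prince 5(4) stepper and per-branch
renormalization of the D variables (log-linearity of the likelihood in D makes
the compensation exact).  The Mk2 kernel is plain Felsenstein pruning with the
closed-form 2-state transition probabilities.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf

# root weighting modes
ROOT_OBS = 0    # weights proportional to the root D values
ROOT_FLAT = 1   # (0.5, 0.5)
ROOT_GIVEN = 2  # user-supplied (pi0, pi1)


# --------------------------------------------------------------------- #
# Mk2 pruning
# --------------------------------------------------------------------- #

@njit(cache=True)
def mk2_prob(q01, q10, t):
    """Closed-form 2-state CTMC transition matrix."""
    P = np.empty((2, 2))
    s = q01 + q10
    if s <= 0.0:
        P[0, 0] = 1.0; P[0, 1] = 0.0
        P[1, 0] = 0.0; P[1, 1] = 1.0
        return P
    e = np.exp(-s * t)
    P[0, 0] = (q10 + q01 * e) / s
    P[0, 1] = (q01 * (1.0 - e)) / s
    P[1, 0] = (q10 * (1.0 - e)) / s
    P[1, 1] = (q01 + q10 * e) / s
    return P


@njit(cache=True)
def mk2_loglik_kernel(left, right, blen, tipD, q01, q10, pi0, pi1):
    """Felsenstein pruning log-likelihood; returns (lnL, partials)."""
    n = left.shape[0]
    D = np.empty((n, 2))
    logcomp = 0.0
    for i in range(n):
        if left[i] < 0:
            D[i, 0] = tipD[i, 0]
            D[i, 1] = tipD[i, 1]
        else:
            for s in range(2):
                D[i, s] = 1.0
            for c in (left[i], right[i]):
                P = mk2_prob(q01, q10, blen[c])
                w0 = P[0, 0] * D[c, 0] + P[0, 1] * D[c, 1]
                w1 = P[1, 0] * D[c, 0] + P[1, 1] * D[c, 1]
                D[i, 0] *= w0
                D[i, 1] *= w1
            m = max(D[i, 0], D[i, 1])
            if m <= 0.0:
                return NEG_INF, D
            D[i, 0] /= m
            D[i, 1] /= m
            logcomp += np.log(m)
    root = n - 1
    L = pi0 * D[root, 0] + pi1 * D[root, 1]
    if L <= 0.0:
        return NEG_INF, D
    return np.log(L) + logcomp, D


# --------------------------------------------------------------------- #
# BiSSE ODE integration (Dormand-Prince 5(4), adaptive)
# --------------------------------------------------------------------- #

@njit(cache=True)
def _bisse_deriv(y, p, out):
    # y = (E0, E1, D0, D1); p = (lam0, lam1, mu0, mu1, q01, q10)
    lam0, lam1, mu0, mu1, q01, q10 = p[0], p[1], p[2], p[3], p[4], p[5]
    E0, E1, D0, D1 = y[0], y[1], y[2], y[3]
    out[0] = mu0 - (lam0 + mu0 + q01) * E0 + lam0 * E0 * E0 + q01 * E1
    out[1] = mu1 - (lam1 + mu1 + q10) * E1 + lam1 * E1 * E1 + q10 * E0
    out[2] = -(lam0 + mu0 + q01) * D0 + q01 * D1 + 2.0 * lam0 * E0 * D0
    out[3] = -(lam1 + mu1 + q10) * D1 + q10 * D0 + 2.0 * lam1 * E1 * D1


@njit(cache=True)
def _integrate_branch(y, tlen, p, rtol, atol):
    """Integrate the 4-dim BiSSE system over a branch of length ``tlen``."""
    if tlen <= 0.0:
        return y
    # Dormand-Prince coefficients
    k1 = np.empty(4); k2 = np.empty(4); k3 = np.empty(4)
    k4 = np.empty(4); k5 = np.empty(4); k6 = np.empty(4); k7 = np.empty(4)
    ytmp = np.empty(4)
    y5 = np.empty(4)
    t = 0.0
    h = tlen * 0.1
    if h > 0.5:
        h = 0.5
    nfail = 0
    while t < tlen:
        if t + h > tlen:
            h = tlen - t
        _bisse_deriv(y, p, k1)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.2 * k1[i])
        _bisse_deriv(ytmp, p, k2)
        for i in range(4):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _bisse_deriv(ytmp, p, k3)
        for i in range(4):
            ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                  + 32.0 / 9.0 * k3[i])
        _bisse_deriv(ytmp, p, k4)
        for i in range(4):
            ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i]
                                  - 25360.0 / 2187.0 * k2[i]
                                  + 64448.0 / 6561.0 * k3[i]
                                  - 212.0 / 729.0 * k4[i])
        _bisse_deriv(ytmp, p, k5)
        for i in range(4):
            ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i]
                                  - 355.0 / 33.0 * k2[i]
                                  + 46732.0 / 5247.0 * k3[i]
                                  + 49.0 / 176.0 * k4[i]
                                  - 5103.0 / 18656.0 * k5[i])
        _bisse_deriv(ytmp, p, k6)
        for i in range(4):
            y5[i] = y[i] + h * (35.0 / 384.0 * k1[i]
                                + 500.0 / 1113.0 * k3[i]
                                + 125.0 / 192.0 * k4[i]
                                - 2187.0 / 6784.0 * k5[i]
                                + 11.0 / 84.0 * k6[i])
        _bisse_deriv(y5, p, k7)
        # embedded 4th-order error estimate
        errnorm = 0.0
        for i in range(4):
            err_i = h * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1[i]
                         + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[i]
                         + (125.0 / 192.0 - 393.0 / 640.0) * k4[i]
                         + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[i]
                         + (11.0 / 84.0 - 187.0 / 2100.0) * k6[i]
                         - 1.0 / 40.0 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            r = err_i / sc
            errnorm += r * r
        errnorm = np.sqrt(errnorm / 4.0)
        if errnorm <= 1.0:
            t += h
            for i in range(4):
                y[i] = y5[i]
            nfail = 0
        else:
            nfail += 1
            if nfail > 60:
                for i in range(4):
                    y[i] = np.nan
                return y
        if errnorm <= 1e-30:
            fac = 5.0
        else:
            fac = 0.9 * errnorm ** -0.2
            if fac > 5.0:
                fac = 5.0
            elif fac < 0.2:
                fac = 0.2
        h = h * fac
        if h < 1e-14:
            h = 1e-14
    # clamp tiny numerical excursions of E outside [0, 1]
    for i in range(2):
        if y[i] < 0.0:
            y[i] = 0.0
        elif y[i] > 1.0:
            y[i] = 1.0
    return y


@njit(cache=True)
def bisse_loglik_kernel(left, right, blen, tipE, tipD, p,
                        root_mode, pi0, pi1, condition,
                        cnode, cstate, rtol, atol):
    """BiSSE log-likelihood of one tree.

    ``cnode >= 0`` constrains that (internal) node to ``cstate`` — used for
    marginal ancestral-state reconstruction.  Returns (lnL, n_clipped) where
    n_clipped counts negative-D clippings.
    """
    n = left.shape[0]
    E = np.empty((n, 2))
    D = np.empty((n, 2))
    y = np.empty(4)
    logcomp = 0.0
    nclip = 0
    for i in range(n):
        if left[i] < 0:
            y[0] = tipE[i, 0]
            y[1] = tipE[i, 1]
            y[2] = tipD[i, 0]
            y[3] = tipD[i, 1]
        else:
            l, r = left[i], right[i]
            y[0] = 0.5 * (E[l, 0] + E[r, 0])
            y[1] = 0.5 * (E[l, 1] + E[r, 1])
            y[2] = p[0] * D[l, 0] * D[r, 0]
            y[3] = p[1] * D[l, 1] * D[r, 1]
        if i == cnode:
            if cstate == 0:
                y[3] = 0.0
            else:
                y[2] = 0.0
        for j in (2, 3):
            if y[j] < 0.0:
                y[j] = 0.0
                nclip += 1
        s = y[2] + y[3]
        if s <= 0.0 or not np.isfinite(s):
            return NEG_INF, nclip
        y[2] /= s
        y[3] /= s
        logcomp += np.log(s)
        if i < n - 1 and blen[i] > 0.0:
            y = _integrate_branch(y, blen[i], p, rtol, atol)
            if not np.isfinite(y[2] + y[3]):
                return NEG_INF, nclip
        E[i, 0] = y[0]
        E[i, 1] = y[1]
        D[i, 0] = y[2]
        D[i, 1] = y[3]
    root = n - 1
    d0, d1 = D[root, 0], D[root, 1]
    e0, e1 = E[root, 0], E[root, 1]
    if root_mode == ROOT_OBS:
        tot = d0 + d1
        w0, w1 = d0 / tot, d1 / tot
    elif root_mode == ROOT_FLAT:
        w0, w1 = 0.5, 0.5
    else:
        w0, w1 = pi0, pi1
    L = w0 * d0 + w1 * d1
    if condition:
        surv = w0 * p[0] * (1.0 - e0) ** 2 + w1 * p[1] * (1.0 - e1) ** 2
        if surv <= 0.0:
            return NEG_INF, nclip
        L = L / surv
    if L <= 0.0 or not np.isfinite(L):
        return NEG_INF, nclip
    return np.log(L) + logcomp, nclip
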