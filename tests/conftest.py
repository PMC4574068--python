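"""Shared fixtures and independent oracles.

The brute-force Mk2 enumerator and the fixed-step BiSSE integrator live here
so that every likelihood test checks the package against an implementation
that shares no code with it.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from selfswitch.params import BisseParams
from selfswitch.treeio import Tree, parse_newick


@pytest.fixture
def toy_tree() -> Tree:
    """3-tip caterpillar with crown age 2: ((A:1,B:1):1,C:2)."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree() -> Tree:
    return parse_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")


@pytest.fixture(scope="session")
def clade_c_small():
    """Reduced clade-C-like dataset (30 trees) reused across tests."""
    from selfswitch.simulators import make_clade_c_like_dataset
    return make_clade_c_like_dataset(seed=2024, n_trees=30)


# --------------------------------------------------------------------- #
# oracles
# --------------------------------------------------------------------- #

def mk2_brute_loglik(tree: Tree, tips, q01, q10, root_prior=(0.5, 0.5)):
    """Mk2 likelihood by exhaustive enumeration of internal-node states."""
    from selfswitch.markov2 import mk2_transition_prob

    dt = tree.dendropy_tree
    internals = list(dt.postorder_internal_node_iter())
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        prob = root_prior[st[id(dt.seed_node)]]
        for n in dt.preorder_node_iter():
            if n is dt.seed_node:
                continue
            P = mk2_transition_prob(q01, q10, n.edge.length)
            ps = st[id(n.parent_node)]
            if n.is_leaf():
                obs = tips[str(n.taxon.label)]
                prob *= 1.0 if obs is None else P[ps, obs]
            else:
                prob *= P[ps, st[id(n)]]
        total += prob
    return np.log(total)


def bisse_fixed_step_loglik(tree: Tree, tips, params: BisseParams,
                            condition=True, root="obs", step=1e-4):
    """BiSSE likelihood via a plain-numpy fixed-step RK4 integrator."""
    arr = tree.index_arrays()
    lam = np.array([params.lam_o, params.lam_s])
    mu = np.array([params.mu_o, params.mu_s])
    q = np.array([params.q_os, params.q_so])

    def deriv(y):
        E, D = y[:2], y[2:]
        dE = mu - (lam + mu + q) * E + lam * E * E + q * E[::-1]
        dD = -(lam + mu + q) * D + q * D[::-1] + 2 * lam * E * D
        return np.concatenate([dE, dD])

    def integrate(y, T):
        nstep = max(1, int(np.ceil(T / step)))
        h = T / nstep
        for _ in range(nstep):
            k1 = deriv(y)
            k2 = deriv(y + h / 2 * k1)
            k3 = deriv(y + h / 2 * k2)
            k4 = deriv(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    inv = {i: n for n, i in arr.tip_index.items()}
    Y = {}
    logcomp = 0.0
    for i in range(arr.n_nodes):
        if arr.left[i] < 0:
            D = np.ones(2) if tips[inv[i]] is None else np.eye(2)[int(tips[inv[i]])]
            y = np.concatenate([[0.0, 0.0], D])
        else:
            l, r = arr.left[i], arr.right[i]
            E = (Y[l][:2] + Y[r][:2]) / 2
            D = lam * Y[l][2:] * Y[r][2:]
            y = np.concatenate([E, D])
        s = y[2:].sum()
        y[2:] /= s
        logcomp += np.log(s)
        if i < arr.n_nodes - 1 and arr.blen[i] > 0:
            y = integrate(y, arr.blen[i])
        Y[i] = y
    d, e = Y[arr.n_nodes - 1][2:], Y[arr.n_nodes - 1][:2]
    w = d / d.sum() if root == "obs" else np.array([0.5, 0.5])
    L = float((w * d).sum())
    if condition:
        L /= float((w * lam * (1 - e) ** 2).sum())
    return np.log(L) + logcomp
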