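"""Forward simulators for dated trees and binary characters.

These generate the synthetic datasets every downstream stage is tested
against: Yule and constant-rate birth–death trees conditioned on a tip count,
joint tree+trait simulation under the BiSSE process, Mk2 character evolution
on a fixed tree, and a "clade-C-like" fixture — a posterior-style sample of
30-tip chronograms (crown age ≈ 5.3 Myr) with a binary mating-type character
scored for 28 of 30 species, 8 of them in the derived (selfing) state.

All simulators take an integer ``seed`` or an explicit numpy ``Generator``
(``rng=``); a fixed seed reproduces output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np

from .errors import ConvergenceError, ParameterError
from .params import BisseParams
from .treeio import BranchingTimes, Tree

MISSING = None

RETRY_CAP = 10_000


def _rng(seed=None, rng: Optional[np.random.Generator] = None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# --------------------------------------------------------------------- #
# Yule
# --------------------------------------------------------------------- #

def yule_branching_times(n: int, lam: float, seed=None, rng=None,
                         final_segment: bool = True) -> BranchingTimes:
    """Branching times of a Yule tree without building the topology.

    Waiting time while ``k`` lineages exist is Exponential(kλ); by default the
    interval from the appearance of the n-th lineage to the present is the
    waiting time to the next (unobserved) event, Exponential(nλ).  With
    ``final_segment=False`` the process stops exactly at the n-th birth (the
    two youngest tips then have zero-length terminal branches).
    """
    if n < 2 or lam <= 0:
        raise ParameterError("need n >= 2 and lambda > 0")
    g = _rng(seed, rng)
    waits = g.exponential(1.0 / (lam * np.arange(2, n + 1)))
    if not final_segment:
        waits[-1] = 0.0
    total = waits.sum()
    event_times = np.concatenate([[0.0], np.cumsum(waits[:-1])])
    return BranchingTimes(np.maximum(total - event_times, 0.0))


def simulate_yule(n: int, lam: float, seed=None, rng=None,
                  final_segment: bool = True) -> Tree:
    """Simulate a dated ultrametric Yule tree with exactly ``n`` tips.

    The crown split happens at time 0 (two initial lineages); at each birth a
    uniformly chosen extant lineage splits.  Event ages are recorded in
    ``tree.metadata["event_ages"]`` (descending, crown first).
    """
    if n < 2 or lam <= 0:
        raise ParameterError("need n >= 2 and lambda > 0")
    g = _rng(seed, rng)
    # children[i] = (a, b) once lineage i has split; birth[i] = birth time
    birth = [0.0, 0.0]
    children: Dict[int, Tuple[int, int]] = {}
    split_time: Dict[int, float] = {}
    active = [0, 1]
    t = 0.0
    event_times = [0.0]
    while len(active) < n:
        k = len(active)
        t += g.exponential(1.0 / (lam * k))
        who = active.pop(int(g.integers(k)))
        a, b = len(birth), len(birth) + 1
        birth.extend([t, t])
        children[who] = (a, b)
        split_time[who] = t
        active.extend([a, b])
        event_times.append(t)
    total = t + (g.exponential(1.0 / (lam * n)) if final_segment else 0.0)
    tree = _assemble_tree(total, [0, 1], birth, children, split_time)
    tree.metadata["event_ages"] = np.array(
        sorted((total - e for e in event_times), reverse=True))
    return tree


def _assemble_tree(total: float, crown: List[int], birth, children,
                   split_time) -> Tree:
    """Build a dendropy tree from lineage records (no extinction)."""
    taxa = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxa)
    counter = [0]

    def build(lin: int, node: dendropy.Node, start: float) -> None:
        if lin in children:
            end = split_time[lin]
            node.edge.length = end - start
            for c in children[lin]:
                build(c, node.new_child(), end)
        else:
            node.edge.length = total - start
            counter[0] += 1
            node.taxon = taxa.new_taxon(label=f"t{counter[0]}")

    root = dt.seed_node
    root.edge.length = 0.0
    for lin in crown:
        build(lin, root.new_child(), 0.0)
    return Tree(dt, dated=True)


# --------------------------------------------------------------------- #
# BiSSE / BD forward Gillespie
# --------------------------------------------------------------------- #

class _Lin:
    __slots__ = ("birth", "state", "alive", "death", "kids", "split_state")

    def __init__(self, birth: float, state: int):
        self.birth = birth
        self.state = state
        self.alive = True
        self.death: Optional[float] = None
        self.kids: Optional[Tuple["_Lin", "_Lin"]] = None
        self.split_state: Optional[int] = None


@dataclass
class BisseSimulation:
    """A reconstructed BiSSE tree with the simulated truth attached."""

    tree: Tree
    tip_states: Dict[str, Optional[int]]
    node_states: Dict[frozenset, int]   # bipartition (incl. root) -> true state
    retries: int


def simulate_bisse(params: BisseParams, n: Optional[int] = None, seed=None,
                   rng=None, root_state="equal",
                   max_time: Optional[float] = None,
                   retry_cap: int = RETRY_CAP) -> BisseSimulation:
    """Joint simulation of tree and binary trait under the BiSSE process.

    Per-lineage Gillespie with events speciation (λ_state), extinction
    (μ_state) and state flip (q away-rate); two crown lineages start in the
    root state at time 0.  The simulation stops at the first passage of the
    extant-lineage count to ``n`` (plus an Exponential final segment, matching
    the Yule stopping convention), or at ``max_time`` if given instead.
    Extinct lineages are pruned; the returned tree is the reconstructed tree.
    True states are recorded at every surviving node.

    Whole-clade extinction (or failure to reach ``n``) triggers a retry, up to
    ``retry_cap``.
    """
    if (n is None) == (max_time is None):
        raise ParameterError("set exactly one stopping rule: n or max_time")
    rates = params.as_array()
    if rates.sum() <= 0:
        raise ParameterError("all BiSSE rates are zero")
    if n is not None and n < 2:
        raise ParameterError("need n >= 2")
    g = _rng(seed, rng)
    lam = np.array([params.lam_o, params.lam_s])
    mu = np.array([params.mu_o, params.mu_s])
    q = np.array([params.q_os, params.q_so])
    per_state = lam + mu + q

    for attempt in range(retry_cap):
        rs = _draw_root_state(root_state, params, g)
        crown = [_Lin(0.0, rs), _Lin(0.0, rs)]
        active = list(crown)
        t = 0.0
        ok = False
        while True:
            k = len(active)
            if k == 0:
                break
            states = np.array([l.state for l in active])
            tot = per_state[states].sum()
            if n is not None and k == n:
                if tot > 0:
                    t += g.exponential(1.0 / tot)
                ok = True
                break
            if tot <= 0:
                break  # frozen: no further events possible, cannot reach n
            dt = g.exponential(1.0 / tot)
            if max_time is not None and t + dt >= max_time:
                t = max_time
                ok = k >= 2
                break
            t += dt
            i = int(g.choice(k, p=per_state[states] / tot))
            lin = active[i]
            s = lin.state
            u = g.random() * per_state[s]
            if u < lam[s]:
                lin.alive = False
                lin.death = t
                lin.split_state = s
                lin.kids = (_Lin(t, s), _Lin(t, s))
                active.pop(i)
                active.extend(lin.kids)
            elif u < lam[s] + mu[s]:
                lin.alive = False
                lin.death = t
                active.pop(i)
            else:
                lin.state = 1 - s
        if ok:
            sim = _prune_and_build(crown, t, rs)
            if sim is not None:
                tree, tips, nodes = sim
                if n is None or tree.n_tips == n:
                    return BisseSimulation(tree=tree, tip_states=tips,
                                           node_states=nodes, retries=attempt)
    raise ConvergenceError(
        f"BiSSE simulation failed to yield a surviving clade in {retry_cap} tries")


def _draw_root_state(root_state, params: BisseParams, g) -> int:
    if root_state in (0, 1):
        return int(root_state)
    if root_state == "equal":
        return int(g.random() < 0.5)
    if root_state == "stationary":
        s = params.q_os + params.q_so
        p1 = params.q_os / s if s > 0 else 0.5
        return int(g.random() < p1)
    raise ParameterError(f"unknown root_state {root_state!r}")


def _prune_and_build(crown: List[_Lin], total: float, root_state: int):
    """Prune extinct lineages and build the reconstructed Tree.

    Returns (tree, tip_states, node_states) or None if < 2 tips survive.
    Records are ("tip", time, state) or ("node", time, state, left, right).
    """
    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))

    def prune(lin: _Lin):
        if lin.alive:
            return ("tip", total, lin.state)
        if lin.kids is None:
            return None
        a = prune(lin.kids[0])
        b = prune(lin.kids[1])
        if a is not None and b is not None:
            return ("node", lin.death, lin.split_state, a, b)
        return a if a is not None else b

    try:
        a = prune(crown[0])
        b = prune(crown[1])
    finally:
        sys.setrecursionlimit(old_limit)
    if a is not None and b is not None:
        top = ("node", 0.0, int(root_state), a, b)
    else:
        top = a if a is not None else b
    if top is None or top[0] == "tip":
        return None

    taxa = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxa)
    counter = [0]
    tip_states: Dict[str, Optional[int]] = {}
    state_of_node: Dict[int, int] = {}

    def build(rec, node: dendropy.Node, start: float):
        if rec[0] == "tip":
            _, when, state = rec
            node.edge.length = when - start
            counter[0] += 1
            name = f"t{counter[0]}"
            node.taxon = taxa.new_taxon(label=name)
            tip_states[name] = int(state)
        else:
            _, when, state, left, right = rec
            node.edge.length = when - start
            state_of_node[id(node)] = int(state)
            build(left, node.new_child(), when)
            build(right, node.new_child(), when)

    root = dt.seed_node
    _, when, state, left, right = top
    # the reconstructed root sits at time `when` (0 if both crown lineages survive)
    root.edge.length = 0.0
    state_of_node[id(root)] = int(state)
    build(left, root.new_child(), when)
    build(right, root.new_child(), when)
    tree = Tree(dt, dated=True)

    clade: Dict[int, frozenset] = {}
    node_states: Dict[frozenset, int] = {}
    st = state_of_node
    for nd in dt.postorder_node_iter():
        kids = nd.child_nodes()
        if not kids:
            clade[id(nd)] = frozenset([str(nd.taxon.label)])
        else:
            s: frozenset = frozenset()
            for k in kids:
                s |= clade[id(k)]
            clade[id(nd)] = s
            node_states[s] = st[id(nd)]
    return tree, tip_states, node_states


def simulate_bd(n: int, lam: float, mu: float, seed=None, rng=None,
                retry_cap: int = RETRY_CAP) -> Tree:
    """Constant-rate birth–death tree conditioned on ``n`` surviving tips.

    Forward Gillespie with reject-and-retry; extinct lineages are pruned so
    the returned tree is the reconstructed tree.  The number of rejected
    attempts is exposed as ``tree.metadata["retries"]``.
    """
    if lam <= mu or mu < 0:
        raise ParameterError("need lambda > mu >= 0")
    sim = simulate_bisse(BisseParams(lam, lam, mu, mu, 0.0, 0.0), n=n,
                         seed=seed, rng=rng, root_state=0, retry_cap=retry_cap)
    sim.tree.metadata["retries"] = sim.retries
    return sim.tree


# --------------------------------------------------------------------- #
# Mk2 character simulation on a fixed tree
# --------------------------------------------------------------------- #

@dataclass
class Mk2Simulation:
    tip_states: Dict[str, int]
    node_states: Dict[frozenset, int]   # bipartition (incl. root tip set) -> state
    root_state: int


def simulate_mk2(tree: Tree, q01: float, q10: float, root_prior="equal",
                 seed=None, rng=None) -> Mk2Simulation:
    """Evolve a binary character down a dated tree under the 2-state CTMC.

    At each branch the child state is drawn from the exact transition
    probabilities; both tip and internal-node truth are returned.
    """
    from .markov2 import mk2_transition_prob  # local import, no cycle

    if q01 < 0 or q10 < 0:
        raise ParameterError("rates must be >= 0")
    g = _rng(seed, rng)
    if root_prior == "equal":
        p1 = 0.5
    elif root_prior == "stationary":
        s = q01 + q10
        p1 = q01 / s if s > 0 else 0.5
    elif root_prior in (0, 1):
        p1 = float(root_prior)
    else:
        raise ParameterError(f"unknown root prior {root_prior!r}")
    root_state = int(g.random() < p1)

    dt = tree.dendropy_tree
    state: Dict[int, int] = {id(dt.seed_node): root_state}
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        ps = state[id(node.parent_node)]
        P = mk2_transition_prob(q01, q10, node.edge.length or 0.0)
        state[id(node)] = int(g.random() < P[ps, 1])

    tip_states: Dict[str, int] = {}
    node_states: Dict[frozenset, int] = {}
    clade: Dict[int, frozenset] = {}
    for node in dt.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            name = str(node.taxon.label)
            clade[id(node)] = frozenset([name])
            tip_states[name] = state[id(node)]
        else:
            s: frozenset = frozenset()
            for k in kids:
                s |= clade[id(k)]
            clade[id(node)] = s
            node_states[s] = state[id(node)]
    return Mk2Simulation(tip_states=tip_states, node_states=node_states,
                         root_state=root_state)


# --------------------------------------------------------------------- #
# clade-C-like fixture
# --------------------------------------------------------------------- #

@dataclass
class CladeCDataset:
    """Posterior-style sample of chronograms plus one tip-state table.

    Emulates the study conditions: ``n_trees`` dated 30-tip trees sharing one
    true topology with jittered node ages (crown age ~ 5.3 Myr), and a binary
    character with 8 derived (state-1) tips and 2 tips coded missing.  The
    generating truth (base tree, all tip states, internal-node states) is kept
    for recovery tests.
    """

    trees: List[Tree]
    tip_states: Dict[str, Optional[int]]      # with the 2 missing entries
    base_tree: Tree
    true_tip_states: Dict[str, int]           # no masking
    true_node_states: Dict[frozenset, int]
    params: BisseParams


#: generating regime for the fixture: the irreversible, extinction-free
#: two-parameter regime (λ_O = 0.68, q_OS = 0.21) the study's model ranking favours
CLADE_C_REGIME = BisseParams(0.68, 0.0, 0.0, 0.0, 0.21, 0.0)

CLADE_C_CROWN_AGE = 5.3


def make_clade_c_like_dataset(seed=None, rng=None, n_trees: int = 1000,
                              n_tips: int = 30, n_derived: int = 8,
                              n_missing: int = 2,
                              crown_age: float = CLADE_C_CROWN_AGE,
                              crown_jitter_sd: float = 0.05,
                              age_jitter_sd: float = 0.05,
                              params: BisseParams = CLADE_C_REGIME) -> CladeCDataset:
    """Generate the clade-C-like dataset (see :class:`CladeCDataset`).

    The base tree is simulated under ``params`` conditioned on ``n_tips`` tips
    and exactly ``n_derived`` derived tips, then rescaled to ``crown_age``.
    Each of the ``n_trees`` sample trees multiplies the crown age by a
    lognormal factor (sd ``crown_jitter_sd``) and jitters internal node ages
    (sd ``age_jitter_sd``) while preserving topology and ultrametricity.
    """
    g = _rng(seed, rng)
    base = None
    for _ in range(RETRY_CAP):
        sim = simulate_bisse(params, n=n_tips, rng=g, root_state=0)
        if sum(v == 1 for v in sim.tip_states.values()) == n_derived:
            base = sim
            break
    if base is None:
        raise ConvergenceError("could not condition on the derived-tip count")

    scale = crown_age / base.tree.crown_age
    base_tree = _scale_tree(base.tree, scale)

    zeros = sorted(k for k, v in base.tip_states.items() if v == 0)
    miss = set(g.choice(zeros, size=n_missing, replace=False))
    tips: Dict[str, Optional[int]] = {
        k: (MISSING if k in miss else v) for k, v in base.tip_states.items()}

    trees = [_jitter_ages(base_tree, g, crown_jitter_sd, age_jitter_sd)
             for _ in range(n_trees)]
    return CladeCDataset(trees=trees, tip_states=tips, base_tree=base_tree,
                         true_tip_states=dict(base.tip_states),
                         true_node_states=dict(base.node_states),
                         params=params)


def _scale_tree(tree: Tree, factor: float) -> Tree:
    dt = tree.dendropy_tree.clone(depth=1)
    for e in dt.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length * factor
    return Tree(dt, dated=True)


def _jitter_ages(tree: Tree, g: np.random.Generator,
                 crown_sd: float, age_sd: float) -> Tree:
    """Perturb node ages multiplicatively, preserving topology/ultrametricity."""
    dt = tree.dendropy_tree.clone(depth=1)
    src_age: Dict[int, float] = {}
    stack: Dict[int, float] = {}
    # source ages
    depth = {id(dt.seed_node): 0.0}
    for node in dt.preorder_node_iter():
        if node is not dt.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    h = max(depth[id(l)] for l in dt.leaf_node_iter())
    for node in dt.preorder_node_iter():
        src_age[id(node)] = h - depth[id(node)]

    new_age: Dict[int, float] = {}
    crown = h * float(np.exp(g.normal(0.0, crown_sd)))
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            new_age[id(node)] = crown
            continue
        if node.is_leaf():
            new_age[id(node)] = 0.0
            continue
        parent_new = new_age[id(node.parent_node)]
        rel = src_age[id(node)] / src_age[id(node.parent_node)]
        a = parent_new * rel * float(np.exp(g.normal(0.0, age_sd)))
        eps = 1e-9 * crown
        new_age[id(node)] = min(max(a, eps), parent_new - eps)
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            node.edge.length = 0.0
        else:
            node.edge.length = new_age[id(node.parent_node)] - new_age[id(node)]
    return Tree(dt, dated=True)
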