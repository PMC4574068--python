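"""Dated-tree data model and I/O.

Trees are rooted, dated (ultrametric) phylogenies with branch lengths in
millions of years (Myr); node ages are measured backward from the present, so
every extant tip sits at age 0 and the root age equals the crown age.  Parsing
and serialization of newick and NEXUS (with TRANSLATE tables) are delegated to
dendropy; everything on top — validation, branching times, lineage-through-time
curves, bipartition indexing — lives here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional

import dendropy
import numpy as np

from .errors import TreeFormatError, TreeValidationError

Bipartition = FrozenSet[str]

#: relative tolerance for the ultrametricity check: max tip age <= TOL * crown age
ULTRAMETRIC_RTOL = 1e-6


class Tree:
    """A rooted, optionally dated phylogeny.

    Thin wrapper around a :class:`dendropy.Tree` that validates the invariants
    the downstream likelihoods rely on (unique tip names, finite non-negative
    branch lengths, ultrametricity when ``dated``) and caches derived views
    (node ages, postorder index arrays, bipartitions).

    Parameters
    ----------
    dtree:
        The underlying dendropy tree.  Ownership is transferred; do not mutate
        it afterwards.
    dated:
        If True (default), the tree must be ultrametric within
        ``ultrametric_rtol`` × crown age; violations raise
        :class:`TreeValidationError` rather than being silently rescaled.
    """

    def __init__(self, dtree: dendropy.Tree, dated: bool = True,
                 ultrametric_rtol: float = ULTRAMETRIC_RTOL):
        self._dt = dtree
        self.dated = dated
        self.metadata: dict = {}
        self._cache: dict = {}
        self._validate(ultrametric_rtol)

    # ------------------------------------------------------------------ #
    # construction / validation
    # ------------------------------------------------------------------ #

    def _validate(self, rtol: float) -> None:
        root = self._dt.seed_node
        if root.edge.length is None:
            root.edge.length = 0.0
        names: List[str] = []
        for leaf in self._dt.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label):
                raise TreeValidationError("tip with empty/absent label")
            names.append(str(leaf.taxon.label))
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeValidationError(f"duplicate tip names: {dup}")
        for node in self._dt.preorder_node_iter():
            bl = node.edge.length
            if bl is None:
                if node is root or not self.dated:
                    node.edge.length = 0.0
                    continue
                raise TreeValidationError("branch without length")
            if not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(f"invalid branch length {bl!r}")
        # depths / ages
        depth: Dict[int, float] = {id(root): 0.0}
        for node in self._dt.preorder_node_iter():
            if node is root:
                continue
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        height = max((depth[id(l)] for l in self._dt.leaf_node_iter()),
                     default=0.0)
        self._age = {k: height - d for k, d in depth.items()}
        self._height = height
        if self.dated and self.n_tips > 1 and height > 0:
            worst = max(self._age[id(l)] for l in self._dt.leaf_node_iter())
            if worst > rtol * height:
                raise TreeValidationError(
                    f"tree flagged dated but not ultrametric: max tip age "
                    f"{worst:g} exceeds {rtol:g} x crown age {height:g}")

    @classmethod
    def from_newick(cls, text: str, dated: bool = True, **kw) -> "Tree":
        return parse_newick(text, dated=dated, **kw)

    # ------------------------------------------------------------------ #
    # basic views
    # ------------------------------------------------------------------ #

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dt

    @property
    def tip_names(self) -> List[str]:
        return [str(l.taxon.label) for l in self._dt.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._dt.leaf_node_iter())

    @property
    def crown_age(self) -> float:
        """Age of the root (Myr before present)."""
        return self._height

    @property
    def binary_root(self) -> bool:
        return len(self._dt.seed_node.child_nodes()) == 2

    def node_age(self, node: dendropy.Node) -> float:
        return self._age[id(node)]

    def internal_node_ages(self) -> np.ndarray:
        """Ages of internal nodes, one entry per child minus one (so polytomies
        count with multiplicity); sorted descending."""
        ages: List[float] = []
        for node in self._dt.preorder_internal_node_iter():
            k = len(node.child_nodes())
            if k >= 2:
                ages.extend([self._age[id(node)]] * (k - 1))
            elif k == 1 and node is not self._dt.seed_node:
                raise TreeValidationError("internal node with a single child")
        return np.sort(np.asarray(ages, dtype=float))[::-1]

    def is_binary(self) -> bool:
        return all(len(n.child_nodes()) == 2
                   for n in self._dt.preorder_internal_node_iter())

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #

    def to_newick(self) -> str:
        s = self._dt.as_string(schema="newick", suppress_rooting=True,
                               real_value_format_specifier=".12g")
        return s.strip()

    def clone(self) -> "Tree":
        return Tree(self._dt.clone(depth=1), dated=self.dated)

    # ------------------------------------------------------------------ #
    # index arrays for the likelihood kernels
    # ------------------------------------------------------------------ #

    def index_arrays(self) -> "TreeArrays":
        """Postorder array encoding of a strictly binary tree (cached)."""
        if "arrays" not in self._cache:
            self._cache["arrays"] = _build_arrays(self)
        return self._cache["arrays"]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Tree n_tips={self.n_tips} crown_age={self.crown_age:.4g}>"


@dataclass
class TreeArrays:
    """Flat postorder encoding of a binary tree.

    Nodes are numbered so that children always precede parents; the root is
    the last index.  ``left``/``right`` are −1 for tips.
    """

    n_nodes: int
    n_tips: int
    left: np.ndarray
    right: np.ndarray
    blen: np.ndarray            # branch length above each node (root: 0)
    age: np.ndarray             # node ages
    tip_index: Dict[str, int]   # tip name -> node index
    bipartitions: Dict[int, Bipartition]  # internal node index -> tip set


def _build_arrays(tree: Tree) -> TreeArrays:
    if not tree.is_binary():
        raise TreeValidationError("likelihood kernels require a binary tree")
    order = list(tree._dt.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(order)}
    n = len(order)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=float)
    age = np.zeros(n, dtype=float)
    tip_index: Dict[str, int] = {}
    biparts: Dict[int, Bipartition] = {}
    clade: Dict[int, frozenset] = {}
    for i, node in enumerate(order):
        blen[i] = node.edge.length or 0.0
        age[i] = tree.node_age(node)
        kids = node.child_nodes()
        if not kids:
            tip_index[str(node.taxon.label)] = i
            clade[i] = frozenset([str(node.taxon.label)])
        else:
            left[i] = idx[id(kids[0])]
            right[i] = idx[id(kids[1])]
            clade[i] = clade[left[i]] | clade[right[i]]
            biparts[i] = clade[i]
    return TreeArrays(n_nodes=n, n_tips=len(tip_index), left=left, right=right,
                      blen=blen, age=age, tip_index=tip_index,
                      bipartitions=biparts)


# ---------------------------------------------------------------------- #
# parsing / writing
# ---------------------------------------------------------------------- #

def parse_newick(text: str, dated: bool = True,
                 ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> Tree:
    """Parse a single newick string into a :class:`Tree`.

    Malformed input raises :class:`TreeFormatError` carrying dendropy's
    diagnostic (line/column of the offending token).
    """
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True,
                               rooting="force-rooted")
    except Exception as exc:  # dendropy raises several tokenizer errors
        raise TreeFormatError(f"newick parse failure: {exc}") from exc
    if dt.seed_node is None or not any(dt.leaf_node_iter()):
        raise TreeFormatError("newick parse produced an empty tree")
    return Tree(dt, dated=dated, ultrametric_rtol=ultrametric_rtol)


def write_newick(tree: Tree) -> str:
    return tree.to_newick()


def write_newick_lines(trees: Iterable[Tree]) -> str:
    """Serialize trees one-newick-per-line."""
    return "\n".join(t.to_newick() for t in trees) + "\n"


def parse_newick_lines(text: str, dated: bool = True) -> List[Tree]:
    return [parse_newick(line, dated=dated)
            for line in text.splitlines() if line.strip()]


def parse_nexus_trees(text: str, dated: bool = True) -> List[Tree]:
    """Parse all trees from a NEXUS TREES block (TRANSLATE table honoured,
    square-bracket comments ignored), in file order, labels de-translated."""
    if not re.search(r"begin\s+trees", text, flags=re.IGNORECASE):
        raise TreeFormatError("NEXUS input lacks a TREES block")
    try:
        tl = dendropy.TreeList.get(data=text, schema="nexus",
                                   suppress_internal_node_taxa=True,
                                   rooting="force-rooted")
    except Exception as exc:
        raise TreeFormatError(f"NEXUS parse failure: {exc}") from exc
    return [Tree(dt, dated=dated) for dt in tl]


def write_nexus_trees(trees: List[Tree]) -> str:
    """Write trees into a minimal NEXUS TREES block (no translate table)."""
    lines = ["#NEXUS", "BEGIN TREES;"]
    for i, t in enumerate(trees):
        lines.append(f"    TREE tree_{i + 1} = [&R] {t.to_newick()}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------- #
# branching times & LTT
# ---------------------------------------------------------------------- #

@dataclass
class BranchingTimes:
    """Node ages of a reconstructed dated tree.

    ``ages[0] = t_2`` is the crown age; ``ages[i]`` is the age at which the
    reconstructed tree went from ``i+1`` to ``i+2`` lineages.  Length is
    ``N − 1`` for an ``N``-tip tree (polytomies counted with multiplicity).
    """

    ages: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.ndim != 1 or self.ages.size < 1:
            raise TreeValidationError("branching times need >=1 age")
        if np.any(np.diff(self.ages) > 0):
            raise TreeValidationError("branching times must be non-increasing")
        if np.any(self.ages <= 0):
            raise TreeValidationError("branching times must be positive")

    @property
    def n_tips(self) -> int:
        return self.ages.size + 1

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])


def branching_times(tree: Tree) -> BranchingTimes:
    """Extract branching times from a dated ultrametric tree (N >= 2)."""
    if not tree.dated:
        raise TreeValidationError("branching times require a dated tree")
    if tree.n_tips < 2:
        raise TreeValidationError("branching times require >= 2 tips")
    return BranchingTimes(tree.internal_node_ages())


@dataclass
class LTTCurve:
    """Lineage-through-time curve: event ages (descending, Myr before present)
    and the lineage count immediately after each event."""

    ages: np.ndarray
    counts: np.ndarray

    @property
    def log_counts(self) -> np.ndarray:
        return np.log(self.counts)

    @property
    def n_tips(self) -> int:
        return int(self.counts[-1])


def ltt_curve(tree: Tree) -> LTTCurve:
    bt = branching_times(tree)
    ages, mult = np.unique(np.round(bt.ages, 12), return_counts=True)
    ages = ages[::-1]
    mult = mult[::-1]
    counts = 1 + np.cumsum(mult)
    return LTTCurve(ages=ages, counts=counts)


def pooled_ltt_slope(trees: Iterable[Tree]) -> float:
    """Mean per-tree OLS slope of log lineage count vs. time since the crown.

    Under a rate-constant process this approximately estimates the net
    diversification rate r (pooling the regression points of trees with very
    different total durations instead would shrink the slope).
    """
    slopes: List[float] = []
    for t in trees:
        c = ltt_curve(t)
        if c.ages.size < 2:
            continue
        x = c.ages[0] - c.ages              # time since crown
        slopes.append(float(np.polyfit(x, np.log(c.counts), 1)[0]))
    return float(np.mean(slopes))


# ---------------------------------------------------------------------- #
# bipartitions
# ---------------------------------------------------------------------- #

ABSENT = "absent"


def bipartition_index(tree: Tree, include_root: bool = False):
    """Map each internal node's descendant tip set to the node.

    Returns a dict-like with ``.get(bipartition, ABSENT)`` semantics; the root
    (whose bipartition is the full tip set) is excluded unless
    ``include_root``.
    """
    arr = tree.index_arrays() if tree.is_binary() else None
    out: Dict[Bipartition, dendropy.Node] = {}
    full = frozenset(tree.tip_names)
    clade: Dict[int, frozenset] = {}
    for node in tree._dt.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            clade[id(node)] = frozenset([str(node.taxon.label)])
        else:
            s: frozenset = frozenset()
            for k in kids:
                s = s | clade[id(k)]
            clade[id(node)] = s
            if s != full or include_root:
                out[s] = node
    return out


def bipartition_frequencies(trees: List[Tree]) -> Dict[Bipartition, float]:
    """Fraction of trees containing each (non-root) bipartition."""
    counts: Dict[Bipartition, int] = {}
    for t in trees:
        for bp in bipartition_index(t):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    return {bp: c / n for bp, c in counts.items()}
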