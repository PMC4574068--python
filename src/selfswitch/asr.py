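"""Ancestral-state containers and averaging across a tree sample.

Node identity across trees is by bipartition: the frozen set of tip names
descending from the node.  This is what lets per-tree marginal
reconstructions from a posterior sample be summarized onto one reference
topology ("mean relative posterior probabilities" per node).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional

import numpy as np

from .errors import DataError
from .treeio import Tree, bipartition_index

Bipartition = FrozenSet[str]


@dataclass
class AncestralStates:
    """Per-node marginal state probabilities keyed by bipartition.

    ``probs[bp]`` is a length-2 array (P(state 0), P(state 1)) summing to 1;
    ``support[bp]`` counts how many source trees contributed to the entry
    (1 for a single-tree reconstruction).  Entries with ``support == 0`` are
    unsupported placeholders produced by :func:`asr_average` when no source
    tree contains the queried bipartition.
    """

    probs: Dict[Bipartition, np.ndarray]
    support: Dict[Bipartition, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.support:
            self.support = {bp: 1 for bp in self.probs}
        for bp, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if self.support.get(bp, 0) > 0:
                if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
                    raise DataError(f"invalid probability vector {p} at {set(bp)}")
            self.probs[bp] = p

    def p1(self, bp: Bipartition) -> float:
        return float(self.probs[bp][1])

    def modal_state(self, bp: Bipartition) -> int:
        """Modal state: 1 iff P(state 1) > 0.5 (exact ties fall to state 0,
        the ancestral state)."""
        return int(self.probs[bp][1] > 0.5)

    def items(self):
        return self.probs.items()

    def __len__(self) -> int:
        return len(self.probs)


def asr_average(per_tree: List[AncestralStates], reference: Tree,
                absent: str = "skip") -> AncestralStates:
    """Average per-tree node reconstructions onto a reference topology.

    For each internal node (bipartition) of ``reference``:

    - ``absent="skip"`` (default): average the probability vectors over the
      source trees that contain the bipartition; the support count records how
      many did.
    - ``absent="zero"``: a source tree lacking the bipartition contributes
      probability 0 of the derived state (the mean P(state 1) is divided by
      the total number of trees, and P(state 0) is its complement).

    A bipartition contained in no source tree is returned with support 0 and
    a NaN probability vector.
    """
    if absent not in ("skip", "zero"):
        raise DataError(f"absent must be 'skip' or 'zero', got {absent!r}")
    ref_bps = list(bipartition_index(reference, include_root=True))
    n_total = len(per_tree)
    probs: Dict[Bipartition, np.ndarray] = {}
    support: Dict[Bipartition, int] = {}
    for bp in ref_bps:
        vecs = [a.probs[bp] for a in per_tree if bp in a.probs]
        support[bp] = len(vecs)
        if not vecs:
            probs[bp] = np.array([np.nan, np.nan])
        elif absent == "skip":
            probs[bp] = np.mean(vecs, axis=0)
        else:
            p1 = sum(float(v[1]) for v in vecs) / n_total
            probs[bp] = np.array([1.0 - p1, p1])
    return AncestralStates(probs=probs, support=support)
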