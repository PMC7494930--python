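"""Topological and branch-length agreement between trees.

Two standard statistics quantify how well trees from different markers or
methods agree: the Robinson–Foulds distance (number of non-trivial
bipartitions present in exactly one tree) and the Kuhner–Felsenfeld branch
score (square root of the summed squared branch-length differences over the
union of bipartitions, absent bipartitions counting as length zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .markers import bipartitions


@dataclass
class TreeComparison:
    rf: int
    rf_max: int
    normalized_rf: float
    branch_score: float


def _check_leaf_sets(t1: TreeNode, t2: TreeNode) -> list[str]:
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return sorted(l1)


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Count of non-trivial bipartitions present in exactly one tree."""
    _check_leaf_sets(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def _bipartition_lengths(tree: TreeNode) -> dict[frozenset[str], float]:
    """Branch length per non-trivial bipartition (summed over parallel
    degree-2 edges, which arise when a rooted tree is treated as unrooted)."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: dict[frozenset[str], float] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[side] = out.get(side, 0.0) + float(node.length or 0.0)
    return out


def branch_score(t1: TreeNode, t2: TreeNode, include_pendant: bool = True) -> float:
    """Kuhner–Felsenfeld branch score.

    Sums squared branch-length differences over the union of bipartitions
    (0 where absent) plus, by default, the pendant (leaf) edges.
    """
    names = _check_leaf_sets(t1, t2)
    b1 = _bipartition_lengths(t1)
    b2 = _bipartition_lengths(t2)
    total = 0.0
    for bp in set(b1) | set(b2):
        total += (b1.get(bp, 0.0) - b2.get(bp, 0.0)) ** 2
    if include_pendant:
        p1 = {t.name: float(t.length or 0.0) for t in t1.tips()}
        p2 = {t.name: float(t.length or 0.0) for t in t2.tips()}
        for name in names:
            total += (p1[name] - p2[name]) ** 2
    return float(np.sqrt(total))


def compare_trees(t1: TreeNode, t2: TreeNode) -> TreeComparison:
    """RF, normalized RF (over 2(n-3)) and branch score in one record."""
    names = _check_leaf_sets(t1, t2)
    n = len(names)
    rf = rf_distance(t1, t2)
    rf_max = max(2 * (n - 3), 1)
    return TreeComparison(rf, rf_max, rf / rf_max, branch_score(t1, t2))
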