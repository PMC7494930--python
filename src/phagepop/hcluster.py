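"""UPGMA dendrograms and cut-height cluster calling.

The cluster-defining step of the analysis: average-linkage (UPGMA)
agglomeration of a binary distance matrix, followed by cutting the
dendrogram at a fixed height. Merge heights are the average inter-cluster
distance itself (not halved), the convention under which published cut-off
heights such as 0.82 or 0.52 on Jaccard distances are directly meaningful.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .kmers import DistanceMatrix


@dataclass
class Dendrogram:
    """Rooted ultrametric cluster tree as an ordered merge list.

    ``merges[i] = (a, b, height)`` joins nodes ``a`` and ``b`` at ``height``.
    Leaves are numbered 0..n-1 in label order; merge i creates node n+i
    (scipy linkage convention).
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves must have n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(h < 0 for h in heights):
            raise ValueError("negative merge height")
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def leaf_sets(self) -> list[frozenset[int]]:
        """Leaf-index set under every node, indexed by node id."""
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(self.n_leaves)]
        for a, b, _h in self.merges:
            sets.append(sets[a] | sets[b])
        return sets

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise merge heights (the cophenetic distances)."""
        n = self.n_leaves
        d = np.zeros((n, n))
        sets = [frozenset([i]) for i in range(n)]
        for a, b, h in self.merges:
            for i in sets[a]:
                for j in sets[b]:
                    d[i, j] = d[j, i] = h
            sets.append(sets[a] | sets[b])
        return DistanceMatrix(list(self.labels), d)


@dataclass
class ClusterAssignment:
    """Genome → cluster-label map produced by cutting a dendrogram."""

    cut_height: float
    labels: dict[str, str]

    def as_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for genome, lab in self.labels.items():
            out.setdefault(lab, set()).add(genome)
        return out


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with deterministic tie-breaking.

    At every step the pair of active nodes with the smallest average
    inter-cluster distance is merged; ties are broken by the lowest
    (node-id, node-id) pair. Merge height is the average distance itself.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if np.isnan(matrix.values).any():
        raise ValueError("NaN in distance matrix")
    # active distance bookkeeping over node ids
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.values[i, j])
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        merges.append((a, b, h))
        active.discard(a)
        active.discard(b)
        sa, sb = sizes[a], sizes[b]
        new_dists = {}
        for c in active:
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            new_dists[(c, next_id)] = (sa * da + sb * db) / (sa + sb)
        del dist[(a, b)]
        dist.update(new_dists)
        sizes[next_id] = sa + sb
        active.add(next_id)
        next_id += 1
    return Dendrogram(list(matrix.labels), merges)


def _cluster_letters(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... (spreadsheet-style)."""
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


def _flat_clusters(dend: Dendrogram, height: float) -> list[set[int]]:
    """Maximal groups whose internal merge heights are all strictly < height."""
    parent = list(range(dend.n_leaves + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sets = [frozenset([i]) for i in range(dend.n_leaves)]
    for idx, (a, b, h) in enumerate(dend.merges):
        node = dend.n_leaves + idx
        sets.append(sets[a] | sets[b])
        if h < height:
            parent[find(a)] = node
            parent[find(b)] = node
    groups: dict[int, set[int]] = {}
    for leaf in range(dend.n_leaves):
        groups.setdefault(find(leaf), set()).add(leaf)
    return list(groups.values())


def _label_clusters(
    dend: Dendrogram, groups: list[set[int]], height: float, names: list[str] | None = None
) -> ClusterAssignment:
    # order: decreasing size, ties by lexicographically smallest member label
    keyed = sorted(groups, key=lambda g: (-len(g), min(dend.labels[i] for i in g)))
    labels: dict[str, str] = {}
    for rank, group in enumerate(keyed):
        name = names[rank] if names is not None else _cluster_letters(rank)
        for i in group:
            labels[dend.labels[i]] = name
    return ClusterAssignment(height, labels)


def cut_dendrogram(dend: Dendrogram, height: float) -> ClusterAssignment:
    """Cut at ``height``: connected subtrees below the cut become clusters.

    Clusters are lettered A, B, C, ... by decreasing size (ties by smallest
    member label). Letters are presentation only — assertions about cluster
    identity should compare partitions, not letters.
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    groups = _flat_clusters(dend, height)
    return _label_clusters(dend, groups, height)


def subcluster(
    dend: Dendrogram, parent: ClusterAssignment, lower_height: float
) -> ClusterAssignment:
    """Refine a parent cut at a lower height, labelling subclusters A1, A2, ...

    Every subcluster is a subset of exactly one parent cluster; a parent
    cluster that does not split keeps a single numbered subcluster label.
    """
    if lower_height >= parent.cut_height:
        raise ValueError(
            f"subcluster height {lower_height} must be below parent cut "
            f"{parent.cut_height}"
        )
    groups = _flat_clusters(dend, lower_height)
    # order subgroups globally (size, then smallest member), then number
    # within each parent cluster in that order
    keyed = sorted(groups, key=lambda g: (-len(g), min(dend.labels[i] for i in g)))
    counters: dict[str, int] = {}
    labels: dict[str, str] = {}
    for group in keyed:
        members = [dend.labels[i] for i in group]
        parents = {parent.labels[m] for m in members}
        if len(parents) != 1:
            raise AssertionError("subcluster spans parent clusters (non-nested cut)")
        p = parents.pop()
        counters[p] = counters.get(p, 0) + 1
        for m in members:
            labels[m] = f"{p}{counters[p]}"
    return ClusterAssignment(lower_height, labels)


def dendrogram_to_tree(dend: Dendrogram) -> TreeNode:
    """Convert to a rooted skbio tree; branch lengths make leaf depth = h/2.

    Cophenetic distance between two leaves in the returned tree equals the
    merge height (each leaf contributes h/2 of path).
    """
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dend.labels]
    depth = [0.0] * dend.n_leaves
    for a, b, h in dend.merges:
        na, nb = nodes[a], nodes[b]
        na.length = h / 2 - depth[a]
        nb.length = h / 2 - depth[b]
        parent = TreeNode(children=[na, nb])
        nodes.append(parent)
        depth.append(h / 2)
    root = nodes[-1]
    root.length = None
    return root
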