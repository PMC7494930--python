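"""Marker-gene phylogenies: alignment, TN93 distances, NJ trees, bootstrap.

Semi-conserved phage marker genes (terminase large subunit, portal protein,
exonucleases) are aligned with a simple deterministic progressive aligner
(UPGMA guide tree on pairwise p-distances; profile–profile global alignment
with affine gaps), pairwise distances are computed under the Tamura–Nei
(TN93) substitution model in closed form, trees are built with
Saitou–Nei neighbor joining, and internal-edge support is estimated by
column-resampling bootstrap. Distance-based NJ stands in for full maximum
likelihood: it is deterministic, fast, and sufficient to resolve
cluster-level structure, which is what downstream stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from numba import njit
from skbio import TreeNode

from .kmers import DistanceMatrix

GAP = "-"

# marker products recognised when pulling marker genes out of annotations
MARKER_PRODUCTS = {
    "terminase_large": "terminase large subunit",
    "portal": "portal protein",
    "exonuclease": "exonuclease",
}


class SaturationError(ValueError):
    """TN93 logarithm argument <= 0: the pair is too diverged to correct."""


@dataclass
class Alignment:
    """Equal-length gapped rows over {A,C,G,T,-}, with ordered ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def columns_resampled(self, rng: np.random.Generator) -> "Alignment":
        idx = rng.integers(0, self.length, size=self.length)
        arr = np.array([list(r) for r in self.rows])
        return Alignment(list(self.ids), ["".join(row) for row in arr[:, idx]])


@dataclass
class TN93Estimate:
    """Closed-form TN93 distance and its sufficient statistics."""

    P1: float  # purine-transition proportion (A<->G)
    P2: float  # pyrimidine-transition proportion (C<->T)
    Q: float  # transversion proportion
    gA: float
    gC: float
    gG: float
    gT: float
    d: float


# ---------------------------------------------------------------------------
# progressive alignment

_pair_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def _pairwise_p_distance(a: str, b: str) -> float:
    aln = _pair_aligner.align(a, b)[0]
    c = aln.counts()
    length = c.identities + c.mismatches + c.gaps
    return 1.0 - c.identities / length


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, GAP: 4}


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 4) base-frequency profile; gap characters carry zero weight."""
    L = len(rows[0])
    prof = np.zeros((L, 4))
    for r in rows:
        arr = np.frombuffer(r.encode(), dtype=np.uint8)
        for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            prof[arr == ord(base), code] += 1.0
    return prof / len(rows)


@njit(cache=False)
def _gotoh(sub, open_pen, ext_pen):  # pragma: no cover - numba kernel
    """Affine-gap global profile alignment over a precomputed column-score
    matrix. Returns the traceback path as an array of moves
    (0 diagonal, 1 up/gap-in-B, 2 left/gap-in-A)."""
    n, m = sub.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A row)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B col)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_pen + (i - 1) * ext_pen
    for j in range(1, m + 1):
        Y[0, j] = open_pen + (j - 1) * ext_pen
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(
                M[i - 1, j] + open_pen, X[i - 1, j] + ext_pen, Y[i - 1, j] + open_pen
            )
            Y[i, j] = max(
                M[i, j - 1] + open_pen, Y[i, j - 1] + ext_pen, X[i, j - 1] + open_pen
            )
    # traceback
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0
    if X[n, m] > M[n, m] and X[n, m] >= Y[n, m]:
        state = 1
    elif Y[n, m] > M[n, m]:
        state = 2
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            moves[k] = 0
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i -= 1
            j -= 1
            if prev == M[i, j]:
                state = 0
            elif prev == X[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            moves[k] = 1
            val = X[i, j]
            if val == M[i - 1, j] + open_pen:
                nxt = 0
            elif val == X[i - 1, j] + ext_pen:
                nxt = 1
            else:
                nxt = 2
            i -= 1
            state = nxt
        else:
            moves[k] = 2
            val = Y[i, j]
            if val == M[i, j - 1] + open_pen:
                nxt = 0
            elif val == Y[i, j - 1] + ext_pen:
                nxt = 2
            else:
                nxt = 1
            j -= 1
            state = nxt
        k += 1
    return moves[:k][::-1].copy()


_SUBST = np.full((4, 4), -1.0) + 2.0 * np.eye(4)  # +1 match, -1 mismatch


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    pa = _profile(rows_a)
    pb = _profile(rows_b)
    sub = pa @ _SUBST @ pb.T
    moves = _gotoh(sub, -5.0, -1.0)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves:
        if mv == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            i += 1
            j += 1
        elif mv == 1:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(seqs: list[tuple[str, str]]) -> Alignment:
    """Progressive multiple alignment of (id, sequence) pairs.

    Guide tree: UPGMA on p-distances of pairwise global alignments
    (+1/-1, gap open -5, extend -1); profiles merged leaf-to-root with the
    same scoring. Deterministic.
    """
    from .hcluster import upgma

    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = [s[0] for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    for _sid, s in seqs:
        if set(s) - set("ACGT"):
            raise ValueError(f"sequence {_sid!r} contains non-ACGT characters")
    n = len(seqs)
    pmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pmat[i, j] = pmat[j, i] = _pairwise_p_distance(seqs[i][1], seqs[j][1])
    guide = upgma(DistanceMatrix(ids, pmat))

    # merge following the guide tree's merge list
    partial: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i][1]]) for i in range(n)
    }
    for idx, (a, b, _h) in enumerate(guide.merges):
        ids_a, rows_a = partial.pop(a)
        ids_b, rows_b = partial.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b)
        partial[n + idx] = (ids_a + ids_b, new_a + new_b)
    final_ids, final_rows = partial[2 * n - 2]
    order = [final_ids.index(i) for i in ids]
    return Alignment(ids, [final_rows[k] for k in order])


# ---------------------------------------------------------------------------
# TN93 distance

_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _ENC.items():
    _CODE[ord(_b)] = _c


def _encode(row: str) -> np.ndarray:
    return _CODE[np.frombuffer(row.encode(), dtype=np.uint8)]


def tn93_distance(row_a: str, row_b: str) -> TN93Estimate:
    """Closed-form TN93 distance between two aligned rows.

    Columns where either row has a gap or ambiguous character are excluded
    (pairwise deletion). Base frequencies are pooled over the two rows.
    Raises :class:`SaturationError` when a logarithm argument is <= 0.
    """
    a = _encode(row_a)
    b = _encode(row_b)
    if len(a) != len(b):
        raise ValueError("rows differ in length")
    usable = (a < 4) & (b < 4)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no usable (gap-free) columns for the pair")
    a = a[usable]
    b = b[usable]
    counts = np.bincount(np.concatenate([a, b]), minlength=4) / (2 * n)
    gA, gC, gG, gT = (float(x) for x in counts)
    diff = a != b
    purine = (a % 2 == 0) & (b % 2 == 0)  # A=0, G=2
    pyrim = (a % 2 == 1) & (b % 2 == 1)  # C=1, T=3
    P1 = float((diff & purine).mean())
    P2 = float((diff & pyrim).mean())
    Q = float((diff & ~purine & ~pyrim).mean())
    if P1 == P2 == Q == 0.0:
        return TN93Estimate(0.0, 0.0, 0.0, gA, gC, gG, gT, 0.0)

    gR = gA + gG
    gY = gC + gT
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0) - (gC * gT * gR / gY if gY > 0 else 0.0))
    w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
    w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
    w3 = 1 - Q / (2 * gR * gY) if gR * gY > 0 else 1.0
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError(
            f"TN93 saturation: log arguments ({w1:.4g}, {w2:.4g}, {w3:.4g})"
        )
    d = -(k1 * np.log(w1) if k1 > 0 else 0.0) - (k2 * np.log(w2) if k2 > 0 else 0.0) - k3 * np.log(w3)
    return TN93Estimate(P1, P2, Q, gA, gC, gG, gT, float(d))


def tn93_matrix(alignment: Alignment, saturation: str = "error") -> DistanceMatrix:
    """All-pairs TN93 distances. ``saturation='cap'`` replaces saturated
    pairs with a large finite distance (used inside bootstrap replicates)."""
    n = len(alignment.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = tn93_distance(alignment.rows[i], alignment.rows[j])
                d[i, j] = d[j, i] = est.d
            except SaturationError:
                if saturation == "cap":
                    d[i, j] = d[j, i] = 5.0
                else:
                    raise
    return DistanceMatrix(list(alignment.ids), d)


def p_distance(row_a: str, row_b: str) -> float:
    """Observed proportion of differing usable columns (pairwise deletion)."""
    a = _encode(row_a)
    b = _encode(row_b)
    usable = (a < 4) & (b < 4)
    if not usable.any():
        raise ValueError("no usable columns")
    return float((a[usable] != b[usable]).mean())


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. Returns an unrooted tree as a trifurcating root.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(matrix.values).any():
        raise ValueError("NaN in distance matrix")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]
    names: list[str] = list(matrix.labels)
    D = matrix.values.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length = float(li)
        nj_.length = float(lj)
        parent = TreeNode(children=[ni, nj_])
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = (D[i, k] + D[j, k] - D[i, j]) / 2
        nodes.append(parent)
        names.append(min(names[i], names[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    x, y, z = active
    lx = (D[x, y] + D[x, z] - D[y, z]) / 2
    ly = (D[x, y] + D[y, z] - D[x, z]) / 2
    lz = (D[x, z] + D[y, z] - D[x, y]) / 2
    children = []
    for k, lk in ((x, lx), (y, ly), (z, lz)):
        nodes[k].length = float(max(lk, 0.0))
        children.append(nodes[k])
    return TreeNode(children=children)


# ---------------------------------------------------------------------------
# bootstrap


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each encoded as the side not containing the
    lexicographically smallest leaf (rooting-invariant)."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    alignment: Alignment, n_replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """Point-estimate NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement; each replicate is re-analysed
    with TN93 + NJ; support is the percentage of replicates containing each
    internal bipartition of the point tree, stored as integer internal node
    names. Seed-deterministic.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = nj_tree(tn93_matrix(alignment, saturation="cap"))
    target = bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = alignment.columns_resampled(rng)
        try:
            tree = nj_tree(tn93_matrix(rep, saturation="cap"))
        except ValueError:
            continue
        found = bipartitions(tree)
        for bp in target:
            if bp in found:
                counts[bp] += 1

    leaves = sorted(t.name for t in point.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if side in counts:
            node.name = str(int(round(100 * counts[side] / n_replicates)))
    return point


def extract_marker_sequences(
    genomes, annotations, marker: str
) -> list[tuple[str, str]]:
    """Marker gene sequences as (leaf_label, sequence) pairs.

    Genomes with multiple copies of the marker contribute one leaf per copy,
    labelled ``genomeid__copyN``.
    """
    if marker not in MARKER_PRODUCTS:
        raise ValueError(f"unknown marker {marker!r}; choose from {sorted(MARKER_PRODUCTS)}")
    product = MARKER_PRODUCTS[marker]
    by_id = {g.id: g for g in genomes}
    per_genome: dict[str, list[str]] = {}
    for a in annotations:
        if a.product == product:
            per_genome.setdefault(a.genome_id, []).append(a.extract(by_id[a.genome_id]))
    out = []
    for gid in sorted(per_genome):
        copies = per_genome[gid]
        if len(copies) == 1:
            out.append((gid, copies[0]))
        else:
            out.extend((f"{gid}__copy{i + 1}", s) for i, s in enumerate(copies))
    return out
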