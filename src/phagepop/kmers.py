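"""Canonical k-mer presence/absence profiles and binary (Jaccard) distances.

Whole-genome diversity is measured alignment-free: each genome is reduced to
the set of its canonical k-mers (the lexicographically smaller of a window
and its reverse complement, so profiles are strand-invariant), and pairs of
genomes are compared with the asymmetric binary distance

    d(A, B) = |A △ B| / |A ∪ B|

which ignores joint absences. The study behind this package used k = 10 and
k = 21; both are supported and k is a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PhageGenome, revcomp


@dataclass(frozen=True)
class KmerProfile:
    genome_id: str
    k: int
    kmers: frozenset[str]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical k-mers of ``seq``; windows containing N are skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = seq.upper()
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    rc = revcomp(seq)
    n = len(seq)
    out: set[str] = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def profile(genome: PhageGenome, k: int) -> KmerProfile:
    return KmerProfile(genome.id, k, frozenset(canonical_kmers(genome.sequence, k)))


def binary_distance(a: KmerProfile, b: KmerProfile) -> float:
    """Jaccard distance between two presence/absence profiles."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    return jaccard_distance(a.kmers, b.kmers)


def jaccard_distance(a: frozenset | set, b: frozenset | set) -> float:
    """|A △ B| / |A ∪ B|, the binary distance over presence/absence sets."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard distance undefined: both sets empty")
    return len(a ^ b) / union


def kmer_distance_matrix(genomes: list[PhageGenome], k: int = 10) -> DistanceMatrix:
    """Pairwise binary distance over canonical k-mer profiles.

    Label order equals input order; duplicate genome ids are rejected.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    profiles = [profile(g, k) for g in genomes]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = binary_distance(profiles[i], profiles[j])
    return DistanceMatrix(ids, d)
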