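"""Ortholog-family clustering, gene presence/absence, and pan-genome partition.

Gene families are built by greedy incremental clustering at a global
nucleotide identity threshold (default 90%, the `-i 90` convention of
Roary-style pan-genome tools, though identity here is nucleotide-level, not
translated): genes are processed longest-first and each joins the first
existing family whose representative it matches at or above the threshold,
else founds a new family. Presence/absence of families defines the binary
profile per genome; the Jaccard distance over those profiles is the
gene-content analogue of the k-mer distance. The pan genome is partitioned
by family prevalence into core (>=99% of genomes), softcore (95-99%),
shell (15-95%) and cloud (<15%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from Bio import Align

from .io import GeneAnnotation, PhageGenome
from .kmers import DistanceMatrix, canonical_kmers, jaccard_distance

PRESCREEN_WORD = 15
PRESCREEN_MIN_FRACTION = 0.05


@dataclass
class GeneFamily:
    family_id: str
    representative: str  # gene id
    representative_seq: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class PanGenomeSummary:
    cluster_id: str
    n_genomes: int
    core: int
    softcore: int
    shell: int
    cloud: int

    @property
    def pan(self) -> int:
        return self.core + self.softcore + self.shell + self.cloud

    @property
    def n_core_genes(self) -> int:
        return self.core + self.softcore

    @property
    def n_accessory_genes(self) -> int:
        return self.shell + self.cloud

    @property
    def core_pct(self) -> int:
        return round_half_up(100 * self.n_core_genes / self.pan)

    @property
    def accessory_pct(self) -> int:
        return round_half_up(100 * self.n_accessory_genes / self.pan)


def round_half_up(x: float, decimals: int = 0) -> float | int:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    v = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return int(v) if decimals == 0 else float(v)


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def global_identity(a: str, b: str) -> float:
    """Matches / alignment length under global alignment (+1/-1, gap -2).

    Gap columns count against identity. A fast exact path is used when the
    sequences have equal length and their best alignment is gapless.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    return _identity_from_alignment(aln)


def _hamming_identity(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((arr_a == arr_b).mean())


def _identity_from_alignment(aln) -> float:
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def extract_gene_sequences(
    genomes: list[PhageGenome], annotations: list[GeneAnnotation]
) -> dict[str, str]:
    """Strand-correct nucleotide sequence per gene id."""
    by_id = {g.id: g for g in genomes}
    out = {}
    for a in annotations:
        out[a.gene_id] = a.extract(by_id[a.genome_id])
    return out


def cluster_gene_families(
    genes: list[tuple[str, str, str]],
    identity_threshold: float = 0.90,
) -> list[GeneFamily]:
    """Greedy incremental clustering of (genome_id, gene_id, sequence) triples.

    Deterministic: genes are sorted by length descending (ties by gene id);
    each joins the earliest-founded family whose representative it matches at
    >= ``identity_threshold`` global identity, else founds a new family.
    Candidate families are prescreened by shared canonical 15-mer content
    (CD-HIT-style short-word filter) before the exact alignment is computed.
    """
    if not genes:
        raise ValueError("empty gene set")
    ordered = sorted(genes, key=lambda t: (-len(t[2]), t[1]))
    families: list[GeneFamily] = []
    word_index: dict[str, set[int]] = {}

    for genome_id, gene_id, seq in ordered:
        words = canonical_kmers(seq, min(PRESCREEN_WORD, len(seq)))
        min_shared = max(1, int(PRESCREEN_MIN_FRACTION * len(words)))
        hits: dict[int, int] = {}
        for w in words:
            for fi in word_index.get(w, ()):
                hits[fi] = hits.get(fi, 0) + 1
        placed = False
        for fi in sorted(fi for fi, c in hits.items() if c >= min_shared):
            fam = families[fi]
            rep = fam.representative_seq
            # gapless fast path: an equal-length pair whose positional
            # identity already clears the threshold cannot score worse
            # under the optimal alignment
            if len(seq) == len(rep) and _hamming_identity(seq, rep) >= identity_threshold:
                fam.members.append((genome_id, gene_id))
                placed = True
                break
            if global_identity(seq, rep) >= identity_threshold:
                fam.members.append((genome_id, gene_id))
                placed = True
                break
        if not placed:
            fi = len(families)
            families.append(
                GeneFamily(
                    family_id=f"F{fi:05d}",
                    representative=gene_id,
                    representative_seq=seq,
                    members=[(genome_id, gene_id)],
                )
            )
            for w in words:
                word_index.setdefault(w, set()).add(fi)
    return families


def presence_absence_matrix(
    families: list[GeneFamily], genome_ids: list[str]
) -> pd.DataFrame:
    """0/1 DataFrame (genomes x families); paralogs collapse to 1."""
    mat = pd.DataFrame(
        0, index=list(genome_ids), columns=[f.family_id for f in families], dtype=int
    )
    for fam in families:
        for genome_id, _gene_id in fam.members:
            if genome_id in mat.index:
                mat.loc[genome_id, fam.family_id] = 1
    return mat


def gene_content_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance between genomes' family sets."""
    if len(matrix.index) < 2:
        raise ValueError("need at least 2 genomes")
    sets = {}
    for gid in matrix.index:
        fams = set(matrix.columns[matrix.loc[gid] == 1])
        if not fams:
            raise ValueError(f"genome {gid!r} has no gene families")
        sets[gid] = fams
    ids = list(matrix.index)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(sets[ids[i]], sets[ids[j]])
    return DistanceMatrix(ids, d)


def partition_pan_genome(matrix: pd.DataFrame, cluster_id: str = "all") -> PanGenomeSummary:
    """Classify each family by prevalence: core >=0.99, softcore [0.95, 0.99),
    shell [0.15, 0.95), cloud < 0.15.

    With fewer than 20 genomes the 0.95/0.99 cut-points mean "core" is
    exactly "present in every genome", which matches how small phage
    clusters are summarised in practice.
    """
    if len(matrix.index) < 2:
        raise ValueError("need at least 2 genomes")
    n = len(matrix.index)
    prevalence = matrix.sum(axis=0) / n
    core = int((prevalence >= 0.99).sum())
    softcore = int(((prevalence >= 0.95) & (prevalence < 0.99)).sum())
    shell = int(((prevalence >= 0.15) & (prevalence < 0.95)).sum())
    cloud = int(((prevalence > 0) & (prevalence < 0.15)).sum())
    return PanGenomeSummary(cluster_id, n, core, softcore, shell, cloud)
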