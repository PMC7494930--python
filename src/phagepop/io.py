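"""Readers, writers and packaged fixtures.

File formats follow the usual conventions: FASTA wrapped at 80 columns,
GFF3 with 1-based inclusive coordinates, PHYLIP square distance matrices,
and Newick trees (via :class:`skbio.TreeNode`). Two printed tables from the
source study — per-phage characteristics and per-cluster pan-genome counts —
ship as TSV fixtures.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

_DNA_ALPHABET = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format."""


@dataclass
class PhageGenome:
    """One assembled genome: id, uppercase DNA sequence, free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r}: non-ACGTN characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A located CDS feature. Coordinates are 1-based and inclusive."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: str = "hypothetical protein"
    family_id: str | None = None
    module_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )

    def extract(self, genome: PhageGenome) -> str:
        """Strand-correct nucleotide sequence of this gene."""
        if self.end > len(genome):
            raise ValueError(
                f"gene {self.gene_id!r} ends at {self.end} beyond genome "
                f"{genome.id!r} length {len(genome)}"
            )
        sub = genome.sequence[self.start - 1 : self.end]
        return sub if self.strand == "+" else revcomp(sub)


@dataclass
class PhageRecord:
    """One row of the packaged phage-characteristics table."""

    name: str
    region: str
    farm_id: str
    host: str
    genome_size: int
    gc: float
    n_cds: int
    related_ref: str
    family: str
    subfamily: str
    genus: str
    cluster_wgs: str
    cluster_tls: str
    cluster_pp: str
    cluster_exo: str
    suspect_typo: bool = False


@dataclass
class PanGenomeRow:
    """One row of the packaged per-cluster pan-genome table."""

    cluster_id: str
    n_phages: int
    phage_names: str
    lcb_min: int
    lcb_max: int
    n_core: int
    core_pct: int
    n_accessory: int
    accessory_pct: int
    pan: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[PhageGenome]:
    """Read FASTA records into :class:`PhageGenome` objects (uppercased)."""
    path = Path(path)
    genomes: list[PhageGenome] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}:1: expected '>' header, found {first!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genomes.append(PhageGenome(rec.id, str(rec.seq), rec.description))
    return genomes


def write_fasta(genomes: Iterable[PhageGenome], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            header = g.description if g.description.startswith(g.id) else g.id
            fh.write(f">{header}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file.

    ``product``, ``family_id`` and ``module_id`` are taken from column-9
    attributes when present; other feature types are ignored.
    """
    path = Path(path)
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            adict = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    adict[k.strip()] = v.strip()
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            out.append(
                GeneAnnotation(
                    genome_id=seqid,
                    gene_id=adict.get("ID", f"{seqid}_{lineno}"),
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    product=adict.get("product", "hypothetical protein"),
                    family_id=adict.get("family_id"),
                    module_id=adict.get("module_id"),
                )
            )
    return out


def write_gff3(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = [f"ID={a.gene_id}", f"product={a.product}"]
            if a.family_id is not None:
                attrs.append(f"family_id={a.family_id}")
            if a.module_id is not None:
                attrs.append(f"module_id={a.module_id}")
            fh.write(
                "\t".join(
                    [
                        a.genome_id,
                        "phagepop",
                        "CDS",
                        str(a.start),
                        str(a.end),
                        ".",
                        a.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix


def write_phylip_square(matrix: "DistanceMatrix", path: str | Path) -> None:
    from .kmers import DistanceMatrix  # local import to avoid cycle

    assert isinstance(matrix, DistanceMatrix)
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_square(path: str | Path) -> "DistanceMatrix":
    from .kmers import DistanceMatrix

    with open(path) as fh:
        n = int(fh.readline().strip())
        labels: list[str] = []
        rows: list[list[float]] = []
        for _ in range(n):
            parts = fh.readline().split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows, dtype=float)
    # symmetrize round-tripped 6-decimal values exactly
    values = (values + values.T) / 2.0
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: TreeNode, path: str | Path) -> None:
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate leaf labels in newick file")
    return tree


# ---------------------------------------------------------------------------
# Packaged fixtures


def _fixture_path(name: str):
    return resources.files("phagepop.data").joinpath(name)


def load_table1_fixture() -> list[PhageRecord]:
    """The 38 phage records (characteristics table), transcribed verbatim.

    The Phage 55 genome size is stored as printed (1,699,535 bp) with
    ``suspect_typo=True``: the running text gives 173,384 bp as the largest
    genome, so the printed value is almost certainly missing a digit swap.
    """
    with resources.as_file(_fixture_path("table1_phages.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PhageRecord(
                name=row.name,
                region=row.region,
                farm_id=str(row.farm_id),
                host=row.host,
                genome_size=int(row.genome_size),
                gc=float(row.gc),
                n_cds=int(row.n_cds),
                related_ref=row.related_ref,
                family=row.family,
                subfamily=row.subfamily,
                genus=row.genus,
                cluster_wgs=row.cluster_wgs,
                cluster_tls=row.cluster_tls,
                cluster_pp=row.cluster_pp,
                cluster_exo=row.cluster_exo,
                suspect_typo=row.suspect_typo == "1",
            )
        )
    return records


def load_table2_fixture() -> list[PanGenomeRow]:
    """Per-cluster pan-genome counts for the eight (sub)clusters A1–F."""
    with resources.as_file(_fixture_path("table2_pangenome.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            PanGenomeRow(
                cluster_id=r.cluster_id,
                n_phages=int(r.n_phages),
                phage_names=r.phage_names,
                lcb_min=int(r.lcb_min),
                lcb_max=int(r.lcb_max),
                n_core=int(r.n_core),
                core_pct=int(r.core_pct),
                n_accessory=int(r.n_accessory),
                accessory_pct=int(r.accessory_pct),
                pan=int(r.pan),
            )
        )
    return rows
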