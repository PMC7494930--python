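"""ICTV-style genus assignment and population summaries.

The ICTV demarcates a phage genus as a group of viruses with > 50%
nucleotide sequence similarity. Whole-genome similarity is operationalised
here as the Sørensen–Dice coefficient over canonical 21-mer sets — a
standard alignment-free proxy for overall nucleotide similarity. A query
inherits the genus (and family/subfamily) of its most similar reference
when similarity exceeds the threshold, and is flagged as a new-genus
candidate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genecontent import round_half_up
from .io import PhageGenome, PhageRecord
from .kmers import canonical_kmers

NEW_GENUS = "NEW_GENUS_CANDIDATE"


@dataclass
class ReferenceTaxon:
    genome: PhageGenome
    genus: str
    family: str = ""
    subfamily: str = ""


@dataclass
class TaxonCall:
    genome_id: str
    best_reference: str
    similarity: float
    genus: str
    family: str = ""
    subfamily: str = ""


@dataclass
class PopulationSummary:
    n_genomes: int
    family_counts: dict[str, int]
    family_pct: dict[str, int]
    genus_within_family_counts: dict[str, dict[str, int]]
    genus_within_family_pct: dict[str, dict[str, float]]
    genome_size_range: tuple[int, int]
    gc_range: tuple[float, float]
    cds_range: tuple[int, int]
    cluster_tallies: dict[str, dict[str, int]]


def genome_similarity(a: PhageGenome, b: PhageGenome, k: int = 21) -> float:
    """Sørensen–Dice coefficient over canonical k-mer sets: 2|A∩B|/(|A|+|B|)."""
    if len(a) < k or len(b) < k:
        raise ValueError(f"both genomes must be at least {k} bp")
    ka = canonical_kmers(a.sequence, k)
    kb = canonical_kmers(b.sequence, k)
    return 2 * len(ka & kb) / (len(ka) + len(kb))


def assign_genus(
    query: PhageGenome,
    references: list[ReferenceTaxon],
    threshold: float = 0.50,
    k: int = 21,
) -> TaxonCall:
    """Assign the query to its best reference's genus if similarity > threshold.

    Ties on similarity resolve to the lexicographically smallest reference id.
    A threshold of 0 always assigns (the demarcation is strictly-greater,
    so 0 disables it).
    """
    if not references:
        raise ValueError("empty reference set")
    scored = sorted(
        ((genome_similarity(query, r.genome, k), r) for r in references),
        key=lambda t: (-t[0], t[1].genome.id),
    )
    sim, best = scored[0]
    if sim > threshold or threshold <= 0:
        return TaxonCall(
            query.id, best.genome.id, sim, best.genus, best.family, best.subfamily
        )
    return TaxonCall(query.id, best.genome.id, sim, NEW_GENUS)


def gc_content(seq: str) -> float:
    """G+C percentage over A/C/G/T bases (N excluded), to one decimal."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no ACGT bases")
    return round_half_up(100 * (counts["G"] + counts["C"]) / denom, 1)


def collapse_cluster_label(label: str) -> str:
    """A1, A2, A_3 → A: strip trailing digits and underscores."""
    return label.rstrip("0123456789").rstrip("_")


def summarize_population(records: list[PhageRecord]) -> PopulationSummary:
    """Table-1-style summary: family/genus composition, ranges, cluster tallies.

    Family percentages are integers rounded half-up; genus prevalence within
    a family is given to one decimal. Genome-size ranges use only rows not
    flagged as suspect transcription errors.
    """
    if not records:
        raise ValueError("no records")
    n = len(records)
    fam_counts: dict[str, int] = {}
    for r in records:
        fam_counts[r.family] = fam_counts.get(r.family, 0) + 1
    fam_pct = {f: int(round_half_up(100 * c / n)) for f, c in fam_counts.items()}

    genus_counts: dict[str, dict[str, int]] = {}
    for r in records:
        d = genus_counts.setdefault(r.family, {})
        d[r.genus] = d.get(r.genus, 0) + 1
    genus_pct = {
        fam: {
            g: round_half_up(100 * c / fam_counts[fam], 1) for g, c in genera.items()
        }
        for fam, genera in genus_counts.items()
    }

    size_rows = [r for r in records if not r.suspect_typo] or records
    sizes = [r.genome_size for r in size_rows]
    gcs = [r.gc for r in records]
    cds = [r.n_cds for r in records]

    tallies: dict[str, dict[str, int]] = {}
    for col in ("cluster_wgs", "cluster_tls", "cluster_pp", "cluster_exo"):
        t: dict[str, int] = {}
        for r in records:
            top = collapse_cluster_label(getattr(r, col))
            t[top] = t.get(top, 0) + 1
        tallies[col] = t

    return PopulationSummary(
        n_genomes=n,
        family_counts=fam_counts,
        family_pct=fam_pct,
        genus_within_family_counts=genus_counts,
        genus_within_family_pct=genus_pct,
        genome_size_range=(min(sizes), max(sizes)),
        gc_range=(min(gcs), max(gcs)),
        cds_range=(min(cds), max(cds)),
        cluster_tallies=tallies,
    )
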