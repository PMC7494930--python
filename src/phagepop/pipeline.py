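"""End-to-end orchestration of the diversity analysis.

One call runs the full chain on a genome set (real files or a simulated
population): k-mer distance matrices and UPGMA cluster calls, ortholog
families and gene-content clustering, pan-genome partitions per cluster,
marker-gene NJ trees with bootstrap, tree-agreement statistics, gene-order
collinear blocks, genus assignment, and a cluster-concordance (ARI) matrix.
All artifacts are written to an output directory with a manifest of SHA256
checksums, so a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import genecontent, hcluster, io, kmers, markers, simulate, synteny, taxonomy
from .hcluster import ClusterAssignment
from .treecmp import compare_trees


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one run.

    Either ``sim`` (a :class:`~phagepop.simulate.SimConfig`) or both
    ``fasta`` and ``gff3`` paths must be given. Cut heights apply to the
    UPGMA dendrograms of the respective distance type.
    """

    sim: simulate.SimConfig | None = None
    fasta: str | None = None
    gff3: str | None = None
    k_values: tuple[int, ...] = (10, 21)
    kmer_cut: float = 0.82
    gene_cut: float = 0.81
    marker_cut: float = 0.15
    identity_threshold: float = 0.90
    markers: tuple[str, ...] = ("terminase_large", "portal", "exonuclease")
    bootstrap_replicates: int = 1000
    min_block_genes: int = 2
    genus_threshold: float = 0.50
    seed: int = 0
    outdir: str = "phagepop_out"

    def validate(self) -> None:
        if self.sim is None and (self.fasta is None or self.gff3 is None):
            raise ValueError("config needs either sim or fasta+gff3 inputs")
        for name in ("kmer_cut", "gene_cut", "marker_cut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RunReport:
    """Per-stage outputs of one pipeline run."""

    manifest: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    assignments: dict[str, ClusterAssignment] = field(default_factory=dict)
    ari_matrix: pd.DataFrame | None = None
    pan_summaries: dict[str, genecontent.PanGenomeSummary] = field(default_factory=dict)
    taxon_calls: list[taxonomy.TaxonCall] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    truth_ari: dict[str, float] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(report: RunReport, outdir: Path, relpath: str, writer) -> None:
    path = outdir / relpath
    path.parent.mkdir(parents=True, exist_ok=True)
    writer(path)
    report.manifest[relpath] = _sha256(path)


def _assignment_from_markers(
    alignment: markers.Alignment, cut: float
) -> ClusterAssignment:
    """Cluster genomes from a marker alignment: UPGMA on TN93 distances cut
    at ``cut``. Multi-copy leaves (``genome__copyN``) are collapsed to their
    genome id; the genome takes its first copy's cluster."""
    dm = markers.tn93_matrix(alignment, saturation="cap")
    dend = hcluster.upgma(dm)
    assign = hcluster.cut_dendrogram(dend, cut)
    collapsed: dict[str, str] = {}
    for leaf, lab in assign.labels.items():
        gid = leaf.split("__copy")[0]
        if gid not in collapsed or leaf.endswith("__copy1"):
            collapsed[gid] = lab
    return ClusterAssignment(cut, collapsed)


def concordance(assignments: dict[str, ClusterAssignment]) -> pd.DataFrame:
    """Pairwise adjusted Rand index between cluster assignments."""
    names = list(assignments)
    genome_sets = [frozenset(assignments[n].labels) for n in names]
    if len(set(genome_sets)) > 1:
        raise ValueError("assignments cover different genome sets")
    genomes = sorted(genome_sets[0])
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            la = [assignments[a].labels[g] for g in genomes]
            lb = [assignments[b].labels[g] for g in genomes]
            ari = adjusted_rand_score(la, lb)
            mat.iloc[i, j] = mat.iloc[j, i] = ari
    return mat


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    # --- stage: inputs ------------------------------------------------------
    truth = None
    if config.sim is not None:
        genomes, annotations, truth = simulate.generate_population(config.sim)
        _write(report, outdir, "genomes.fasta", lambda p: io.write_fasta(genomes, p))
        _write(report, outdir, "genes.gff3", lambda p: io.write_gff3(annotations, p))
        _write(
            report,
            outdir,
            "truth.tsv",
            lambda p: pd.DataFrame(
                sorted(truth.cluster_of.items()), columns=["genome_id", "true_cluster"]
            ).to_csv(p, sep="\t", index=False),
        )
    else:
        genomes = io.read_fasta(config.fasta)
        annotations = io.read_gff3(config.gff3)
    genome_ids = [g.id for g in genomes]

    # --- stage: k-mer distances + clusters ----------------------------------
    for k in config.k_values:
        dm = kmers.kmer_distance_matrix(genomes, k)
        _write(report, outdir, f"dist_k{k}.phylip", lambda p: io.write_phylip_square(dm, p))
        dend = hcluster.upgma(dm)
        assign = hcluster.cut_dendrogram(dend, config.kmer_cut)
        report.assignments[f"kmer_k{k}"] = assign
        _write(
            report,
            outdir,
            f"clusters_k{k}.tsv",
            lambda p: pd.DataFrame(
                sorted(assign.labels.items()), columns=["genome_id", "cluster"]
            ).to_csv(p, sep="\t", index=False),
        )
        _write(
            report,
            outdir,
            f"upgma_k{k}.nwk",
            lambda p: io.write_newick(hcluster.dendrogram_to_tree(dend), p),
        )

    # --- stage: gene content -------------------------------------------------
    gene_seqs = genecontent.extract_gene_sequences(genomes, annotations)
    triples = [(a.genome_id, a.gene_id, gene_seqs[a.gene_id]) for a in annotations]
    families = genecontent.cluster_gene_families(triples, config.identity_threshold)
    pa = genecontent.presence_absence_matrix(families, genome_ids)
    _write(report, outdir, "presence_absence.tsv", lambda p: pa.to_csv(p, sep="\t"))
    gene_dm = genecontent.gene_content_distance(pa)
    gene_dend = hcluster.upgma(gene_dm)
    gene_assign = hcluster.cut_dendrogram(gene_dend, config.gene_cut)
    report.assignments["gene_content"] = gene_assign

    # annotate families back onto genes for the synteny stage
    fam_of_gene = {
        gene_id: fam.family_id for fam in families for (_g, gene_id) in fam.members
    }
    annotated = [
        simulate.replace_annotation(a, family_id=fam_of_gene[a.gene_id])
        for a in annotations
    ]

    # --- stage: pan genome per cluster ---------------------------------------
    for lab, members in sorted(gene_assign.as_sets().items()):
        if len(members) < 2:
            report.skipped.append(f"pan_genome:{lab} (singleton cluster)")
            continue
        sub = pa.loc[sorted(members)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        report.pan_summaries[lab] = genecontent.partition_pan_genome(sub, lab)
    if report.pan_summaries:
        _write(
            report,
            outdir,
            "pan_genome.tsv",
            lambda p: pd.DataFrame(
                [
                    {
                        "cluster": s.cluster_id,
                        "n_genomes": s.n_genomes,
                        "core": s.core,
                        "softcore": s.softcore,
                        "shell": s.shell,
                        "cloud": s.cloud,
                        "pan": s.pan,
                        "core_pct": s.core_pct,
                        "accessory_pct": s.accessory_pct,
                    }
                    for s in report.pan_summaries.values()
                ]
            ).to_csv(p, sep="\t", index=False),
        )

    # --- stage: marker trees --------------------------------------------------
    marker_trees: dict[str, object] = {}
    for marker in config.markers:
        seqs = markers.extract_marker_sequences(genomes, annotations, marker)
        if len(seqs) < 3:
            report.skipped.append(f"marker:{marker} (<3 sequences)")
            continue
        aln = markers.progressive_align(seqs)
        tree = markers.bootstrap_support(
            aln, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
        marker_trees[marker] = tree
        _write(report, outdir, f"marker_{marker}.nwk", lambda p: io.write_newick(tree, p))
        report.assignments[f"marker_{marker}"] = _assignment_from_markers(
            aln, config.marker_cut
        )

    # --- stage: tree agreement -------------------------------------------------
    names = sorted(marker_trees)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ta, tb = marker_trees[a], marker_trees[b]
            tips_a = {t.name for t in ta.tips()}
            tips_b = {t.name for t in tb.tips()}
            common = tips_a & tips_b
            if common != tips_a or common != tips_b:
                report.skipped.append(f"tree_compare:{a}-vs-{b} (leaf sets differ)")
                continue
            cmp_ = compare_trees(ta, tb)
            rows.append(
                {
                    "tree_a": a,
                    "tree_b": b,
                    "rf": cmp_.rf,
                    "rf_max": cmp_.rf_max,
                    "normalized_rf": cmp_.normalized_rf,
                    "branch_score": cmp_.branch_score,
                }
            )
    if rows:
        _write(
            report,
            outdir,
            "tree_agreement.tsv",
            lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False),
        )

    # --- stage: synteny ---------------------------------------------------------
    blocks = synteny.find_lcbs(annotated, config.min_block_genes)
    census = synteny.lcb_census(blocks, genome_ids)
    _write(report, outdir, "lcb_census.tsv", lambda p: census.to_csv(p, sep="\t"))

    # --- stage: taxonomy ---------------------------------------------------------
    # references: one exemplar per k-mer cluster (first genome by id)
    ref_assign = report.assignments.get(f"kmer_k{config.k_values[0]}")
    if ref_assign is not None:
        refs = []
        by_id = {g.id: g for g in genomes}
        for lab, members in sorted(ref_assign.as_sets().items()):
            exemplar = sorted(members)[0]
            refs.append(taxonomy.ReferenceTaxon(by_id[exemplar], genus=f"genus_{lab}"))
        for g in genomes:
            report.taxon_calls.append(
                taxonomy.assign_genus(g, refs, config.genus_threshold)
            )
        _write(
            report,
            outdir,
            "taxon_calls.tsv",
            lambda p: pd.DataFrame(
                [
                    {
                        "genome_id": c.genome_id,
                        "best_reference": c.best_reference,
                        "similarity": round(c.similarity, 6),
                        "genus": c.genus,
                    }
                    for c in report.taxon_calls
                ]
            ).to_csv(p, sep="\t", index=False),
        )

    # --- stage: concordance -------------------------------------------------------
    if len(report.assignments) >= 2:
        report.ari_matrix = concordance(report.assignments)
        _write(
            report,
            outdir,
            "concordance_ari.tsv",
            lambda p: report.ari_matrix.to_csv(p, sep="\t"),
        )
    if truth is not None:
        for name, assign in report.assignments.items():
            genomes_sorted = sorted(truth.cluster_of)
            report.truth_ari[name] = adjusted_rand_score(
                [truth.cluster_of[g] for g in genomes_sorted],
                [assign.labels[g] for g in genomes_sorted],
            )

    _write(
        report,
        outdir,
        "manifest.json",
        lambda p: p.write_text(
            json.dumps(dict(sorted(report.manifest.items())), indent=2) + "\n"
        ),
    )
    return report
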