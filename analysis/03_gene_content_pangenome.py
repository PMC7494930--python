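"""Ortholog families, gene-content clustering and per-cluster pan genomes.

Clusters all genes at 90% global nucleotide identity, builds the gene
presence/absence matrix, clusters genomes by Jaccard distance over family
sets (UPGMA, cut 0.81), and partitions each cluster's pan genome into
core/softcore/shell/cloud.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from phagepop import genecontent, hcluster
from phagepop.io import read_fasta, read_gff3

BASE = Path(__file__).resolve().parent.parent / "results"
CUT = 0.81


def main() -> None:
    genomes = read_fasta(BASE / "population" / "genomes.fasta")
    annotations = read_gff3(BASE / "population" / "genes.gff3")
    truth = pd.read_csv(BASE / "population" / "truth.tsv", sep="\t").set_index(
        "genome_id"
    )["true_cluster"]

    seqs = genecontent.extract_gene_sequences(genomes, annotations)
    fams = genecontent.cluster_gene_families(
        [(a.genome_id, a.gene_id, seqs[a.gene_id]) for a in annotations]
    )
    print(f"{len(fams)} gene families from {len(annotations)} genes")

    pa = genecontent.presence_absence_matrix(fams, [g.id for g in genomes])
    pa.to_csv(BASE / "presence_absence.tsv", sep="\t")

    assign = hcluster.cut_dendrogram(
        hcluster.upgma(genecontent.gene_content_distance(pa)), CUT
    )
    ari = adjusted_rand_score(
        [truth[g] for g in sorted(truth.index)],
        [assign.labels[g] for g in sorted(truth.index)],
    )
    print(f"gene-content clustering at cut {CUT}: ARI vs truth = {ari:.3f}")

    rows = []
    for lab, members in sorted(assign.as_sets().items()):
        if len(members) < 2:
            continue
        sub = pa.loc[sorted(members)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        s = genecontent.partition_pan_genome(sub, lab)
        rows.append(
            {
                "cluster": lab,
                "n_genomes": s.n_genomes,
                "core": s.core,
                "softcore": s.softcore,
                "shell": s.shell,
                "cloud": s.cloud,
                "pan": s.pan,
                "core_pct": s.core_pct,
                "accessory_pct": s.accessory_pct,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(BASE / "pan_genome.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
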