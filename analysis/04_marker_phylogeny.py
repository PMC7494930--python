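"""Marker-gene phylogenies and their agreement.

Builds NJ trees (TN93 distances, 100 bootstrap replicates) for the
terminase large subunit, portal protein and exonuclease markers, writes
them as Newick, and quantifies pairwise topological/branch-length
agreement (Robinson-Foulds distance and branch score) where leaf sets
coincide.
"""

from pathlib import Path

import pandas as pd

from phagepop import markers
from phagepop.io import read_fasta, read_gff3, write_newick
from phagepop.treecmp import compare_trees

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1
MARKERS = ("terminase_large", "portal", "exonuclease")


def main() -> None:
    genomes = read_fasta(BASE / "population" / "genomes.fasta")
    annotations = read_gff3(BASE / "population" / "genes.gff3")

    trees = {}
    for marker in MARKERS:
        seqs = markers.extract_marker_sequences(genomes, annotations, marker)
        aln = markers.progressive_align(seqs)
        tree = markers.bootstrap_support(aln, n_replicates=100, seed=SEED)
        write_newick(tree, BASE / f"marker_{marker}.nwk")
        supports = [
            int(n.name)
            for n in tree.non_tips(include_self=False)
            if n.name is not None
        ]
        print(
            f"{marker}: {len(seqs)} leaves, alignment {aln.length} columns, "
            f"median support {sorted(supports)[len(supports) // 2]}"
        )
        trees[marker] = tree

    rows = []
    names = sorted(trees)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            tips_a = {t.name for t in trees[a].tips()}
            tips_b = {t.name for t in trees[b].tips()}
            if tips_a != tips_b:
                print(f"{a} vs {b}: leaf sets differ (multi-copy marker); skipped")
                continue
            c = compare_trees(trees[a], trees[b])
            rows.append(
                {"tree_a": a, "tree_b": b, "rf": c.rf, "rf_max": c.rf_max,
                 "normalized_rf": round(c.normalized_rf, 4),
                 "branch_score": round(c.branch_score, 6)}
            )
            print(
                f"{a} vs {b}: RF {c.rf}/{c.rf_max}, branch score {c.branch_score:.4f}"
            )
    if rows:
        pd.DataFrame(rows).to_csv(BASE / "tree_agreement.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
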