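import numpy as np
import pandas as pd
import pytest

from phagepop.genecontent import (
    cluster_gene_families,
    extract_gene_sequences,
    gene_content_distance,
    global_identity,
    partition_pan_genome,
    presence_absence_matrix,
    round_half_up,
)
from phagepop.kmers import jaccard_distance
from phagepop.simulate import apply_rearrangement, mutate_sequence


def make_diverged(seq: str, n_diffs: int, rng) -> str:
    """Substitute exactly n_diffs positions (guaranteed different base)."""
    pos = rng.choice(len(seq), size=n_diffs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_exact_hamming_construction(self):
        # 100 sites, exactly 10 substitutions, no indels: the gapless
        # alignment is optimal and identity is exactly 0.90
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = make_diverged(a, 10, rng)
        assert global_identity(a, b) == pytest.approx(0.90)

    def test_single_deletion(self):
        assert global_identity("ACGTACGT", "ACGACGT") == pytest.approx(7 / 8)


class TestClusterGeneFamilies:
    def test_all_identical_genes_one_family(self):
        seq = "ATG" + "ACGTTC" * 60 + "TAA"
        genes = [(f"g{i}", f"g{i}_x", seq) for i in range(4)]
        fams = cluster_gene_families(genes)
        assert len(fams) == 1
        assert len(fams[0].members) == 4

    def test_eighty_percent_identity_splits_at_ninety_threshold(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=600))
        b = make_diverged(a, 120, rng)  # 80% positional identity
        # the score-optimal alignment may squeeze out slightly more identity
        # via gaps, but stays far below the clustering threshold
        assert 0.79 <= global_identity(a, b) <= 0.84
        fams = cluster_gene_families([("g1", "x", a), ("g2", "y", b)], 0.90)
        assert len(fams) == 2

    def test_ninety_five_percent_identity_merges(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=600))
        b = make_diverged(a, 30, rng)
        fams = cluster_gene_families([("g1", "x", a), ("g2", "y", b)], 0.90)
        assert len(fams) == 1

    def test_zero_divergence_population_recovers_truth_families(
        self, clean_pair_population
    ):
        _cfg, (genomes, annotations, truth) = clean_pair_population
        seqs = extract_gene_sequences(genomes, annotations)
        triples = [(a.genome_id, a.gene_id, seqs[a.gene_id]) for a in annotations]
        fams = cluster_gene_families(triples)
        # observed partition of gene ids == truth partition
        observed = {
            frozenset(gene_id for _g, gene_id in f.members) for f in fams
        }
        by_truth: dict[str, set[str]] = {}
        for gene_id, fam in truth.family_of.items():
            by_truth.setdefault(fam, set()).add(gene_id)
        assert observed == {frozenset(v) for v in by_truth.values()}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_gene_families([])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=450))
        genes = [
            (f"g{i}", f"g{i}_x", mutate_sequence(base, rate, seed=i))
            for i, rate in enumerate([0.0, 0.03, 0.06, 0.12, 0.25])
        ]
        counts = [
            len(cluster_gene_families(genes, t)) for t in (0.70, 0.80, 0.90, 0.99)
        ]
        assert counts == sorted(counts)


class TestPresenceAbsence:
    def test_single_genome_all_ones(self):
        seq1 = "ATG" + "AACCGGTT" * 40
        seq2 = "ATG" + "TTGGCCAA" * 45
        fams = cluster_gene_families([("g1", "a", seq1), ("g1", "b", seq2)])
        mat = presence_absence_matrix(fams, ["g1"])
        assert mat.values.sum() == len(fams)

    def test_paralogs_collapse_to_one(self):
        seq = "ATG" + "AACCGGTT" * 40
        fams = cluster_gene_families([("g1", "a", seq), ("g1", "b", seq)])
        assert len(fams) == 1
        mat = presence_absence_matrix(fams, ["g1"])
        assert mat.values.tolist() == [[1]]

    def test_module_loss_zeroes_exactly_those_families(self, clean_pair_population):
        _cfg, (genomes, annotations, truth) = clean_pair_population
        g = genomes[0]
        coords = truth.module_coords[g.id]
        lost_mod = next(m for m, *_ in coords if m.startswith("v"))
        anns_g = [a for a in annotations if a.genome_id == g.id]
        g_lost, anns_lost, _c, _ = apply_rearrangement(
            g, anns_g, coords, "loss", lost_mod
        )
        other = [a for a in annotations if a.genome_id != g.id]
        all_anns = other + anns_lost
        all_genomes = [g_lost] + [x for x in genomes if x.id != g.id]
        seqs = extract_gene_sequences(all_genomes, all_anns)
        fams = cluster_gene_families(
            [(a.genome_id, a.gene_id, seqs[a.gene_id]) for a in all_anns]
        )
        mat = presence_absence_matrix(fams, [x.id for x in all_genomes])
        lost_fams = {
            a.family_id for a in annotations
            if a.genome_id == g.id and a.module_id == lost_mod
        }
        fam_map = {
            f.family_id: {a.family_id for _g, gid in f.members
                          for a in all_anns if a.gene_id == gid}
            for f in fams
        }
        for fid, truth_fams in fam_map.items():
            if truth_fams & lost_fams:
                assert mat.loc[g.id, fid] == 0
            else:
                assert mat.loc[g.id, fid] == 1


class TestGeneContentDistance:
    def test_nested_sets(self):
        mat = pd.DataFrame(
            [[1, 1], [1, 0]], index=["g1", "g2"], columns=["f1", "f2"]
        )
        dm = gene_content_distance(mat)
        assert dm[("g1", "g2")] == pytest.approx(0.5)

    def test_matrix_equals_brute_force(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(5, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"f{j}" for j in range(12)],
        )
        mat.iloc[:, 0] = 1  # no empty genomes
        dm = gene_content_distance(mat)
        for i in range(5):
            for j in range(i + 1, 5):
                a = set(mat.columns[mat.iloc[i] == 1])
                b = set(mat.columns[mat.iloc[j] == 1])
                assert dm.values[i, j] == pytest.approx(jaccard_distance(a, b))

    def test_empty_genome_rejected(self):
        mat = pd.DataFrame([[1, 1], [0, 0]], index=["g1", "g2"], columns=["f1", "f2"])
        with pytest.raises(ValueError, match="g2"):
            gene_content_distance(mat)


class TestPanGenomePartition:
    def test_every_family_everywhere_is_all_core(self):
        mat = pd.DataFrame(1, index=["g1", "g2", "g3"], columns=["f1", "f2"])
        s = partition_pan_genome(mat)
        assert s.core == 2 and s.pan == 2
        assert s.core_pct == 100 and s.accessory_pct == 0

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_g = int(rng.integers(2, 25))
            n_f = int(rng.integers(1, 40))
            mat = pd.DataFrame(
                rng.integers(0, 2, size=(n_g, n_f)),
                index=[f"g{i}" for i in range(n_g)],
                columns=[f"f{j}" for j in range(n_f)],
            )
            s = partition_pan_genome(mat)
            n_present = int((mat.sum(axis=0) > 0).sum())
            assert s.core + s.softcore + s.shell + s.cloud == n_present == s.pan

    def test_small_n_core_means_present_in_all(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 1, 1], [1, 0, 1]],
            index=["g1", "g2", "g3"],
            columns=["f1", "f2", "f3"],
        )
        s = partition_pan_genome(mat)
        assert s.core == 1  # only f1 in all three
        assert s.softcore == 0
        assert s.shell == 2

    def test_rounding_is_half_up(self):
        assert round_half_up(38.5) == 39
        assert round_half_up(72.94117647058823) == 73
        assert round_half_up(45.45454545, 1) == 45.5
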