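import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from phagepop.hcluster import upgma
from phagepop.kmers import DistanceMatrix
from phagepop.markers import (
    Alignment,
    SaturationError,
    bipartitions,
    bootstrap_support,
    extract_marker_sequences,
    nj_tree,
    p_distance,
    progressive_align,
    tn93_distance,
    tn93_matrix,
)
from phagepop.treecmp import rf_distance


def random_seqs(rng, n, length):
    return [
        (f"s{i}", "".join(rng.choice(list("ACGT"), size=length))) for i in range(n)
    ]


class TestProgressiveAlign:
    def test_identical_sequences_have_no_gap_columns(self):
        seq = "ACGTACGTACGTGGCC"
        aln = progressive_align([("a", seq), ("b", seq), ("c", seq)])
        assert all(row == seq for row in aln.rows)

    def test_single_deletion_yields_one_gap(self):
        aln = progressive_align([("a", "ACGTACGT"), ("b", "ACGACGT")])
        assert aln.length == 8
        gap_count = sum(row.count("-") for row in aln.rows)
        assert gap_count == 1

    def test_degapping_returns_inputs(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=120))
        seqs = []
        for i in range(5):
            s = list(base)
            # random codon deletions
            for _ in range(rng.integers(0, 3)):
                p = int(rng.integers(0, len(s) // 3)) * 3
                del s[p : p + 3]
            seqs.append((f"s{i}", "".join(s)))
        aln = progressive_align(seqs)
        for i, (sid, s) in enumerate(seqs):
            assert aln.ids[i] == sid
            assert aln.degapped(i) == s

    def test_alignment_length_at_least_longest_input(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            seqs = [
                (f"s{i}", "".join(rng.choice(list("ACGT"), size=rng.integers(30, 60))))
                for i in range(4)
            ]
            aln = progressive_align(seqs)
            assert aln.length >= max(len(s) for _i, s in seqs)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([("a", "ACGT")])


class TestTN93:
    def test_identical_rows_zero(self):
        est = tn93_distance("ACGTACGT", "ACGTACGT")
        assert est.d == 0.0
        assert est.P1 == est.P2 == est.Q == 0.0

    def test_reduces_to_k2p_under_equal_frequencies(self):
        # 20 columns, balanced bases, no transitions, Q = 0.2
        a = "ACGT" * 5
        b = "ACGT" * 4 + "CAGT"  # A<->C and C<->A at cols 16,17: transversions
        est = tn93_distance(a, b)
        assert est.Q == pytest.approx(0.1)
        P, Q = 0.0, est.Q
        k2p = -0.5 * np.log((1 - 2 * P - Q) * np.sqrt(1 - 2 * Q))
        assert est.d == pytest.approx(k2p, rel=1e-9)

    def test_matches_simulated_divergence(self):
        # independent JC substitution process at t = 0.1 subs/site
        rng = np.random.default_rng(2)
        L = 100_000
        t = 0.1
        p_change = 0.75 * (1 - np.exp(-4 * t / 3))
        bases = list("ACGT")
        a = rng.choice(4, size=L)
        flip = rng.random(L) < p_change
        shift = rng.integers(1, 4, size=L)
        b = np.where(flip, (a + shift) % 4, a)
        row_a = "".join(bases[i] for i in a)
        row_b = "".join(bases[i] for i in b)
        est = tn93_distance(row_a, row_b)
        assert abs(est.d - t) <= 0.01

    def test_distance_at_least_p_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            L = 200
            a = "".join(rng.choice(list("ACGT"), size=L))
            b = "".join(
                c if rng.random() > 0.2 else rng.choice(list("ACGT")) for c in a
            )
            try:
                est = tn93_distance(a, b)
            except SaturationError:
                continue
            assert est.d >= p_distance(a, b) - 1e-12

    def test_gap_columns_excluded(self):
        est = tn93_distance("ACGT--AC", "ACGTGGAC")
        assert est.d == 0.0

    def test_saturation_raises_not_nan(self):
        a = "AG" * 50
        b = "GA" * 50  # every site a purine transition
        with pytest.raises(SaturationError):
            tn93_distance(a, b)


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_equations(self):
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        lens = {t.name: t.length for t in tree.tips()}
        assert lens["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lens["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lens["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_recovers_random_additive_trees_exactly(self, n):
        rng = np.random.default_rng(n)
        for _rep in range(3):
            matrix, source = _random_additive_matrix(rng, n)
            inferred = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], matrix))
            assert rf_distance(inferred, source) == 0
            # path distances reproduced
            tips = {t.name: t for t in inferred.tips()}
            for i in range(n):
                for j in range(i + 1, n):
                    got = tips[f"t{i}"].distance(tips[f"t{j}"])
                    assert got == pytest.approx(matrix[i, j])

    def test_topology_matches_skbio_nj(self):
        rng = np.random.default_rng(9)
        m, _src = _random_additive_matrix(rng, 7)
        labels = [f"t{i}" for i in range(7)]
        ours = nj_tree(DistanceMatrix(labels, m))
        theirs = skbio_nj(SkbioDM(m, ids=labels))
        assert rf_distance(ours, theirs) == 0

    def test_ultrametric_input_matches_upgma_topology(self):
        rng = np.random.default_rng(10)
        raw = rng.uniform(0.1, 1.0, (6, 6))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0)
        labels = [f"t{i}" for i in range(6)]
        dend = upgma(DistanceMatrix(labels, raw))
        coph = dend.cophenetic_matrix()  # ultrametric by construction
        from phagepop.hcluster import dendrogram_to_tree

        nj_topo = nj_tree(coph)
        upgma_topo = dendrogram_to_tree(dend)
        assert rf_distance(nj_topo, upgma_topo) == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


def _random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths; returns its leaf
    path-distance matrix and the tree itself."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 0.5))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.05, 0.5))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    tips = list(root.tips())
    m = np.zeros((n, n))
    by_name = {t.name: t for t in tips}
    for i in range(n):
        for j in range(i + 1, n):
            d = by_name[f"t{i}"].distance(by_name[f"t{j}"])
            m[i, j] = m[j, i] = d
    return m, root


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(11)
        seqs = random_seqs(rng, 5, 60)
        aln = progressive_align(seqs)
        tree = bootstrap_support(aln, n_replicates=1, seed=1)
        supports = [
            int(node.name)
            for node in tree.non_tips(include_self=False)
            if node.name is not None
        ]
        assert supports and all(s in (0, 100) for s in supports)

    def test_same_seed_gives_identical_supports(self):
        rng = np.random.default_rng(12)
        seqs = random_seqs(rng, 5, 80)
        aln = progressive_align(seqs)
        t1 = bootstrap_support(aln, n_replicates=20, seed=5)
        t2 = bootstrap_support(aln, n_replicates=20, seed=5)
        assert str(t1) == str(t2)

    def test_separated_clusters_get_high_support(self, small_population):
        _cfg, (genomes, annotations, truth) = small_population
        seqs = extract_marker_sequences(genomes, annotations, "terminase_large")
        aln = progressive_align(seqs)
        tree = bootstrap_support(aln, n_replicates=100, seed=3)
        clusters = {}
        for gid, c in truth.cluster_of.items():
            clusters.setdefault(c, set()).add(gid)
        leaves = sorted(t.name for t in tree.tips())
        ref = leaves[0]
        all_set = frozenset(leaves)
        cluster_sides = set()
        for mem in clusters.values():
            side = frozenset(mem)
            if ref in side:
                side = all_set - side
            if 2 <= len(side) <= len(leaves) - 2:
                cluster_sides.add(side)
        found = 0
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_set - side
            if side in cluster_sides:
                found += 1
                assert int(node.name) >= 95
        assert found == len(cluster_sides)

    def test_multicopy_markers_get_copy_labels(self, small_population):
        _cfg, (genomes, annotations, truth) = small_population
        seqs = extract_marker_sequences(genomes, annotations, "exonuclease")
        n_exo = sum(1 for a in annotations if a.product == "exonuclease")
        assert len(seqs) == n_exo
        multi = [s for s, _ in seqs if "__copy" in s]
        per_genome = {}
        for a in annotations:
            if a.product == "exonuclease":
                per_genome[a.genome_id] = per_genome.get(a.genome_id, 0) + 1
        if any(v > 1 for v in per_genome.values()):
            assert multi

    def test_invalid_replicate_count_rejected(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=0, seed=1)
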