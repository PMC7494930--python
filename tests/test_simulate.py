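import numpy as np
import pytest

from phagepop.io import revcomp
from phagepop.kmers import kmer_distance_matrix
from phagepop.simulate import (
    ConfigError,
    PACKAGING_PRODUCTS,
    SimConfig,
    apply_rearrangement,
    gc_fraction,
    generate_population,
    mutate_sequence,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"within_cluster_sub_rate": -0.1}, "within_cluster_sub_rate"),
            ({"hgt_swap_prob": 1.5}, "hgt_swap_prob"),
            ({"genome_length_range": (1000, 50000)}, "genome_length_range"),
            ({"genome_length_range": (50000, 300000)}, "genome_length_range"),
            (
                {"within_cluster_sub_rate": 0.2, "between_cluster_sub_rate": 0.1},
                "between_cluster_sub_rate",
            ),
            ({"n_clusters": 0}, "n_clusters"),
        ],
    )
    def test_invalid_config_names_offending_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs).validate()


class TestMutateSequence:
    def test_rate_zero_is_identity(self):
        seq = "ACGTACGTAC" * 50
        assert mutate_sequence(seq, 0.0, seed=1) == seq

    def test_rate_one_changes_every_site(self):
        seq = "A" * 500
        out = mutate_sequence(seq, 1.0, seed=2)
        assert all(b != "A" for b in out)
        assert len(out) == 500

    def test_observed_fraction_near_rate(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        out = mutate_sequence(seq, 0.1, seed=4)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert abs(frac - 0.1) <= 0.01

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="ACGT"):
            mutate_sequence("ACGN", 0.1, seed=5)


class TestGeneratePopulation:
    def test_zero_within_divergence_gives_identical_genomes(self, clean_pair_population):
        _cfg, (genomes, _ann, _truth) = clean_pair_population
        assert genomes[0].sequence == genomes[1].sequence
        dm = kmer_distance_matrix(genomes, 21)
        assert dm.values[0, 1] == 0.0

    def test_seed_determinism_is_byte_identical(self):
        cfg = SimConfig(
            n_clusters=2,
            genomes_per_cluster=2,
            genome_length_range=(25_000, 35_000),
            n_variable_modules=3,
            seed=9,
        )
        g1, a1, t1 = generate_population(cfg)
        g2, a2, t2 = generate_population(cfg)
        assert [g.sequence for g in g1] == [g.sequence for g in g2]
        assert a1 == a2
        assert t1.cluster_of == t2.cluster_of
        assert t1.family_of == t2.family_of

    def test_lengths_and_gc_within_configured_ranges(self, small_population):
        cfg, (genomes, _ann, truth) = small_population
        lo, hi = cfg.genome_length_range
        for g in genomes:
            assert lo <= len(g) <= hi
            target = truth.gc_targets[truth.cluster_of[g.id]]
            assert abs(gc_fraction(g.sequence) - target) <= 0.02

    def test_packaging_module_order_conserved_in_every_genome(self, small_population):
        _cfg, (genomes, annotations, _truth) = small_population
        for g in genomes:
            anns = sorted(
                (a for a in annotations if a.genome_id == g.id), key=lambda a: a.start
            )
            products = [a.product for a in anns if a.product in PACKAGING_PRODUCTS]
            assert tuple(products) == PACKAGING_PRODUCTS

    def test_each_genome_has_one_to_three_exonucleases(self, small_population):
        _cfg, (genomes, annotations, _truth) = small_population
        for g in genomes:
            n = sum(
                1
                for a in annotations
                if a.genome_id == g.id and a.product == "exonuclease"
            )
            assert 1 <= n <= 3

    def test_conservation_within_cluster(self, small_population):
        _cfg, (_genomes, annotations, truth) = small_population
        by_cluster = {}
        for gid, cl in truth.cluster_of.items():
            order = [m for m, _o in truth.module_order[gid]]
            fams = sorted(
                a.family_id for a in annotations if a.genome_id == gid
            )
            by_cluster.setdefault(cl, []).append((order, fams))
        for entries in by_cluster.values():
            assert all(e == entries[0] for e in entries)

    def test_every_gene_has_exactly_one_true_family(self, small_population):
        _cfg, (_genomes, annotations, truth) = small_population
        for a in annotations:
            assert truth.family_of[a.gene_id] == a.family_id

    def test_between_cluster_distances_exceed_within(self, small_population):
        _cfg, (genomes, _ann, truth) = small_population
        dm = kmer_distance_matrix(genomes, 21)
        ids = dm.labels
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                same = truth.cluster_of[ids[i]] == truth.cluster_of[ids[j]]
                (within if same else between).append(dm.values[i, j])
        assert min(between) > max(within)


class TestApplyRearrangement:
    @pytest.fixture()
    def one_genome(self, clean_pair_population):
        _cfg, (genomes, annotations, truth) = clean_pair_population
        g = genomes[0]
        anns = [a for a in annotations if a.genome_id == g.id]
        return g, anns, truth.module_coords[g.id]

    def test_inversion_is_an_involution(self, one_genome):
        g, anns, coords = one_genome
        mod = coords[2][0]
        g1, a1, c1, _ = apply_rearrangement(g, anns, coords, "inversion", mod)
        assert g1.sequence != g.sequence
        g2, a2, _c2, _ = apply_rearrangement(g1, a1, c1, "inversion", mod)
        assert g2.sequence == g.sequence
        key = lambda anns_: sorted((a.gene_id, a.start, a.end, a.strand) for a in anns_)
        assert key(a2) == key(anns)

    def test_inverted_slice_is_reverse_complement(self, one_genome):
        g, anns, coords = one_genome
        mod, start, end, _o = coords[3]
        g1, _a1, _c1, _ = apply_rearrangement(g, anns, coords, "inversion", mod)
        assert g1.sequence[start - 1 : end] == revcomp(g.sequence[start - 1 : end])
        assert g1.sequence[: start - 1] == g.sequence[: start - 1]
        assert g1.sequence[end:] == g.sequence[end:]

    def test_loss_removes_exactly_that_modules_genes(self, one_genome):
        g, anns, coords = one_genome
        mod = coords[1][0]
        mod_genes = [a for a in anns if a.module_id == mod]
        g1, a1, _c1, _rec = apply_rearrangement(g, anns, coords, "loss", mod)
        assert len(a1) == len(anns) - len(mod_genes)
        assert all(a.module_id != mod for a in a1)
        span = coords[1][2] - coords[1][1] + 1
        assert len(g1) == len(g) - span

    def test_repeat_duplicates_module_in_tandem(self, one_genome):
        g, anns, coords = one_genome
        mod, start, end, _o = coords[2]
        span = end - start + 1
        g1, a1, c1, _ = apply_rearrangement(g, anns, coords, "repeat", mod)
        assert len(g1) == len(g) + span
        assert g1.sequence[start - 1 : end + span] == g.sequence[start - 1 : end] * 2
        assert sum(1 for m in c1 if m[0] == mod) == 2

    def test_unknown_module_rejected(self, one_genome):
        g, anns, coords = one_genome
        with pytest.raises(ValueError, match="no_such"):
            apply_rearrangement(g, anns, coords, "inversion", "no_such_module")

    def test_hgt_swap_transfers_donor_families(self):
        cfg = SimConfig(
            n_clusters=2,
            genomes_per_cluster=1,
            genome_length_range=(25_000, 35_000),
            n_variable_modules=3,
            within_cluster_sub_rate=0.0,
            between_cluster_sub_rate=0.2,
            seed=21,
        )
        genomes, annotations, truth = generate_population(cfg)
        recipient, donor = genomes
        r_anns = [a for a in annotations if a.genome_id == recipient.id]
        d_anns = [a for a in annotations if a.genome_id == donor.id]
        var_mod = next(m for m, *_ in truth.module_coords[recipient.id] if m.startswith("v"))
        _m, ds, de, _o = next(
            m for m in truth.module_coords[donor.id] if m[0] == var_mod
        )
        donor_slice = donor.sequence[ds - 1 : de]
        donor_genes = [
            a
            for a in d_anns
            if ds <= a.start and a.end <= de
        ]
        rel = [
            type(a)(
                genome_id=a.genome_id,
                gene_id=a.gene_id,
                start=a.start - ds + 1,
                end=a.end - ds + 1,
                strand=a.strand,
                product=a.product,
                family_id=a.family_id,
                module_id=a.module_id,
            )
            for a in donor_genes
        ]
        g1, a1, _c1, _ = apply_rearrangement(
            recipient, r_anns, truth.module_coords[recipient.id],
            "hgt_swap", var_mod, donor=(donor_slice, rel),
        )
        swapped = [a for a in a1 if a.module_id == var_mod]
        donor_fams = {a.family_id for a in donor_genes}
        assert {a.family_id for a in swapped} == donor_fams
        assert all(f"fam_C1_{var_mod}" in f for f in donor_fams)
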