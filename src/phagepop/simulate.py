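"""Synthetic mosaic phage populations with known truth.

The generator emulates the genome architecture the downstream analysis
assumes: populations of linear dsDNA phage genomes (tens to ~175 kb,
G+C roughly 35–47%) organised into clusters. Genomes within a cluster
descend from a cluster ancestor; cluster ancestors share conserved gene
modules derived from a common ancestor (a DNA-packaging module with the
fixed order terminase small subunit → terminase large subunit → portal
protein → capsid → scaffold, an exonuclease module with 1–3 copies, and
generic conserved modules) interleaved with cluster-specific variable
modules — the classic mosaic structure. Optional per-genome events
(module swap between clusters, inversion, loss, tandem repeat) create the
rearrangements the synteny stage detects.

Every piece of randomness flows from one :class:`numpy.random.Generator`
seeded by ``SimConfig.seed``, in a fixed call order, so identical configs
give byte-identical populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import GeneAnnotation, PhageGenome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

PACKAGING_PRODUCTS = (
    "terminase small subunit",
    "terminase large subunit",
    "portal protein",
    "major capsid protein",
    "capsid scaffold protein",
)
_PACKAGING_LENGTHS = (600, 1800, 1500, 1200, 900)

EXONUCLEASE_PRODUCT = "exonuclease"
_EXO_LENGTH = 900


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic population.

    Substitution rates are expected substitutions per site relative to the
    respective ancestor; event probabilities are per genome (per module for
    ``module_loss_prob``).
    """

    n_clusters: int = 3
    genomes_per_cluster: int = 5
    genome_length_range: tuple[int, int] = (45_000, 170_000)
    gc_range: tuple[float, float] = (0.355, 0.464)
    n_core_modules: int = 6
    n_variable_modules: int = 8
    genes_per_module: tuple[int, int] = (2, 10)
    within_cluster_sub_rate: float = 0.01
    between_cluster_sub_rate: float = 0.15
    hgt_swap_prob: float = 0.0
    inversion_prob: float = 0.0
    module_loss_prob: float = 0.0
    repeat_region_prob: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.genomes_per_cluster < 1:
            raise ConfigError("genomes_per_cluster must be >= 1")
        lo, hi = self.genome_length_range
        if not (20_000 <= lo <= hi <= 200_000):
            raise ConfigError("genome_length_range must lie within [20000, 200000]")
        glo, ghi = self.gc_range
        if not (0.0 < glo <= ghi < 1.0):
            raise ConfigError("gc_range must lie within (0, 1)")
        for name in (
            "within_cluster_sub_rate",
            "between_cluster_sub_rate",
            "hgt_swap_prob",
            "inversion_prob",
            "module_loss_prob",
            "repeat_region_prob",
            "indel_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.between_cluster_sub_rate <= self.within_cluster_sub_rate:
            raise ConfigError(
                "between_cluster_sub_rate must exceed within_cluster_sub_rate"
            )
        if self.n_core_modules < 2:
            raise ConfigError("n_core_modules must be >= 2 (packaging + exonuclease)")
        if self.n_variable_modules < 1:
            raise ConfigError("n_variable_modules must be >= 1")
        ng_lo, ng_hi = self.genes_per_module
        if not (1 <= ng_lo <= ng_hi):
            raise ConfigError("genes_per_module must be a valid count range")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated population."""

    cluster_of: dict[str, str]
    module_order: dict[str, list[tuple[str, int]]]
    family_of: dict[str, str]
    applied_events: list[tuple[str, str, str]] = field(default_factory=list)
    # internal plumbing: per-genome module spans (module_id, start, end, orient)
    module_coords: dict[str, list[tuple[str, int, int, int]]] = field(default_factory=dict)
    # per-cluster targets the generator aimed for (label -> value)
    gc_targets: dict[str, float] = field(default_factory=dict)
    length_targets: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence-level primitives


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def mutate_sequence(seq: str, rate: float, seed: int | np.random.Generator) -> str:
    """Substitute each site with probability ``rate``, uniformly over the
    three alternative bases. Length-preserving; non-ACGT input is rejected."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = _BASE_INDEX[arr]
    if (idx == 255).any():
        raise ValueError("mutate_sequence requires an ACGT-only sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hit = rng.random(len(seq)) < rate
    offsets = rng.integers(1, 4, size=len(seq))
    new_idx = np.where(hit, (idx.astype(np.int64) + offsets) % 4, idx)
    return _BASES[new_idx].tobytes().decode()


def gc_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return float(((arr == ord("G")) | (arr == ord("C"))).mean())


# ---------------------------------------------------------------------------
# structured genome representation (internal)


@dataclass
class _Gene:
    seq: str
    product: str
    family_id: str
    strand: str = "+"


@dataclass
class _ModuleInstance:
    module_id: str
    genes: list[_Gene]
    spacers: list[str]  # one trailing spacer per gene
    orientation: int = 1

    @property
    def length(self) -> int:
        return sum(len(g.seq) for g in self.genes) + sum(len(s) for s in self.spacers)

    def assemble(self) -> str:
        parts = []
        for g, sp in zip(self.genes, self.spacers):
            parts.append(g.seq if g.strand == "+" else revcomp(g.seq))
            parts.append(sp)
        return "".join(parts)


def _draw_gene_length(rng: np.random.Generator, lo: int = 300, hi: int = 3000) -> int:
    return int(rng.integers(lo // 3, hi // 3 + 1)) * 3


def _draw_spacer(rng: np.random.Generator, gc: float) -> str:
    return random_sequence(rng, int(rng.integers(2, 201)), gc)


# ---------------------------------------------------------------------------
# population generation


def _plan_clusters(cfg: SimConfig, rng: np.random.Generator):
    """Per-cluster target length and G+C, spread over the configured ranges."""
    lo, hi = cfg.genome_length_range
    glo, ghi = cfg.gc_range
    lengths, gcs = [], []
    for c in range(cfg.n_clusters):
        frac = (c + 0.5) / cfg.n_clusters
        jitter = rng.uniform(-0.25, 0.25) / cfg.n_clusters
        f = min(max(frac + jitter, 0.02), 0.98)
        lengths.append(int(lo + f * (hi - lo)))
        # larger phage genomes tend to be more AT-rich; mirror that trend
        gcs.append(ghi - f * (ghi - glo))
    return lengths, gcs


def generate_population(
    config: SimConfig,
) -> tuple[list[PhageGenome], list[GeneAnnotation], SyntheticTruth]:
    """Generate genomes, annotations and truth for one synthetic population.

    Deterministic for a fixed config (including seed). Every genome carries
    the conserved packaging-module gene order and 1–3 exonuclease genes.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g0 = (cfg.gc_range[0] + cfg.gc_range[1]) / 2

    lengths, gcs = _plan_clusters(cfg, rng)
    n_exo_by_cluster = [int(rng.integers(1, 4)) for _ in range(cfg.n_clusters)]
    max_exo = 3

    # --- global ancestral core modules -------------------------------------
    # module ids fix genome positions; content of "var" modules is
    # cluster-specific, core modules descend from these ancestors.
    core_genes: dict[str, list[tuple[str, str, str]]] = {}  # mod -> [(fam, product, seq)]
    core_genes["m00_pack"] = [
        (f"fam_pack_{i}", prod, random_sequence(rng, ln, g0))
        for i, (prod, ln) in enumerate(zip(PACKAGING_PRODUCTS, _PACKAGING_LENGTHS))
    ]
    core_genes["m01_exo"] = [
        (f"fam_exo_{i}", EXONUCLEASE_PRODUCT, random_sequence(rng, _EXO_LENGTH, g0))
        for i in range(max_exo)
    ]
    generic_ids = [f"m{2 + i:02d}_core" for i in range(cfg.n_core_modules - 2)]
    for mod in generic_ids:
        n_g = int(rng.integers(cfg.genes_per_module[0], cfg.genes_per_module[1] + 1))
        core_genes[mod] = [
            (
                f"fam_{mod}_{i}",
                "hypothetical protein",
                random_sequence(rng, _draw_gene_length(rng, 300, 1200), g0),
            )
            for i in range(n_g)
        ]

    var_ids = [f"v{i:02d}_var" for i in range(cfg.n_variable_modules)]
    # interleave conserved and variable modules: pack first, then alternate
    order: list[str] = ["m00_pack"]
    rest_core = ["m01_exo"] + generic_ids
    vi, ci = 0, 0
    while vi < len(var_ids) or ci < len(rest_core):
        if vi < len(var_ids):
            order.append(var_ids[vi])
            vi += 1
        if ci < len(rest_core):
            order.append(rest_core[ci])
            ci += 1

    # --- cluster ancestors --------------------------------------------------
    cluster_modules: list[dict[str, _ModuleInstance]] = []
    for c in range(cfg.n_clusters):
        label = f"C{c}"
        mods: dict[str, _ModuleInstance] = {}
        core_parts: list[str] = []
        for mod, genes in core_genes.items():
            use = genes[: n_exo_by_cluster[c]] if mod == "m01_exo" else genes
            inst_genes = [
                _Gene(mutate_sequence(seq, cfg.between_cluster_sub_rate, rng), prod, fam)
                for fam, prod, seq in use
            ]
            mods[mod] = _ModuleInstance(mod, inst_genes, spacers=[])
            core_parts.extend(g.seq for g in inst_genes)
        core_seq = "".join(core_parts)
        core_len = len(core_seq)
        core_gc = gc_fraction(core_seq)

        # spacer lengths drawn up front so the variable-gene budget is exact
        n_core_genes = sum(len(m.genes) for m in mods.values())
        spacer_lens = []
        # variable module gene counts sized to fill the remaining length
        budget_guess = lengths[c] - core_len
        ng_lo, ng_hi = cfg.genes_per_module
        var_counts = []
        per_mod = budget_guess / cfg.n_variable_modules
        for _ in var_ids:
            n_g = int(round(per_mod / 1200))
            var_counts.append(min(max(n_g, ng_lo), ng_hi))
        n_var_genes = sum(var_counts)
        n_spacers = n_core_genes + n_var_genes
        spacer_lens = [int(rng.integers(2, 201)) for _ in range(n_spacers)]
        var_budget = lengths[c] - core_len - sum(spacer_lens)
        var_budget = max(var_budget, 300 * n_var_genes)

        # solve the variable-region G+C so the whole genome hits its target
        target_gc = gcs[c]
        other_len = var_budget + sum(spacer_lens)
        g_v = (target_gc * (core_len + other_len) - core_gc * core_len) / other_len
        g_v = min(max(g_v, 0.15), 0.85)

        # draw variable gene lengths summing ~ var_budget
        weights = rng.uniform(0.8, 1.2, size=n_var_genes)
        raw = weights / weights.sum() * var_budget
        gene_lens = [min(max(int(round(x / 3)) * 3, 300), 3000) for x in raw]

        gi = 0
        si = 0
        for mod, n_g in zip(var_ids, var_counts):
            inst_genes = []
            for j in range(n_g):
                seq = random_sequence(rng, gene_lens[gi], g_v)
                inst_genes.append(
                    _Gene(seq, "hypothetical protein", f"fam_{label}_{mod}_{j}")
                )
                gi += 1
            mods[mod] = _ModuleInstance(mod, inst_genes, spacers=[])
        # assign spacers in module order
        for mod in order:
            inst = mods[mod]
            inst.spacers = [
                random_sequence(rng, spacer_lens[si + j], g_v)
                for j in range(len(inst.genes))
            ]
            si += len(inst.genes)
        cluster_modules.append(mods)

    # --- genomes ------------------------------------------------------------
    genomes: list[PhageGenome] = []
    annotations: list[GeneAnnotation] = []
    truth = SyntheticTruth(cluster_of={}, module_order={}, family_of={})

    for c in range(cfg.n_clusters):
        label = f"C{c}"
        truth.gc_targets[label] = gcs[c]
        truth.length_targets[label] = lengths[c]
        for g in range(cfg.genomes_per_cluster):
            gid = f"{label}_g{g}"
            modules = []
            for mod in order:
                anc = cluster_modules[c][mod]
                genes = []
                for gene in anc.genes:
                    seq = mutate_sequence(gene.seq, cfg.within_cluster_sub_rate, rng)
                    if cfg.indel_rate > 0:
                        seq = _apply_codon_indels(seq, cfg.indel_rate, rng)
                    genes.append(replace(gene, seq=seq))
                spacers = [
                    mutate_sequence(sp, cfg.within_cluster_sub_rate, rng)
                    for sp in anc.spacers
                ]
                modules.append(_ModuleInstance(mod, genes, spacers))

            events = _draw_events(cfg, rng, modules, c)
            for kind, mod_id, donor_cluster in events:
                modules = _apply_structured_event(
                    modules, kind, mod_id, cluster_modules, donor_cluster, rng, cfg
                )
                truth.applied_events.append((gid, kind, mod_id))

            seq, annots, coords = _assemble(gid, modules)
            genomes.append(PhageGenome(gid, seq, f"{gid} synthetic cluster {label}"))
            annotations.extend(annots)
            truth.cluster_of[gid] = label
            truth.module_order[gid] = [(m.module_id, m.orientation) for m in modules]
            truth.module_coords[gid] = coords
            for a in annots:
                truth.family_of[a.gene_id] = a.family_id
    return genomes, annotations, truth


def _apply_codon_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Insert/delete whole codons at ~``rate`` events per codon."""
    n_codons = len(seq) // 3
    n_events = rng.binomial(n_codons, rate)
    for _ in range(n_events):
        pos = int(rng.integers(0, max(len(seq) // 3, 1))) * 3
        if rng.random() < 0.5 and len(seq) > 303:
            seq = seq[:pos] + seq[pos + 3 :]
        else:
            codon = random_sequence(rng, 3, 0.5)
            seq = seq[:pos] + codon + seq[pos:]
    return seq


def _draw_events(cfg: SimConfig, rng, modules, cluster_idx):
    """Per-genome event draws, in a fixed order (swap, inversion, loss, repeat)."""
    events: list[tuple[str, str, int | None]] = []
    var_mods = [m.module_id for m in modules if m.module_id.startswith("v")]
    losable = [
        m.module_id
        for m in modules
        if m.module_id not in ("m00_pack", "m01_exo")
    ]
    if rng.random() < cfg.hgt_swap_prob and cfg.n_clusters > 1 and var_mods:
        mod = var_mods[int(rng.integers(len(var_mods)))]
        donors = [c for c in range(cfg.n_clusters) if c != cluster_idx]
        donor = donors[int(rng.integers(len(donors)))]
        events.append(("hgt_swap", mod, donor))
    if rng.random() < cfg.inversion_prob:
        all_mods = [m.module_id for m in modules]
        events.append(("inversion", all_mods[int(rng.integers(len(all_mods)))], None))
    for mod in losable:
        if rng.random() < cfg.module_loss_prob:
            events.append(("loss", mod, None))
    if rng.random() < cfg.repeat_region_prob and var_mods:
        events.append(("repeat", var_mods[int(rng.integers(len(var_mods)))], None))
    return events


def _apply_structured_event(
    modules: list[_ModuleInstance],
    kind: str,
    module_id: str,
    cluster_modules,
    donor_cluster: int | None,
    rng,
    cfg: SimConfig,
) -> list[_ModuleInstance]:
    out: list[_ModuleInstance] = []
    for m in modules:
        if m.module_id != module_id:
            out.append(m)
            continue
        if kind == "loss":
            continue
        if kind == "inversion":
            out.append(_invert_module(m))
        elif kind == "repeat":
            out.append(m)
            copy = _ModuleInstance(
                m.module_id,
                [replace(g) for g in m.genes],
                list(m.spacers),
                m.orientation,
            )
            out.append(copy)
        elif kind == "hgt_swap":
            donor = cluster_modules[donor_cluster][module_id]
            genes = [
                _Gene(
                    mutate_sequence(g.seq, cfg.within_cluster_sub_rate, rng),
                    g.product,
                    g.family_id,
                    g.strand,
                )
                for g in donor.genes
            ]
            out.append(_ModuleInstance(module_id, genes, list(donor.spacers)))
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    if all(m.module_id != module_id for m in modules):
        raise ValueError(f"module {module_id!r} not present in genome")
    return out


def _invert_module(m: _ModuleInstance) -> _ModuleInstance:
    """Reverse-complement a module: genes reversed, strands flipped."""
    genes = []
    spacers = []
    # module layout is (gene, spacer)*; the reverse complement is
    # (rc(spacer), rc(gene))* — keep the (gene, spacer) layout by pairing
    # each reversed gene with the reverse-complemented preceding spacer.
    for g, sp in zip(reversed(m.genes), reversed(m.spacers)):
        genes.append(replace(g, strand="-" if g.strand == "+" else "+"))
        spacers.append(revcomp(sp))
    return _ModuleInstance(m.module_id, genes, spacers, orientation=-m.orientation)


def _assemble(
    gid: str, modules: list[_ModuleInstance]
) -> tuple[str, list[GeneAnnotation], list[tuple[str, int, int, int]]]:
    """Concatenate modules into a genome with 1-based gene coordinates."""
    parts: list[str] = []
    annots: list[GeneAnnotation] = []
    coords: list[tuple[str, int, int, int]] = []
    pos = 0
    gene_counter = 0
    for m in modules:
        start = pos + 1
        for g, sp in zip(m.genes, m.spacers):
            gene_counter += 1
            gene_id = f"{gid}_g{gene_counter:03d}"
            gseq = g.seq if g.strand == "+" else revcomp(g.seq)
            annots.append(
                GeneAnnotation(
                    genome_id=gid,
                    gene_id=gene_id,
                    start=pos + 1,
                    end=pos + len(g.seq),
                    strand=g.strand,
                    product=g.product,
                    family_id=g.family_id,
                    module_id=m.module_id,
                )
            )
            parts.append(gseq)
            pos += len(g.seq)
            parts.append(sp)
            pos += len(sp)
        coords.append((m.module_id, start, pos, m.orientation))
    return "".join(parts), annots, coords


# ---------------------------------------------------------------------------
# standalone rearrangement on assembled genomes


def apply_rearrangement(
    genome: PhageGenome,
    annotations: list[GeneAnnotation],
    module_map: list[tuple[str, int, int, int]],
    event_kind: str,
    module_id: str,
    seed: int = 0,
    donor: tuple[str, list[GeneAnnotation]] | None = None,
) -> tuple[PhageGenome, list[GeneAnnotation], list[tuple[str, int, int, int]], tuple]:
    """Apply one rearrangement event to an assembled genome.

    ``module_map`` lists (module_id, start, end, orientation) spans, 1-based
    inclusive. For ``hgt_swap`` the ``donor`` is the replacement sequence and
    its gene annotations with coordinates relative to the donor sequence.
    Returns the new genome, annotations, module map, and an event record.
    """
    spans = [m for m in module_map if m[0] == module_id]
    if not spans:
        raise ValueError(f"module {module_id!r} not present in genome {genome.id!r}")
    mod_id, start, end, orient = spans[0]
    seq = genome.sequence
    prefix, mid, suffix = seq[: start - 1], seq[start - 1 : end], seq[end:]

    inside = [a for a in annotations if start <= a.start and a.end <= end]
    before = [a for a in annotations if a.end < start]
    after = [a for a in annotations if a.start > end]

    if event_kind == "inversion":
        new_mid = revcomp(mid)
        new_inside = []
        for a in inside:
            s = start + (end - a.end)
            e = start + (end - a.start)
            new_inside.append(
                replace_annotation(a, start=s, end=e, strand="-" if a.strand == "+" else "+")
            )
        new_seq = prefix + new_mid + suffix
        new_annots = before + sorted(new_inside, key=lambda a: a.start) + after
        new_map = [
            (m, s, e, -o) if (m, s, e, o) == spans[0] else (m, s, e, o)
            for (m, s, e, o) in module_map
        ]
    elif event_kind == "loss":
        delta = -(end - start + 1)
        new_seq = prefix + suffix
        new_annots = before + [
            replace_annotation(a, start=a.start + delta, end=a.end + delta) for a in after
        ]
        new_map = [(m, s, e, o) for (m, s, e, o) in module_map if (m, s, e, o) != spans[0]]
        new_map = [
            (m, s + delta, e + delta, o) if s > end else (m, s, e, o)
            for (m, s, e, o) in new_map
        ]
    elif event_kind == "repeat":
        delta = end - start + 1
        new_seq = prefix + mid + mid + suffix
        copy = [
            replace_annotation(
                a, gene_id=a.gene_id + "_r2", start=a.start + delta, end=a.end + delta
            )
            for a in inside
        ]
        new_annots = before + inside + copy + [
            replace_annotation(a, start=a.start + delta, end=a.end + delta) for a in after
        ]
        new_map = []
        for m, s, e, o in module_map:
            if (m, s, e, o) == spans[0]:
                new_map.append((m, s, e, o))
                new_map.append((m, s + delta, e + delta, o))
            elif s > end:
                new_map.append((m, s + delta, e + delta, o))
            else:
                new_map.append((m, s, e, o))
    elif event_kind == "hgt_swap":
        if donor is None:
            raise ValueError("hgt_swap requires a donor (sequence, annotations)")
        donor_seq, donor_annots = donor
        delta = len(donor_seq) - (end - start + 1)
        new_seq = prefix + donor_seq + suffix
        new_inside = [
            replace_annotation(
                a,
                genome_id=genome.id,
                gene_id=f"{genome.id}_{a.gene_id}",
                start=a.start + start - 1,
                end=a.end + start - 1,
            )
            for a in donor_annots
        ]
        new_annots = before + new_inside + [
            replace_annotation(a, start=a.start + delta, end=a.end + delta) for a in after
        ]
        new_map = []
        for m, s, e, o in module_map:
            if (m, s, e, o) == spans[0]:
                new_map.append((m, s, s + len(donor_seq) - 1, o))
            elif s > end:
                new_map.append((m, s + delta, e + delta, o))
            else:
                new_map.append((m, s, e, o))
    else:
        raise ValueError(f"unknown event kind {event_kind!r}")

    record = (genome.id, event_kind, module_id)
    return (
        PhageGenome(genome.id, new_seq, genome.description),
        new_annots,
        new_map,
        record,
    )


def replace_annotation(a: GeneAnnotation, **kw) -> GeneAnnotation:
    from dataclasses import replace as _dc_replace

    return _dc_replace(a, **kw)
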