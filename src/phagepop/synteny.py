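"""Gene-order locally collinear blocks (LCBs).

A collinear block is a maximal run of gene families that appears in two or
more genomes in the same relative order and orientation (or exactly
reversed with flipped strands). Blocks are detected on the gene-order level
— phage genomes are organised in gene modules, so gene-order blocks
capture the same structure whole-genome aligners report as LCBs, and they
can be validated directly against simulated module truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GeneAnnotation


@dataclass
class BlockMember:
    genome_id: str
    start_index: int  # gene index in the genome's filtered gene order
    end_index: int
    orientation: int  # +1 = same order as block, -1 = reversed


@dataclass
class CollinearBlock:
    block_id: str
    families: list[tuple[str, int]]  # (family_id, orientation) in block order
    members: list[BlockMember]

    def __len__(self) -> int:
        return len(self.families)


def _gene_orders(
    annotations: list[GeneAnnotation],
) -> dict[str, list[tuple[str, int, str]]]:
    """Per genome: ordered (family_id, strand_sign, gene_id), by start coord."""
    per: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        if a.family_id is None:
            raise ValueError(f"gene {a.gene_id!r} has no family_id")
        per.setdefault(a.genome_id, []).append(a)
    out = {}
    for gid, anns in per.items():
        anns.sort(key=lambda a: a.start)
        out[gid] = [(a.family_id, 1 if a.strand == "+" else -1, a.gene_id) for a in anns]
    return out


def find_lcbs(
    annotations: list[GeneAnnotation], min_block_genes: int = 2
) -> list[CollinearBlock]:
    """Detect maximal collinear blocks shared by >=2 genomes.

    Deterministic seed-and-extend: genomes are scanned in input order,
    positions left to right. A seed family occurrence is matched with the
    leftmost unused occurrence of the same family in every other genome;
    the block is extended in both directions while *all* members continue
    with the same next family and consistent relative orientation. Each
    gene occurrence joins at most one block.
    """
    orders = _gene_orders(annotations)
    genome_ids = list(orders)
    # occurrences per family: (genome, index)
    occurrences: dict[str, list[tuple[str, int]]] = {}
    for gid in genome_ids:
        for idx, (fam, _s, _g) in enumerate(orders[gid]):
            occurrences.setdefault(fam, []).append((gid, idx))

    used: set[tuple[str, int]] = set()
    blocks: list[CollinearBlock] = []

    def entry(gid: str, idx: int) -> tuple[str, int]:
        return orders[gid][idx][0], orders[gid][idx][1]

    for gid in genome_ids:
        for seed_idx in range(len(orders[gid])):
            if (gid, seed_idx) in used:
                continue
            seed_fam, seed_sign = entry(gid, seed_idx)
            # seed member plus the leftmost unused occurrence in every other genome
            members: list[list] = [[gid, seed_idx, seed_idx, 1]]
            for other, oidx in occurrences.get(seed_fam, ()):
                if other == gid or (other, oidx) in used:
                    continue
                if any(m[0] == other for m in members):
                    continue
                _ofam, osign = entry(other, oidx)
                members.append([other, oidx, oidx, 1 if osign == seed_sign else -1])
            if len(members) < 2:
                continue

            taken = {(m[0], m[1]) for m in members}

            def can_step(m, direction: int):
                """Member m's next occurrence when the block grows one family
                in `direction` (seed coordinates); None if it cannot."""
                mgid, lo, hi, orient = m
                nxt = (hi + 1) if direction * orient > 0 else (lo - 1)
                if (
                    nxt < 0
                    or nxt >= len(orders[mgid])
                    or (mgid, nxt) in used
                    or (mgid, nxt) in taken
                ):
                    return None
                fam, sign = entry(mgid, nxt)
                return nxt, fam, sign * orient

            for direction in (1, -1):
                while True:
                    steps = [can_step(m, direction) for m in members]
                    if any(s is None for s in steps):
                        break
                    if len({(f, rs) for _n, f, rs in steps}) != 1:
                        break
                    for m, s in zip(members, steps):
                        if direction * m[3] > 0:
                            m[2] = s[0]
                        else:
                            m[1] = s[0]
                        taken.add((m[0], s[0]))

            if members[0][2] - members[0][1] + 1 < min_block_genes:
                continue
            used.update(taken)
            fams_in_block = [
                (orders[gid][k][0], orders[gid][k][1])
                for k in range(members[0][1], members[0][2] + 1)
            ]
            blocks.append(
                CollinearBlock(
                    block_id=f"LCB{len(blocks) + 1:03d}",
                    families=fams_in_block,
                    members=[BlockMember(m[0], m[1], m[2], m[3]) for m in members],
                )
            )
    return blocks


def lcb_census(blocks: list[CollinearBlock], genome_ids: list[str]) -> pd.DataFrame:
    """Block x genome presence table with a per-genome count row appended."""
    table = pd.DataFrame(
        0, index=[b.block_id for b in blocks], columns=list(genome_ids), dtype=int
    )
    for b in blocks:
        for m in b.members:
            if m.genome_id in table.columns:
                table.loc[b.block_id, m.genome_id] += 1
    return table


def per_genome_block_counts(blocks: list[CollinearBlock], genome_ids: list[str]) -> dict[str, int]:
    counts = {g: 0 for g in genome_ids}
    for b in blocks:
        for m in b.members:
            if m.genome_id in counts:
                counts[m.genome_id] += 1
    return counts
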