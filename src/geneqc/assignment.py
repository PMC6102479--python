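"""Read multiplicity classification and read-to-gene assignment.

Builds, per gene i, the two read sets the dependent variable needs:
G_i (every alignment unit assigned to the gene) and U_i (the uniquely
mapping subset), plus the pairwise counts of multi-mapping reads (MMRs)
shared between genes that drive the transcriptomic feature D2.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "ReadMultiplicity",
    "GeneReadSets",
    "classify_reads",
    "aligned_blocks",
    "assign_reads_to_genes",
    "shared_mmr_counts",
]


@dataclass(frozen=True)
class ReadMultiplicity:
    read_id: str  # alignment unit id (read, or read/1 read/2 for pairs)
    n_top_alignments: int

    @property
    def is_mmr(self) -> bool:
        return self.n_top_alignments > 1


@dataclass
class GeneReadSets:
    gene_id: str
    G: set[str] = field(default_factory=set)  # all assigned units
    U: set[str] = field(default_factory=set)  # uniquely-mapping subset


def classify_reads(
    alignments: Iterable[AlignmentRecord],
) -> dict[str, ReadMultiplicity]:
    """Determine each alignment unit's mapping multiplicity.

    Precedence: the NH tag when present (max taken, with a warning, if records
    of one unit disagree); otherwise the number of the unit's records tying at
    the maximal AS score (all records tie when AS is absent).  Secondary
    alignments count toward multiplicity; supplementary ones are ignored.
    """
    nh_seen: dict[str, list[int]] = {}
    scores: dict[str, list[int | None]] = {}
    for rec in alignments:
        if rec.is_unmapped or rec.is_supplementary:
            continue
        unit = rec.unit_id
        scores.setdefault(unit, []).append(rec.align_score)
        if rec.nh is not None:
            nh_seen.setdefault(unit, []).append(rec.nh)

    result: dict[str, ReadMultiplicity] = {}
    for unit, unit_scores in scores.items():
        nhs = nh_seen.get(unit)
        if nhs:
            if len(set(nhs)) > 1:
                warnings.warn(
                    f"conflicting NH values {sorted(set(nhs))} for unit {unit};"
                    " taking the maximum",
                    stacklevel=2,
                )
            n = max(nhs)
        else:
            present = [s for s in unit_scores if s is not None]
            if present:
                top = max(present)
                n = sum(1 for s in present if s == top)
            else:
                n = len(unit_scores)
        result[unit] = ReadMultiplicity(unit, max(n, 1))
    return result


_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")


def aligned_blocks(pos: int, cigar: str) -> list[tuple[int, int]]:
    """0-based half-open reference blocks covered by an alignment.

    M/=/X/D extend the current block; N closes it (a splice gap is consumed
    reference but not an aligned block); I/S/H/P touch no reference.
    """
    blocks: list[tuple[int, int]] = []
    ref = pos - 1
    cur_start: int | None = None
    for length_s, op in _CIGAR_OP.findall(cigar):
        length = int(length_s)
        if op in "M=XD":
            if cur_start is None:
                cur_start = ref
            ref += length
        elif op == "N":
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
            ref += length
    if cur_start is not None:
        blocks.append((cur_start, ref))
    return blocks


def assign_reads_to_genes(
    alignments: Iterable[AlignmentRecord],
    genes: list[GeneModel],
    multiplicity: Mapping[str, ReadMultiplicity],
    min_overlap_bp: int = 1,
) -> list[GeneReadSets]:
    """Assign alignment units to genes by genomic-span overlap.

    A unit lands in G_i when at least one of its alignments has an aligned
    block overlapping gene i's span by >= min_overlap_bp; it is additionally
    in U_i when its multiplicity is 1.  Alignments on contigs absent from the
    annotation are skipped (counted and logged).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(genes):
        s0, e0 = gene.span0
        trees.setdefault(gene.contig, IntervalTree()).addi(s0, e0, idx)

    sets = [GeneReadSets(g.gene_id) for g in genes]
    skipped = 0
    for rec in alignments:
        if rec.is_unmapped or rec.is_supplementary:
            continue
        tree = trees.get(rec.contig)
        if tree is None:
            skipped += 1
            continue
        unit = rec.unit_id
        for bs, be in aligned_blocks(rec.pos, rec.cigar):
            for iv in tree.overlap(bs, be):
                if min(be, iv.end) - max(bs, iv.begin) >= min_overlap_bp:
                    sets[iv.data].G.add(unit)
    if skipped:
        logger.info("skipped %d alignments on contigs absent from annotation", skipped)

    for gene_sets in sets:
        gene_sets.U = {
            u
            for u in gene_sets.G
            if u in multiplicity and multiplicity[u].n_top_alignments == 1
        }
    return sets


def shared_mmr_counts(
    gene_read_sets: list[GeneReadSets],
    multiplicity: Mapping[str, ReadMultiplicity],
) -> dict[tuple[str, str], int]:
    """Count MMR units shared between gene pairs (symmetric, zero pairs omitted).

    Keys are lexicographically sorted (gene_i, gene_y) tuples.
    """
    unit_genes: dict[str, list[str]] = {}
    for gene_sets in gene_read_sets:
        for unit in gene_sets.G:
            mult = multiplicity.get(unit)
            if mult is not None and mult.is_mmr:
                unit_genes.setdefault(unit, []).append(gene_sets.gene_id)

    counts: dict[tuple[str, str], int] = {}
    for genes_of_unit in unit_genes.values():
        if len(genes_of_unit) < 2:
            continue
        for a, b in combinations(sorted(genes_of_unit), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts
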