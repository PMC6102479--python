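"""Self-contained synthetic inputs: toy genomes with duplicated genes,
GFF3 annotations, SAM alignments with ground-truth multiplicity, and
D-score samples drawn from known mixtures.

The generator emulates the one phenomenon the scoring pipeline exists to
measure — gene duplication creating reads that fit several genomic locations
equally well.  Reads are error-free and a read's multiplicity is *defined*
as its number of exact occurrences in the genome (either strand), so the
ground truth carried in the NH tags is unambiguous.  Defaults describe a
small but realistic instance: 200 genes of 500 bp on one contig with 200 bp
spacers, 30% of genes duplicated at 2% per-base divergence, 75 bp reads at
20x mean depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel
from .similarity import reverse_complement

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_reads_sam",
    "simulate_dscore_sample",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    gene_length_bp: int = 500
    duplicate_fraction: float = 0.3
    divergence: float = 0.02
    read_length_bp: int = 75
    mean_depth: float = 20.0
    spacer_bp: int = 200
    contig: str = "chr1"
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must lie in [0, 1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if min(self.n_genes, self.gene_length_bp, self.read_length_bp, self.spacer_bp) < 1:
            raise ValueError("counts and lengths must be positive")
        if self.read_length_bp > self.gene_length_bp:
            raise ValueError("read_length_bp must not exceed gene_length_bp")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    """Copy ``seq`` with per-base substitutions at ``rate``; returns
    (copy, realized identity)."""
    if rate == 0.0:
        return seq, 1.0
    chars = np.array(list(seq))
    hits = rng.random(chars.size) < rate
    for idx in np.nonzero(hits)[0]:
        choices = [b for b in "ACGT" if b != chars[idx]]
        chars[idx] = rng.choice(choices)
    return "".join(chars), 1.0 - hits.sum() / chars.size


def simulate_genome(
    config: SimulationConfig,
) -> tuple[str, str, pd.DataFrame, list[GeneModel]]:
    """Build a toy genome: random genes, a fraction duplicated elsewhere.

    Returns (fasta_text, gff3_text, truth, genes) where ``truth`` has columns
    source / copy / identity, one row per duplicate pair, and ``genes`` are
    the annotated models (originals first, then copies, genomic order).
    """
    rng = np.random.default_rng(config.seed)
    originals = [_random_seq(rng, config.gene_length_bp) for _ in range(config.n_genes)]
    n_dup = int(round(config.duplicate_fraction * config.n_genes))
    dup_sources = sorted(rng.choice(config.n_genes, size=n_dup, replace=False))

    blocks: list[str] = []  # gene sequences in genomic order
    names: list[str] = []
    truth_rows = []
    for gi, seq in enumerate(originals):
        blocks.append(seq)
        names.append(f"gene{gi + 1:04d}")
    for ci, src in enumerate(dup_sources):
        copy_seq, identity = _diverge(rng, originals[src], config.divergence)
        copy_name = f"gene{config.n_genes + ci + 1:04d}"
        blocks.append(copy_seq)
        names.append(copy_name)
        truth_rows.append(
            {"source": names[src], "copy": copy_name, "identity": identity}
        )

    genes: list[GeneModel] = []
    pos = 0  # 0-based cursor
    parts: list[str] = []
    for name, seq in zip(names, blocks):
        parts.append(_random_seq(rng, config.spacer_bp))
        pos += config.spacer_bp
        start0 = pos
        parts.append(seq)
        pos += len(seq)
        genes.append(GeneModel(name, config.contig, start0 + 1, pos, "+"))
    parts.append(_random_seq(rng, config.spacer_bp))
    genome = "".join(parts)

    fasta_lines = [f">{config.contig}"]
    for i in range(0, len(genome), 70):
        fasta_lines.append(genome[i : i + 70])
    fasta_text = "\n".join(fasta_lines) + "\n"

    gff_lines = ["##gff-version 3"]
    for g in genes:
        gff_lines.append(
            f"{g.contig}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
    gff3_text = "\n".join(gff_lines) + "\n"

    truth = pd.DataFrame(truth_rows, columns=["source", "copy", "identity"])
    return fasta_text, gff3_text, truth, genes


def _occurrences(genome: str, query: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrence positions of query."""
    hits = []
    idx = genome.find(query)
    while idx != -1:
        hits.append(idx)
        idx = genome.find(query, idx + 1)
    return hits


def simulate_reads_sam(
    genome: str,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> str:
    """Error-free reads uniform over gene bodies; one SAM record per exact
    genomic occurrence of the read (either strand), NH = occurrence count,
    identical AS on all records of a read (they tie by construction)."""
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length_bp
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{config.contig}\tLN:{len(genome)}",
        "@PG\tID:geneqc-sim\tPN:geneqc-sim",
    ]
    read_no = 0
    for gene in genes:
        s0, e0 = gene.span0
        n_reads = int(round(config.mean_depth * gene.length / rl))
        if e0 - s0 < rl:
            continue
        starts = rng.integers(s0, e0 - rl + 1, size=n_reads)
        for start in starts:
            read = genome[start : start + rl]
            read_no += 1
            fwd = _occurrences(genome, read)
            rev = _occurrences(genome, reverse_complement(read))
            nh = len(fwd) + len(rev)
            mapq = 60 if nh == 1 else 1
            first = True
            for occ_pos, is_rev in [(p, False) for p in fwd] + [(p, True) for p in rev]:
                flags = 0
                if is_rev:
                    flags |= 0x10
                if not first:
                    flags |= 0x100
                seq = read if not is_rev else reverse_complement(read)
                lines.append(
                    "\t".join(
                        (
                            f"r{read_no:06d}",
                            str(flags),
                            config.contig,
                            str(occ_pos + 1),
                            str(mapq),
                            f"{rl}M",
                            "*",
                            "0",
                            "0",
                            seq,
                            "*",
                            f"NH:i:{nh}",
                            "AS:i:0",
                        )
                    )
                )
                first = False
    return "\n".join(lines) + "\n"


def simulate_dscore_sample(
    family: str,
    weights: Sequence[float],
    params: Sequence[tuple[float, float]],
    n: int,
    seed: int = 1,
) -> np.ndarray:
    """n draws from a known mixture, for exercising the fitting machinery.

    Gaussian components are (mean, sd); Gamma components are (shape, scale).
    """
    w = np.asarray(weights, dtype=float)
    if w.size != len(params):
        raise ValueError("weights and params disagree on component count")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(w.size, size=n, p=w)
    out = np.empty(n)
    for j, (a, b) in enumerate(params):
        mask = comp == j
        if family == "gaussian":
            out[mask] = rng.normal(a, b, size=mask.sum())
        elif family == "gamma":
            out[mask] = rng.gamma(a, b, size=mask.sum())
        else:
            raise ValueError(f"unknown family {family!r}")
    return out
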