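"""Pairwise gene-sequence similarity and the genomic feature D1.

For a gene i and a partner y, a local alignment of the two gene sequences
yields ``ss`` (fraction of identical columns in the best local alignment)
and ``l`` (the longest run of consecutively matching bases within it).
D1(i) = max over partners y of ss_{i,y} * l_{i,y}: a gene that shares a long,
near-identical block with another genomic location scores high, because reads
from that block cannot be placed unambiguously.

The set ``S`` of *significant* similarity partners (used by the network
feature D3) is gated by a minimum identity and minimum match length so that
weak, short local hits do not inflate a gene's degree.

Alignment scoring defaults: match +1, mismatch -1, gap open -2, gap extend
-1; pairs whose best local score falls below ``min_score`` are treated as
unrelated.  Both orientations (partner as given and reverse-complemented)
are aligned and the higher-scoring one kept, since duplications happen on
either strand.  The two sequences are canonicalized (sorted) before aligning
so the result is exactly symmetric in its arguments.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner

__all__ = [
    "SimilarityHit",
    "reverse_complement",
    "align_pair",
    "find_candidate_pairs",
    "compute_D1",
    "significant_partners",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimilarityHit:
    """Similarity of gene_i to one partner location gene_y."""

    gene_i: str
    gene_y: str
    ss: float  # identity fraction of the best local alignment, in [0, 1]
    l: int  # longest consecutive run of matching bases, in bp

    @property
    def product(self) -> float:
        return self.ss * self.l


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _align_oriented(
    seq_a: str, seq_b: str, aligner: PairwiseAligner
) -> tuple[float, float, int]:
    """(score, ss, l) for the best local alignment of seq_a vs seq_b as given."""
    alignments = aligner.align(seq_a, seq_b)
    score = alignments.score
    if score <= 0:
        return score, 0.0, 0
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    columns = 0
    matches = 0
    run = 0
    longest = 0
    prev_a = prev_b = None
    for (a_start, a_end), (b_start, b_end) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            columns += (a_start - prev_a) + (b_start - prev_b)  # gap columns
            run = 0
        for x, y in zip(seq_a[a_start:a_end], seq_b[b_start:b_end]):
            columns += 1
            if x == y:
                matches += 1
                run += 1
                if run > longest:
                    longest = run
            else:
                run = 0
        prev_a, prev_b = a_end, b_end
    ss = matches / columns if columns else 0.0
    return score, ss, longest


def align_pair(
    seq_i: str,
    seq_y: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    min_score: float = 20.0,
) -> tuple[float, int]:
    """Return (ss, l) for the better orientation of the two sequences.

    (0.0, 0) when the best local score is below ``min_score``.
    """
    if not seq_i or not seq_y:
        raise ValueError("align_pair requires two non-empty sequences")
    a, b = (seq_i, seq_y) if seq_i <= seq_y else (seq_y, seq_i)
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    fwd = _align_oriented(a, b, aligner)
    rev = _align_oriented(a, reverse_complement(b), aligner)
    score, ss, longest = fwd if fwd[0] >= rev[0] else rev
    if score < min_score:
        return 0.0, 0
    return ss, longest


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    n = len(seq)
    kmers: set[str] = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        bwd = rc[n - k - i : n - i]
        kmers.add(fwd if fwd <= bwd else bwd)
    return kmers


def find_candidate_pairs(
    shared_mmr: Mapping[tuple[str, str], int],
    gene_sequences: Mapping[str, str],
    kmer_size: int = 15,
    min_shared_kmers: int = 3,
) -> set[tuple[str, str]]:
    """Gene pairs worth aligning: any shared-MMR pair, plus pairs sharing
    >= min_shared_kmers exact canonical k-mers.  Keys are sorted tuples."""
    pairs: set[tuple[str, str]] = {tuple(sorted(p)) for p in shared_mmr}

    index: dict[str, list[str]] = defaultdict(list)
    for gene_id, seq in gene_sequences.items():
        if len(seq) >= kmer_size:
            for kmer in _canonical_kmers(seq, kmer_size):
                index[kmer].append(gene_id)

    pair_counts: Counter[tuple[str, str]] = Counter()
    for genes in index.values():
        if len(genes) < 2:
            continue
        genes = sorted(genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                pair_counts[(genes[i], genes[j])] += 1
    pairs.update(p for p, c in pair_counts.items() if c >= min_shared_kmers)
    return {p for p in pairs if p[0] != p[1]}


def compute_D1(gene_i: str, hits: Iterable[SimilarityHit]) -> float:
    """D1 = max over partners of ss * l (0 with no hits)."""
    best = 0.0
    for hit in hits:
        if hit.gene_i != gene_i:
            raise ValueError(f"hit for {hit.gene_i!r} passed to compute_D1({gene_i!r})")
        if hit.product > best:
            best = hit.product
    return best


def significant_partners(
    hits: Iterable[SimilarityHit],
    min_identity: float = 0.8,
    min_match_len: int = 30,
) -> set[str]:
    """The set S of partner locations with significant sequence similarity."""
    return {
        h.gene_y
        for h in hits
        if h.product > 0 and h.ss >= min_identity and h.l >= min_match_len
    }
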