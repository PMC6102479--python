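"""Per-gene feature assembly: D1, D2, D3, the dependent variable D4,
and min-max normalization.

D2 is the largest fraction of a gene's assigned reads that are multi-mapping
reads shared with a single partner location.  D3 = log10(|S ∪ M| + 1) is the
gene's degree in the similarity / shared-MMR network (S: partners significant
by sequence similarity, M: partners sharing at least one MMR).  D4 — the
regression target — approximates the proportion of ambiguous reads: with
U_i ⊆ R_i ⊆ G_i (unique-only vs true vs all-matches read sets), the true
count is approximated by the midpoint (|G|+|U|)/2, giving
D4 = 1 − (|G|+|U|)/(2|G|) ∈ [0, 0.5].
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import GeneReadSets
from .io_formats import GeneModel

__all__ = [
    "compute_D2",
    "compute_D3",
    "compute_D4",
    "min_max_normalize",
    "mmr_partners",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ("gene_id", "D1", "D2", "D3", "G_size", "U_size")


def compute_D2(
    gene_id: str,
    G_size: int,
    shared: Mapping[tuple[str, str], int],
) -> float:
    """Maximum shared-MMR fraction |G_i ∩ G_y|_MMR / |G_i| over partners y."""
    if G_size <= 0:
        return 0.0
    best = 0
    for (a, b), count in shared.items():
        if gene_id in (a, b) and count > best:
            best = count
    return min(best / G_size, 1.0)


def compute_D3(S: Iterable[str], M: Iterable[str]) -> float:
    """Network degree feature log10(|S ∪ M| + 1)."""
    return math.log10(len(set(S) | set(M)) + 1)


def compute_D4(G_size: int, U_size: int) -> float:
    """Approximate ambiguous-read proportion 1 − (|G|+|U|) / (2|G|)."""
    if G_size < 1:
        raise ValueError("D4 is undefined for a gene with no assigned reads")
    if not 0 <= U_size <= G_size:
        raise ValueError(f"need 0 <= U_size <= G_size, got U={U_size} G={G_size}")
    return 1.0 - (G_size + U_size) / (2.0 * G_size)


def min_max_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """(x − min) / (max − min); an all-equal vector maps to all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def mmr_partners(
    gene_id: str, shared: Mapping[tuple[str, str], int]
) -> set[str]:
    """The set M: partner locations sharing at least one MMR with gene_id."""
    partners: set[str] = set()
    for (a, b), count in shared.items():
        if count > 0:
            if a == gene_id:
                partners.add(b)
            elif b == gene_id:
                partners.add(a)
    return partners


def build_feature_table(
    genes: Sequence[GeneModel],
    read_sets: Sequence[GeneReadSets],
    shared: Mapping[tuple[str, str], int],
    d1_by_gene: Mapping[str, float],
    similarity_partners: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Assemble the public per-gene feature table (columns FEATURE_COLUMNS).

    ``similarity_partners`` maps gene_id -> S (significant similarity set);
    M is derived from ``shared``.  Gene order follows ``genes``.
    """
    by_id = {rs.gene_id: rs for rs in read_sets}
    rows = []
    for gene in genes:
        rs = by_id.get(gene.gene_id)
        g_size = len(rs.G) if rs else 0
        u_size = len(rs.U) if rs else 0
        S = similarity_partners.get(gene.gene_id, set())
        M = mmr_partners(gene.gene_id, shared)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "D1": float(d1_by_gene.get(gene.gene_id, 0.0)),
                "D2": compute_D2(gene.gene_id, g_size, shared),
                "D3": compute_D3(S, M),
                "G_size": g_size,
                "U_size": u_size,
            }
        )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
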