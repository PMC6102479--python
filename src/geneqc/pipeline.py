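"""End-to-end orchestration: extract features -> fit D-score model ->
categorize -> write the report and a JSON sidecar of fit diagnostics.

The pipeline has a stable intermediate interface, the feature TSV
(columns gene_id, D1, D2, D3, G_size, U_size): ``extract_features`` produces
it from SAM + FASTA + GFF3, ``model_features`` consumes it.  ``run_pipeline``
composes the two in memory, so extract-then-model is bit-identical to a
single run.

Genes with no assigned reads have an undefined dependent variable; they are
reported with zero features, category Low and alternative likelihood 0, and
excluded from model fitting.  D-scores of exactly 0 are excluded from the
mixture fit (a point mass degenerates EM) and deterministically categorized
Low; their s_d is still evaluated under the fitted model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment, categorize, dscore, features, io_formats, mixture, similarity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SchemaError", "extract_features", "model_features", "run_pipeline"]


class SchemaError(ValueError):
    """A feature TSV is missing or mistypes a required column."""


@dataclass
class RunConfig:
    """All pipeline knobs with their documented defaults."""

    sam: str = ""
    fasta: str = ""
    gff: str = ""
    out: str = "geneqc_report.tsv"
    feature_types: tuple[str, ...] = ("gene",)
    min_overlap_bp: int = 1
    # similarity thresholds
    min_score: float = 20.0
    min_identity: float = 0.8
    min_match_len: int = 30
    kmer_size: int = 15
    min_shared_kmers: int = 3
    # regression
    alpha: float = 0.5  # L2 fraction of the penalty
    n_folds: int = 5
    # mixture / categorization
    k: int = 3
    families: tuple[str, ...] = ("gaussian", "gamma")
    restarts: int = 10
    grid_points: int = 10_000
    bic_mode: str = "standard"
    cutoff_density: str = "unweighted"
    seed: int = 1


def extract_features(config: RunConfig) -> pd.DataFrame:
    """SAM + FASTA + GFF3 -> per-gene feature table (FEATURE_COLUMNS)."""
    genome = io_formats.read_fasta(config.fasta)
    genes = io_formats.read_gff_genes(config.gff, config.feature_types)
    logger.info("annotation: %d genes on %d contig(s)", len(genes), len(genome))

    records = [
        r
        for r in io_formats.stream_sam_alignments(config.sam)
        if not r.is_unmapped
    ]
    multiplicity = assignment.classify_reads(records)
    n_mmr = sum(1 for m in multiplicity.values() if m.is_mmr)
    logger.info(
        "alignments: %d records, %d units (%d multi-mapping)",
        len(records), len(multiplicity), n_mmr,
    )

    read_sets = assignment.assign_reads_to_genes(
        records, genes, multiplicity, config.min_overlap_bp
    )
    shared = assignment.shared_mmr_counts(read_sets, multiplicity)

    gene_seqs: dict[str, str] = {}
    for gene in genes:
        contig = genome.get(gene.contig)
        if contig is None:
            logger.warning("gene %s on unknown contig %s", gene.gene_id, gene.contig)
            continue
        s0, e0 = gene.span0
        gene_seqs[gene.gene_id] = contig.sequence[s0:e0]

    pairs = similarity.find_candidate_pairs(
        shared, gene_seqs, config.kmer_size, config.min_shared_kmers
    )
    logger.info("similarity: %d candidate pairs", len(pairs))
    hits_by_gene: dict[str, list[similarity.SimilarityHit]] = {}
    for a, b in sorted(pairs):
        if a not in gene_seqs or b not in gene_seqs:
            continue
        ss, l = similarity.align_pair(
            gene_seqs[a], gene_seqs[b], min_score=config.min_score
        )
        if ss * l > 0:
            hits_by_gene.setdefault(a, []).append(similarity.SimilarityHit(a, b, ss, l))
            hits_by_gene.setdefault(b, []).append(similarity.SimilarityHit(b, a, ss, l))

    d1_by_gene = {
        g: similarity.compute_D1(g, hits) for g, hits in hits_by_gene.items()
    }
    s_sets = {
        g: similarity.significant_partners(
            hits, config.min_identity, config.min_match_len
        )
        for g, hits in hits_by_gene.items()
    }
    return features.build_feature_table(genes, read_sets, shared, d1_by_gene, s_sets)


def _check_schema(feat: pd.DataFrame) -> None:
    for col in features.FEATURE_COLUMNS:
        if col not in feat.columns:
            raise SchemaError(f"feature table is missing column {col!r}")
    for col in ("D1", "D2", "D3", "G_size", "U_size"):
        if not np.issubdtype(np.asarray(feat[col]).dtype, np.number):
            raise SchemaError(f"feature column {col!r} is not numeric")


def model_features(
    feat: pd.DataFrame, config: RunConfig
) -> tuple[list[io_formats.ReportRow], dict]:
    """Feature table -> report rows + JSON-ready sidecar of diagnostics."""
    _check_schema(feat)
    feat = feat.reset_index(drop=True)
    modeled = feat["G_size"] >= 1
    sub = feat[modeled]
    if len(sub) < 3:
        raise ValueError("need at least 3 genes with assigned reads to fit the model")

    y = np.array(
        [features.compute_D4(g, u) for g, u in zip(sub["G_size"], sub["U_size"])]
    )
    Xn = np.column_stack(
        [features.min_max_normalize(sub[c].to_numpy(dtype=float)) for c in ("D1", "D2", "D3")]
    )

    lam = dscore.select_lambda(Xn, y, config.alpha, config.n_folds, config.seed)
    model = dscore.fit_elastic_net(
        Xn, y, config.alpha, lam, feature_names=("D1", "D2", "D3")
    )
    model.cv_folds, model.cv_seed = config.n_folds, config.seed
    scores = dscore.predict_dscores(model, Xn)
    logger.info(
        "elastic net: lambda=%.6g, coefficients=%s", lam, model.coefficients.tolist()
    )

    nonzero = scores[scores > 0]
    k = config.k
    if nonzero.size:
        k = min(k, int(np.unique(nonzero).size), max(nonzero.size, 1))
    k = max(k, 1)
    best = None
    candidates: list[mixture.MixtureModel] = []
    while k >= 1 and best is None:
        try:
            if nonzero.size == 0:
                break
            best, candidates = mixture.fit_mixture(
                nonzero,
                k=k,
                families=tuple(config.families),
                seed=config.seed,
                restarts=config.restarts,
            )
        except (mixture.DegenerateSampleError, mixture.MixtureFitError):
            k -= 1
    if config.bic_mode != "standard" and candidates:
        for cand in candidates:  # re-rank under the audit formula
            cand.bic = mixture.bic(cand, config.bic_mode)
        best = mixture.select_best(candidates)

    weighted = config.cutoff_density == "weighted"
    cutoffs = None
    if best is not None and best.k >= 2:
        cutoffs = categorize.cutoffs_for(best, config.grid_points, weighted)
    if best is not None:
        logger.info(
            "mixture: family=%s k=%d bic=%.3f cutoffs=%s",
            best.family, best.k, best.bic,
            None if cutoffs is None else list(cutoffs.values),
        )

    score_by_pos = dict(zip(sub.index, scores))
    rows: list[io_formats.ReportRow] = []
    counts = {"Low": 0, "Medium": 0, "High": 0}
    for idx, row in feat.iterrows():
        if idx not in score_by_pos:  # no assigned reads
            category, d, s_d = "Low", 0.0, 0.0
        else:
            d = float(score_by_pos[idx])
            if best is None:
                category, s_d = "Low", 0.0
            elif d == 0.0 or cutoffs is None:
                # zero scores are deterministically Low; a single-component
                # model puts everything in the lone (Low) component
                category = "Low"
                s_d = categorize.alternative_likelihood(d, 1, best)
            else:
                comp = categorize.component_index(d, cutoffs)
                category = categorize.assign_category(d, cutoffs)
                s_d = categorize.alternative_likelihood(d, comp, best)
        counts[category] += 1
        rows.append(
            io_formats.ReportRow(
                gene_id=str(row["gene_id"]),
                d1=float(row["D1"]),
                d2=float(row["D2"]),
                d3=float(row["D3"]),
                d_score=d,
                category=category,
                alt_likelihood=s_d,
            )
        )

    sidecar = {
        "seed": config.seed,
        "alpha": config.alpha,
        "lambda_total": lam,
        "coefficients": {
            "intercept": model.intercept,
            **{n: float(c) for n, c in zip(model.feature_names, model.coefficients)},
        },
        "n_genes": int(len(feat)),
        "n_modeled": int(modeled.sum()),
        "n_mixture_sample": int(nonzero.size),
        "mixture": None
        if best is None
        else {
            "family": best.family,
            "k": best.k,
            "weights": best.weights.tolist(),
            "params": [list(p) for p in best.params],
            "loglik": best.loglik,
            "bic": best.bic,
            "converged": best.converged,
            "candidates": [
                {"family": c.family, "k": c.k, "bic": c.bic} for c in candidates
            ],
        },
        "cutoffs": None if cutoffs is None else list(cutoffs.values),
        "category_counts": counts,
    }
    return rows, sidecar


def run_pipeline(config: RunConfig) -> dict:
    """Full run: extract -> model -> write report TSV + sidecar JSON.

    Returns the sidecar dict.  On any stage failure, partially written
    outputs are removed before the error propagates.
    """
    out = Path(config.out)
    sidecar_path = out.with_suffix(out.suffix + ".json")
    try:
        feat = extract_features(config)
        rows, sidecar = model_features(feat, config)
        io_formats.write_report(rows, out)
        with open(sidecar_path, "w") as handle:
            json.dump(sidecar, handle, indent=2, sort_keys=True, default=float)
            handle.write("\n")
    except Exception:
        for path in (out, sidecar_path):
            Path(path).unlink(missing_ok=True)
        raise
    logger.info("report written to %s (%d genes)", out, len(rows))
    return sidecar
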