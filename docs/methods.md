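# Methods

This note documents the statistical procedure implemented by `geneqc`, the
choices made where the design was genuinely open, and what the bundled
synthetic data does and does not establish.

## Problem and model

After spliced alignment of an RNA-Seq library, a read that fits two or more
genomic locations with tied best scores (a multi-mapping read, MMR) cannot be
attributed to a single gene. Genes inside duplicated or repetitive regions
therefore carry expression estimates of unknown reliability. `geneqc`
quantifies that unreliability per gene with a continuous D-score and a
discrete Low/Medium/High category.

The model is a two-stage construction:

1. **Regression stage.** The proportion of ambiguous reads per gene is not
   observable, but it is bracketed: with U ⊆ R ⊆ G (unique-only, true, and
   all-matches read sets), the midpoint approximation R̂ = (|G|+|U|)/2 yields
   the dependent variable D4 = 1 − R̂/|G| ∈ [0, 0.5]. D4 is regressed on
   three min-max-normalized covariates capturing *why* reads are ambiguous:
   local sequence similarity to the nearest partner (D1), the largest shared-
   MMR fraction with a single partner (D2), and the log-scaled degree of the
   gene in the similarity/shared-MMR network (D3). The regression is an
   elastic net; its fitted value, floored at zero, is the D-score. Fitting to
   the midpoint rather than either extreme means a D-score reads as an
   expected ambiguous-read proportion, with 0.5 the structural ceiling
   (attained when a gene has no uniquely mapping read at all).

2. **Categorization stage.** Across a dataset, D-scores empirically cluster
   into reliability regimes. The non-zero scores are fitted with k-component
   mixtures (default k = 3) of Gaussians and of Gammas; EM is initialized by
   one-dimensional k-means with randomized initial grouping, and the family
   with the lower BIC is kept. Category boundaries are the intersections of
   adjacent *unweighted* component densities; each gene also receives an
   alternative likelihood s_d = max{1 − F_{i−1}(d), F_{i+1}(d)}, the largest
   tail probability with which a neighboring component claims its score.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.5 | L2 fraction of the elastic-net penalty: λ2 = αλ, λ1 = (1−α)λ. **Reversed relative to glmnet/sklearn's `l1_ratio`** — α = 1 is ridge, α = 0 lasso. 0.5 balances selection against the strong D1–D3 collinearity. |
| λ (`lambda_total`) | CV-selected | Seeded 5-fold CV over a 50-point log grid spanning 4 decades down from λ_max (the smallest λ zeroing all coefficients). Ties resolve toward the larger λ. |
| `min_score` | 20 | Local-alignment score (match +1, mismatch −1, gap open −2, extend −1) below which a gene pair is treated as unrelated. ≈20 bp of exact match; random 50-mers stay well below it. |
| `min_identity`, `min_match_len` | 0.8, 30 bp | Gate for the *significant* similarity set S feeding D3. Without a gate, any positive local hit would make S near-total and D3 uninformative. |
| `kmer_size`, `min_shared_kmers` | 15, 3 | Candidate-pair screen (canonical k-mers, both strands). Two random 1 kb sequences share ≈0 15-mers, so the screen admits only plausibly homologous pairs plus any pair already sharing an MMR. |
| `min_overlap_bp` | 1 | Reference-consuming CIGAR blocks (M/=/X/D) must overlap a gene's span by at least this much; splice gaps (N) never count as overlap. |
| `k` | 3 | Number of uncertainty regimes. Reduced automatically when the non-zero D-score sample has too few distinct values to support it. |
| `restarts` | 10 | k-means restarts; best within-cluster sum of squares wins. |
| `grid_points` | 10 000 | Grid resolution for Gamma density intersections (between adjacent component modes). |
| `bic_mode` | `standard` | p·ln(n) − 2·L̂ with p = 3k − 1 free parameters, minimized. A literal variant −2k·ln(n) − 2·L̂ is kept for auditing only; it decreases with both k and fit and cannot drive selection. |
| `cutoff_density` | `unweighted` | Intersections of unweighted component densities. The mixture-weighted variant is available; it shifts each cutoff toward the lighter component. |
| `seed` | 1 | Drives k-means restarts, CV folds and every simulator. Same seed ⇒ byte-identical outputs. |

## Numerical choices

- **Multiplicity precedence**: NH tag (max, with a warning, on conflict) >
  count of records tying at the maximal AS > raw record count. Secondary
  alignments (0x100) count toward multiplicity; supplementary (0x800) are
  ignored. Paired mates are separate countable units (`read/1`, `read/2`).
- **Coordinates**: GFF3/SAM stay 1-based inclusive at the parsing boundary
  and are converted exactly once to 0-based half-open spans for all interval
  arithmetic.
- **Local alignment**: Biopython's `PairwiseAligner` in local mode. The pair
  of sequences is canonicalized (lexicographic sort) before aligning so the
  result is exactly symmetric under argument order even when co-optimal
  alignments exist; both orientations (partner as given and
  reverse-complemented) are tried and the higher-scoring one kept.
- **Elastic net**: scikit-learn coordinate descent behind the module
  surface, with the exact parameter translation a·l1 = λ1/(2n),
  a·(1−l1) = λ2/n; λ = 0 is solved directly by least squares. Unit tests pin
  the three closed-form limits (OLS, soft-thresholding on an orthonormal
  design, ridge).
- **Gaussian EM**: biased (N_k-denominator) variance estimates, variance
  floor 1e-10, convergence at relative log-likelihood change < 1e-6 (max 500
  iterations), components with weight < 1/(10n) pruned with a warning,
  components reported sorted by mean.
- **Gamma EM**: M step by responsibility-weighted method of moments
  (shape = m²/v, scale = v/m) instead of digamma Newton iterations — robust
  on near-zero D-scores, at the cost of the likelihood being monotone only
  to ~1e-6 (an overshooting step reverts to the previous state). The fit
  requires strictly positive data; the pipeline clips the sample at 1e-6 for
  the Gamma candidate only.
- **Degenerate samples**: D-scores equal to 0 form a point mass that breaks
  EM; they are excluded from fitting and deterministically categorized Low
  (their s_d is still evaluated under the fitted model). If the remaining
  sample has fewer distinct values than k, k is reduced (k = 2 → Low/High,
  k = 1 → all Low).
- **Cutoff roots**: the Gaussian intersection quadratic is solved in closed
  form and the root inside (μ_i, μ_{i+1}) kept; equal variances reduce to the
  linear (midpoint) case. If no root lies in the interval, a grid search for
  the equal-density point is used with a warning. A score exactly at a cutoff
  goes to the upper category (left-closed intervals).
- **Genes with no assigned reads** have an undefined D4; they are reported
  with zero features, category Low and s_d = 0, and excluded from fitting.

## Synthetic data: what it emulates and what it does not

`geneqc.simulate` generates single-contig genomes of random genes with 200 bp
spacers, duplicating a configurable fraction of genes at a configurable
per-base divergence (defaults: 200 genes × 500 bp, 30% duplicated, 2%
divergence, 75 bp reads at 20× depth). Reads are error-free and drawn
uniformly from gene bodies; a read's multiplicity is *defined* as its number
of exact occurrences in the genome (either strand) and recorded in NH, so the
MMR ground truth is exact. The 2% default divergence mimics recent paralogs
and produces a continuum of shared-MMR fractions and D4 values; divergence 0
produces the fully degenerate exact-duplication regime, which the pipeline
must (and does) survive via the k-reduction fallback.

What the simulator deliberately omits: sequencing errors, indels and splicing
(reads are contiguous genome substrings), non-uniform coverage, fragment-level
paired-end structure, and aligner-specific scoring artifacts. Passing tests
on this data therefore demonstrate the correctness of the feature algebra,
the regression/mixture machinery and the end-to-end ranking behavior
(duplicated genes out-score singletons; singletons land in Low) — not
calibration of absolute D-scores on real libraries, which depends on the
aligner and genome at hand.

Problem sizes used in tests and in the acceptance script — 200 genes at 20×
depth end-to-end, n = 10 000 for mixture parameter-recovery benchmarks, 100
parameter draws for the cutoff closed-form check, |G| ≤ 1000 for the
exhaustive D4 ceiling — were chosen as the smallest instances at which the
checked statistical properties are stable.

## Known limitations

- Gene assignment uses the annotated genomic span, not exon structure; reads
  in introns of a spanned gene are counted for it.
- D1 is computed between annotated gene sequences only; similarity to
  unannotated repeats is invisible to D1 (though it still surfaces in D2/D3
  through shared MMRs if reads multi-map there — and such alignments on
  contigs absent from the annotation are skipped with a counter).
- The Gamma M step is a moment approximation; with heavily overlapping
  skewed components its parameter estimates are less efficient than full MLE.
- λ selection minimizes mean CV error on a fixed 50-point grid; on
  pure-noise data the argmin can sit a few grid steps below λ_max (chance
  fold-level overfitting), which only strengthens shrinkage-adjacent fits.
- The alternative likelihood is a tail probability of *unweighted* neighbor
  components, matching the cutoff convention; it is a confidence heuristic,
  not a calibrated posterior probability.
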