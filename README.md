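# geneqc

Per-gene **mapping-uncertainty scoring** for RNA-Seq alignments.

When reads are mapped to a reference genome, duplicated or highly similar
genomic regions produce *multi-mapping reads* (MMRs): reads whose alignments
tie at the best score across two or more locations. Expression estimates for
the affected genes are unreliable in a way that read-level QC (FastQC-style)
cannot detect, because the problem arises *after* alignment. `geneqc` sits
between the aligner and quantification: it scores every annotated gene for
mapping uncertainty and flags the genes whose expression values should not be
trusted downstream (differential expression, enrichment, networks).

## Method

For each annotated gene *i* (any genomic region — gene, transcript or exon),
three features are extracted from the SAM/FASTA/GFF3 inputs:

- **D1** = max<sub>y</sub> { ss<sub>i,y</sub> · l<sub>i,y</sub> } — sequence
  similarity to the closest partner location, where *ss* is the identity
  fraction of the best local alignment and *l* the longest run of
  consecutively matching bases;
- **D2** = max<sub>y</sub> |G<sub>i</sub> ∩ G<sub>y</sub>|<sub>MMR</sub> / |G<sub>i</sub>| —
  the largest fraction of the gene's assigned reads that are MMRs shared
  with a single partner, with G<sub>i</sub> the set of reads assigned to gene *i*;
- **D3** = log₁₀(|S ∪ M| + 1) — the gene's degree in the
  similarity/shared-MMR network (S: significant-similarity partners,
  M: shared-MMR partners).

A dependent variable bounds the truth between the two classical extremes of
MMR handling (unique-only U<sub>i</sub> vs all-matches G<sub>i</sub>):

    D4 = 1 − (|G_i| + |U_i|) / (2 |G_i|)   ∈ [0, 0.5]

D4 is regressed on min-max-normalized (D1, D2, D3) with an **elastic net**

    L(λ1, λ2, β) = ‖y − Xβ‖² + λ2 ‖β‖² + λ1 ‖β‖₁,

with mixing α = λ2/(λ1+λ2) = 0.5 by default (note: **α is the L2 fraction**;
α = 1 is ridge, α = 0 is the lasso) and λ chosen by seeded 5-fold
cross-validation. The fitted value, floored at 0, is the gene's **D-score**:
higher means less reliable expression estimation.

The D-score sample is then fitted with 3-component **Gaussian and Gamma
mixtures** (k-means initialization with randomized grouping, then EM); the
family with the lower BIC wins. Category boundaries are the intersections of
adjacent component densities (closed-form quadratic for Gaussians, grid
estimation for Gammas), giving **Low / Medium / High** uncertainty classes,
each gene annotated with an **alternative likelihood**
s<sub>d</sub> = max{1 − F<sub>i−1</sub>(d), F<sub>i+1</sub>(d)} — the
strongest claim a neighboring category can make on that gene's score.

## Worked example

No external data is needed — the package ships a simulator that generates a
toy genome with duplicated genes, a GFF3 annotation and a SAM alignment with
ground-truth multiplicity in NH tags:

```sh
geneqc simulate --outdir demo --seed 5
# simulated 260 genes (60 duplicate pairs) into demo
geneqc run --sam demo/reads.sam --genome demo/genome.fasta \
           --gff demo/genes.gff3 --out demo/report.tsv --seed 1 --quiet
# {"Low": 140, "Medium": 44, "High": 76}
```

`demo/report.tsv` (one row per annotated gene):

```text
Gene ID     D1      D2        D3       D-score   Category  Alternative likelihood
gene0001    0       0         0        0.000004  Low       0.079372
gene0004    104.976 0.124138  0.30103  0.062156  Medium    0.010698
gene0008    193.83  0.550802  0.30103  0.275349  High      0.000006
```

- `gene0001` has no similar partner and no shared MMRs: D-score ≈ 0,
  its expression estimate is safe to use.
- `gene0008` shares 55% of its reads with a diverged duplicate
  (D2 = 0.55) and carries a strong local-similarity hit (D1 ≈ 194 —
  identity × match length): its D-score 0.275 lands above the second
  density-intersection cutoff, so its expression estimate is flagged High
  uncertainty. The alternative likelihood 6·10⁻⁶ says this High call is
  essentially unambiguous.
- The JSON sidecar `demo/report.tsv.json` records the fitted coefficients
  (here D2 dominates: β̂ = (0.0004, 0.356, 0)), the selected mixture
  (Gaussian, k = 3), the cutoffs (4.7·10⁻⁵, 0.133) and the category tally.

The same pipeline runs in two stages — `geneqc extract` writes a feature TSV
(`gene_id, D1, D2, D3, G_size, U_size`), `geneqc model` consumes it — and
composes bit-identically with `geneqc run`.

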