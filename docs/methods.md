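# Methods

This note documents the statistical procedures implemented in `sctme`, the
choices made where a procedure is conventionally under-specified, what the
synthetic generators do and do not emulate, and the problem sizes used by
the shipped tests and the acceptance script.

## Data model and conventions

Counts are cells × genes, sparse, non-negative integers. Genomic
coordinates are 0-based half-open everywhere (cytobands, CNV windows). Gene
identity is the case-sensitive symbol string. Group labels form a closed
vocabulary (`MPLC_Tumour`, `MPLC_Normal`, `SPLC_Tumour`, `SPLC_Normal`)
validated at load; readers reject invariant violations (duplicate barcodes,
non-integral counts, malformed bands) rather than repairing them.

## Quality control

Per cell: `n_genes` (genes with count > 0), `n_umi`, `pct_mito`
(percentage of counts on genes with the configurable prefix `MT-`; 0 for an
empty cell). Default thresholds: keep iff 200 ≤ n_genes ≤ 5000,
n_umi ≤ 30 000, pct_mito ≤ 30. The removal phrases behind these defaults
("fewer than 200", "exceeding 30 000", "over 30%") are read strictly, so a
cell sitting exactly on a bound survives; whether the original analysis was
inclusive at the bounds is unknowable from the description, and the strict
reading is documented here as the package's convention.

Normalization is `ln(1 + s·x/n_umi)` with `s = 10 000`; it is invariant to
rescaling a cell's library depth. Cell-cycle (or any nuisance) correction is
implemented as per-gene least-squares regression on user-supplied covariates
with gene means restored — typically module scores of S and G2M gene sets
computed by `module_score`. Regressing scores rather than deleting genes is
an interpretation choice: "regressing out cell cycle" can also mean removing
the genes, but score regression preserves the gene universe and matches the
dominant toolchain convention.

## Marker statistics

For in-group vs out-group on a single gene: `AUC = U/(n₁n₂)` with ties
counted half, identical to the Wilcoxon rank-sum statistic. p-values use the
tie-corrected normal approximation without continuity correction; when
`n₁+n₂ ≤ 12` the exact two-sided p is computed by enumerating all label
assignments and counting |U − n₁n₂/2| at least as extreme.
`log2FC = log2((mean(expm1(norm_in)) + 1)/(mean(expm1(norm_out)) + 1))`:
means are taken on the back-transformed normalized scale with a +1
stabilizer, the convention of the standard single-cell toolchain; it is
documented here because "log fold change" alone does not pin it down.

`find_all_markers` Bonferroni-adjusts per cluster over the genes tested and
retains genes with `pct_in ≥ 0.25`, adjusted p < 0.05 and log2FC > 0.25.
"Expressed" always means raw count > 0 (pct_in/pct_out, quadrant
classification, ligand/receptor fractions).

Cluster annotation scores each candidate type as the mean normalized
expression of its reference markers over the cluster's cells and takes the
argmax. Manual annotation from marker plots is not an algorithm; this scoring
rule is the package's reproducible surrogate, and calls whose top two scores
are within 10% (relative) are flagged ambiguous rather than silently
assigned. Ties break lexicographically for determinism.

Signature extraction takes the top n = 10 retained markers by descending
log2FC, ties broken by smaller p then gene id.

## Cluster × group preference

For each (cluster i, group j): a = cells in both, b = in i only, c = in j
only, d = neither. The odds ratio is the cross-product ratio `ad/bc`; when
any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe) before
forming the ratio — the conditional-MLE estimate is a known alternative but
the sample OR is what the upstream toolchain reports. The p-value is the
two-sided Fisher exact probability (hypergeometric mass of tables at most
as probable as observed, with 1e-7 relative tolerance on probability ties,
matching the scipy implementation used). BH adjustment pools all
cluster × group combinations into one family; a per-group family would also
be defensible, but pooling is the stricter and simpler reading. Labels:
enriched iff adjusted p < .01 and OR > 1.5; depleted iff adjusted p < .01
and OR < 0.5.

Cells are the counting unit. Because cells from one sample are not
independent, `or_preference_matrix(by="samples")` offers a
pseudo-replication-aware variant that counts each sample at most once per
cluster.

## CNV scoring and clonality

CNV input is a cells × windows matrix of copy-neutral-centered residuals (0
= diploid). `estimate_cnv_residuals` provides a deliberately simple
estimate from normalized expression — reference-mean centering, clipping at
±3 SD (SD over all cells: a near-noiseless reference would otherwise clip a
genuine aberration to nothing), block moving average over
`window_size_genes` genes in genomic order, per-cell median re-centering.
It is smoothing plumbing, not a hidden-Markov CNV caller, and is not used
by the recovery tests, which consume generator residuals directly.

Per-cell score = Σ residual² over windows ("departure-from-diploid
energy"); whether the original quadratic sum ran over genes or windows is
not decidable from its description — windows are used, and the score is
invariant to window permutation either way. Malignant iff score >
reference mean + 2 × reference sample SD (ddof = 1). The intended reference
population is T/NK cells from para-tumour tissue (subsampled, fixed seed)
when real data are used; the generators emit explicit reference cells.

Arm events: each window is assigned to the p or q arm containing the
majority of its span; an arm is gained when its mean residual exceeds +0.3
and lost below −0.3. The cutoffs are configurable defaults — no published
numeric cutoff exists for this step — and sit at 30% of the generator's
unit effect size. Cells with identical event sets collapse into subclones
(fractions over all cells considered). The clonal tree attaches each
subclone to the node whose event set is the largest proper subset of its
own (ties: larger cell fraction, then lexicographically smallest label);
incomparable sets attach to the diploid root. This maximal-subset rule is a
reconstruction of what clonal-tree renderers consume; only the renderer,
not the rule, is named in the source description. Newick serialization uses
cell fraction as branch length and labels like `5q+|7-` (a chromosome whose
p and q arms share a direction collapses to `7+`).

## Preranked GSEA

Ranking metric: AUC − 0.5, descending (signed so 0 = uninformative).
Enrichment score: weighted KS running sum with weight p = 1 — hits add
`|metric|/Σ_hits|metric|`, misses subtract `1/(N − N_hits)`; ES is the
extremum of the walk; when the positive and negative extremes tie in
magnitude (within 1e-12) the positive one is taken, so the sign is
deterministic on symmetric inputs. Null distributions use gene-set
permutation (random same-size sets from the ranked universe) — appropriate
because the input is a preranked list, where phenotype permutation is
unavailable. NES divides ES by the mean |null ES| of matching sign; p is
the same-sign null tail fraction; FDR is the standard per-sign
ratio-of-tails estimator on pooled null NES, capped at 1. The quantities
(ES, NES, FDR) are named by the source method; the estimator details follow
the original GSEA convention since no alternative is specified.

## Ligand–receptor interactions

Communication probability = `LR/(0.5 + LR)` where L is the 25%-per-tail
trimmed mean of ligand normalized expression over senders and R the
geometric mean over receptor subunits of their trimmed means over receivers
(any zero subunit gives R = 0). This Hill-saturated score is a documented
simplified surrogate for dedicated interaction tools whose internals are
out of scope; the *retention criteria* are implemented verbatim: ligand and
receptor expressed (count > 0) in > 10% of sender and receiver cells,
ligand log2FC (sender vs all other cells, marker-module formula) > 0.1,
BH-adjusted permutation p < .05. The permutation null shuffles cluster
labels among the union of sender and receiver cells, all pairs seeing the
same shuffles; `p = (1 + #{null ≥ observed})/(1 + n_perm)`.

## Module scores, correlation, survival

Module score: genes are placed into 24 equal-frequency bins by mean
expression; each set gene contributes `n_ctrl = 100` control genes sampled
from its bin (with replacement when the bin is small); score = mean(set) −
mean(pooled controls) per cell. Spearman correlation is the Pearson
correlation of average ranks; p by t approximation, exact enumeration over
permutations for n ≤ 8.

Signature survival: per gene log2(x+1) (the +1 guards zeros; the original
transform is stated without a pseudocount), z-score across samples with
sample SD; score = mean z over signature genes; split at the median with
ties going low (a stated convention — the source is silent on ties). KM and
the log-rank test use lifelines; the univariate Cox model is fit in-package
by Newton–Raphson on the Breslow partial likelihood to |Δβ| < 1e-8
(Breslow chosen as the simplest consistent tie rule; lifelines' Efron fit
is used as an independent cross-check in tests on tie-free data, where the
two coincide). CI = exp(β ± 1.96·SE), p by Wald. Monotone likelihood
(complete separation) and non-convergence raise errors rather than
returning unstable estimates. The binary high/low split is the primary
covariate, matching "high and low expression groups"; the continuous score
can be passed directly.

Group comparisons reuse the Wilcoxon engine with stars `*`, `**`, `***` at
p < .05, .01, .001.

## Synthetic generators

All generators are pure functions of (config, seed); each derives an
independent substream from the global seed so stages never share random
state. Truth tables are returned beside the data, never embedded.

**Expression**: counts are negative binomial (gamma–Poisson) with per-gene
means log-normal (σ = 0.5) around `nb_mean = 0.5` UMI and dispersion 2 —
typical droplet-data sparsity and overdispersion. Cluster identity
multiplies marker-gene means by `2^shift`. Per-sample cluster counts are
multinomial from the group's composition row; the default study plants one
cluster at 30% in MPLC tumours vs 10% elsewhere (a 3× relative abundance,
the scale of the composition shifts the pipeline is meant to detect), 2000
cells per group (4 samples × 500). The first ten genes carry the `MT-`
prefix and are rescaled per cell to a target mitochondrial fraction
uniform on [2%, 10%]. Not emulated: gene–gene correlation, doublets, batch
effects — so passing recovery tests demonstrate statistical correctness of
each stage under its own model, not robustness to those artefacts. A
consequence of the log-normal gene means worth knowing: a planted marker
or ligand occasionally draws a very low baseline and is undetectable by
construction; stochastic recovery rates (e.g. ligand retention) reflect
this.

**CNV**: reference cells get Normal(0, noise_sd) residuals per window;
subclone cells add ±effect_size on every window of a gained/lost arm.
Defaults: effect 1.0, noise SD 0.1, 100-window arms — separations at which
the mean+2SD classifier should be near-perfect, per the normal tail bound.

**Survival**: latent group z ~ Bernoulli(1/2); event times exponential with
hazard `h₀·HR^z` (h₀ = 0.05/month, HR = 1.5 — a moderate, clinically
plausible effect); censoring times independent exponential with the rate
solved in closed form so the expected censored fraction equals
`censor_rate` (uniform-on-[0,T] censoring was rejected because it is
informative). Signature genes are `2^(5 + N(0,1) + 2z)` on the linear
scale, so the downstream log2/z-score pipeline sees a 2-SD group shift and
the median split recovers z almost perfectly at n = 1000.

## Problem sizes and tolerances

The shipped test suite runs in ~70 s on one CPU: the OR-recovery study uses
100 seeds × 8000 cells (metadata-scale genes, since the statistic consumes
only labels), the Fisher oracle enumerates all 135 750 tables with total
≤ 40 at 1e-7 relative tolerance, CNV recovery uses 20 seeds × 200 cells ×
200 windows, Cox recovery 50 cohorts of n = 1000, GSEA oracle all subsets
of rankings up to 10 genes plus the exhaustive C(8,2) null, and interaction
recovery 20 seeds × 400 cells. `scripts/acceptance.py` re-runs the same
computations (~1 min) and reports the measured values unmodified.

## Known limitations

- The annotation score and the communication probability are reproducible
  surrogates for procedures that were manual or tool-internal in the
  original setting; their retention/threshold logic is exact, their scores
  are not claimed to match any external tool numerically.
- `estimate_cnv_residuals` is a smoother, not an HMM; it will blur focal
  events smaller than a window and has no posterior state probabilities.
- Composition testing treats cells as independent; use `by="samples"` when
  pseudo-replication matters.
- The GSEA FDR is the ratio-of-tails estimator; it is conservative for
  small set collections and is not a multi-level exact p.
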