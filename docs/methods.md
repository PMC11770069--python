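# Methods

This note documents the models and procedures implemented in
`metastates`, the defaults chosen where the workflow leaves them open,
and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

Tumors and their microenvironment are mixtures of *cell states*:
recurrent transcriptional configurations within a cell type (for
example, a proliferative or a stem-like configuration of leukemic
blasts). Per-sample non-negative matrix factorization (NMF) can expose
such configurations as additive gene programs, but single-sample factors
are noisy and partly idiosyncratic. The workflow implemented here
discovers programs independently within each sample and then keeps only
those that recur — across factorization ranks within a sample and
across samples — before summarizing recurrent programs into
*meta-programs* interpreted as cell states. Downstream, the package
quantifies those states in bulk expression cohorts, tests their clinical
associations, detects co-existing ensembles of states across patients,
and distills a gene-level survival risk score from an ensemble's
signature genes.

## Discovery chain

### Normalization

Counts are converted to analytic Pearson residuals under a
negative-binomial noise model: the expected count is
`mu_gc = (gene total × cell total) / grand total` and the residual is
`r = (x − mu) / sqrt(mu + mu²/θ)` with fixed inverse-dispersion
`θ = 100`. Residuals are clipped at `sqrt(n_cells)` and negative values
are set to zero so the matrix is a valid NMF input. This reproduces the
residual structure of regularized-GLM normalizers without per-gene
regression fits; an externally normalized non-negative matrix is
accepted as-is. All-zero genes are dropped (they carry no information
and make the residual undefined); an all-zero cell is an error because
its library size is meaningless.

### Per-sample NMF

Each sample is factorized at every rank K in 3..8 (33 factors per
sample), minimizing squared Frobenius error by coordinate descent with
non-negative double-SVD initialization; optional seeded random restarts
keep the lowest-error solution. Solver parameters (`max_iter = 500`,
`tol = 1e−5`) are free choices — the contract is determinism given the
seed. Factors are ordered by total usage so program identifiers are
stable. Each factor becomes a *program*: the 50 genes with the largest
coefficients (ties broken lexicographically for reproducibility), the
full coefficient vector, and the per-cell usage row.

### Program quality control

Within one (sample, K) decomposition the K usages of each cell are
normalized to sum to one; a program's representativeness is the median
of its normalized usage across cells and its dynamic range is the
interquartile range (linear-interpolation quantiles, the common type-7
default). Programs whose median or IQR falls strictly below the 0.25
quantile of their (sample, K) cohort are removed. The quantile cutoffs
are relative rather than absolute so the rule is scale-free across
samples; both the quantiles and absolute-cutoff alternatives are
configurable.

### Robustness criteria

A program is retained when it (1) shares at least 35 of its 50 top
genes with a program from a different rank of the same sample, and
(2) shares at least 10 of 50 with a program from another sample.
(3) Within each sample the survivors are then made mutually distinct:
programs are visited in decreasing order of their criterion-(1) overlap
(ties by program id) and kept only if they share at most 10 genes with
every previously kept program of that sample. The greedy
strongest-first pass is a deterministic resolution of the distinctness
requirement that favours the most internally supported programs; its
output is invariant to input order.

### Meta-programs

Robust programs are clustered on the dissimilarity
`d = 1 − shared_genes/50` (a bounded, monotone transform of the
shared-gene similarity, needed because silhouette widths require a
dissimilarity). Linkage is Ward's criterion applied directly to the
dissimilarities with the squared-distance update — the convention of R's
`hclust(method = "ward.D2")`, which `scipy.cluster.hierarchy.linkage(method="ward")`
reproduces on a precomputed condensed distance matrix. The cluster
number is the maximizer of the mean silhouette width over k = 2..15
(ties to the smaller k; a manual override is available since silhouette
curves on real data can be flat). Each cluster's signature is the 50
genes with the largest average coefficient over member programs; member
coefficient vectors are normalized to unit sum before averaging
(configurable) so that samples with larger coefficient scales do not
dominate, and genes missing from a member contribute zero.

### Saturation analysis

Because decompositions are per-sample, downsampling re-runs only the QC
→ robustness → clustering stages on random sample subsets, recording the
meta-program count per (subset size, replicate). Subset sizes below two
are skipped — the inter-sample criterion is undefined.

## Cell scoring and abundances

Cells are scored against a signature as mean signature-gene expression
minus mean expression of bin-matched control genes: genes are split into
24 equal-frequency bins of average expression and, for each signature
gene, 100 control genes are drawn (seeded, with replacement) from the
*non-signature* genes of its bin. Excluding signature genes from the
control pool keeps the score an unbiased contrast of the signature
against its expression-matched background even when signature genes
dominate a bin; if a bin holds only signature genes the whole bin is
used, with a warning. Counts are log-normalized (counts per 10k, log1p)
before scoring — module scores conventionally operate on log scale —
while already-normalized layers are scored as given. Each cell is
assigned to its highest-scoring state (exact ties go to the
lexicographically first state and are flagged).

State abundance is compartment-relative: the fraction of a sample's
cells of the state's own cell type that are assigned to the state, so
fractions within a compartment sum to one. Samples need strictly more
than 15 cells in every required compartment to be retained; sparse
compartments can be exempted from the requirement.

## Bulk quantification and associations

ssGSEA follows the rank-weighted running-sum formulation: per sample,
genes are ranked by expression (average ranks for ties, walk order
stable by gene symbol), in-set genes step the running sum up by
`rank^0.25` normalized by the total in-set weight, out-of-set genes step
down uniformly, and the enrichment score is the integral (sum) of the
running sum. With `normalize=True` all scores are divided by the
max − min over the whole cohort matrix.

Associations use univariate Cox proportional hazards for survival
(scores z-scored per cohort first so statistics are comparable across
cohorts; Efron tie handling; positive z means higher score, higher
hazard), logistic regression for categorical variables (one-vs-rest
beyond two levels; perfect separation is flagged rather than silently
penalized) and ordinary least squares for continuous ones. Statistics
are reported as signed −log10 p. Cross-cohort evidence is pooled with
the weighted-z (Liptak) rule `Z = Σ w_i z_i / sqrt(Σ w_i²)` with
`w_i = 1/sqrt(n_i)`; note this *down-weights* larger cohorts — the
convention adopted by this workflow — and `weights="sqrt_n"` provides
the conventional alternative.

## Ecosystems

States are clustered on `1 − Spearman ρ` of their abundance profiles
across retained samples (rank correlation is robust to the scale
differences between compartments); the cluster number again maximizes
mean silhouette. Constant-abundance states have undefined correlation
and become singleton clusters with a warning. Co-existence is
independently validated by the Jaccard index over presence calls at
abundance > 0.5. An ecosystem's membership is automated as the cluster
containing a designated focal state plus that state itself — an
approximation of what is otherwise a manual, correlation-guided choice —
and its per-sample score is the geometric mean of member abundances
(pseudocount 1e−4 guards zero abundances). Samples strictly above the
median score are the high-ecosystem group.

## Risk signature

Candidate genes (the pooled ecosystem signature genes) are filtered by
stability selection: 1000 iterations, each dropping a seeded random 10%
of samples and fitting an L1-penalized Cox model on the rest, with the
penalty chosen per iteration by internal 10-fold cross-validated
held-out partial likelihood. The default penalty rule is the 1-SE rule
(strongest penalty within one standard error of the best held-out
likelihood): because leave-out-10% subsamples overlap pairwise by ~80%,
the minimum-deviance penalty admits large supports in which
chance-correlated null genes are re-selected in nearly every iteration,
defeating the purpose of the frequency filter; the parsimonious 1-SE
rule restores the intended behaviour while keeping strongly prognostic
genes at selection frequency ≈ 1. `penalty_rule="min"` gives the
minimum-deviance alternative. Genes selected in ≥ 900 of 1000 iterations
enter a bidirectional stepwise Cox regression minimizing AIC (the most
common stepwise convention), whose surviving genes and coefficients form
the risk model.

The risk score is the linear predictor `score_s = Σ_i Exp_is · β_i`.
Expression is z-scored per gene within a cohort by default so the
coefficients transfer across cohorts; a raw-scale mode applies the
formula literally. Samples strictly above the median score are
high-risk; the median is computed per cohort at application time.
Evaluation uses the two-group log-rank test, multivariate Cox
adjustment for clinical covariates (collinearity detected by pairwise
correlation > 0.999 and flagged, with a tiny ridge penalty to keep the
fit defined), and Harrell's concordance index with 0.5 credit for score
ties (higher score = higher risk, so a perfectly ordering score gives
C = 1).

## Synthetic data

`simulate_cells` draws negative-binomial baseline counts (dispersion
0.5, so variance = mu + 0.5·mu²) with per-gene lognormal mean levels and
per-cell lognormal library-size variation (CV 0.3) — realistic
overdispersion without any dataset downloads — and multiplies the means
of planted program genes by the effect size (default 5) in
program-active cells. By default the planted programs partition each
sample's cells (equal active fractions summing to one), mirroring the
workflow's assignment of every cell to a state; fractions summing to
less than one leave program-free cells. The default study conditions
are 20 samples × 300 cells × 500 genes with three disjoint 50-gene
programs shared by all samples.

`simulate_survival_cohort` draws standard-normal expression and
exponential event times with hazard `h0·exp(Σ β_g x_g)`; censoring times
are uniform on [0, c] with c calibrated by bisection on the drawn event
times so the observed censoring fraction approximates the target.

What the synthetic benchmarks show: that the chain recovers planted
recurrent programs, that the saturation count plateaus at the planted
truth, that cells are re-assigned to their generating program, and that
the selection/stepwise/score pipeline recovers planted prognostic genes
and separates held-out survival. What they do not show: robustness to
batch effects between platforms, to overlapping or hierarchical
programs, to compositional shifts between compartments, or to the much
weaker effect sizes of real tumors — real-data counts of states are not
reproduced here, and passing these benchmarks does not certify them.

## Problem sizes and numerical notes

The bundled benchmarks use 20 samples × 300 cells (discovery), a
68-sample miniature cohort (program bookkeeping), and survival cohorts
of 300 training + 150 held-out samples with 100 stability iterations —
sizes chosen so a full verification run completes on a laptop while
preserving every structural property being tested. Degenerate inputs
are errors, not silent results: all-zero usage vectors are flagged,
all-identical programs make the clustering distance degenerate, constant
scores cannot be split at a median, and an empty QC result advises
relaxing thresholds. All stochastic steps (NMF restarts, control-gene
draws, subsampling, fold assignment, simulation) consume explicit seeds.
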