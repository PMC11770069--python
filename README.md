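# metastates

Discovery of recurrent transcriptional **cell states** across many
single-cell RNA-seq samples, and their translation into bulk-cohort
clinical analyses: state quantification by ssGSEA, survival and clinical
associations with cross-cohort z-combination, detection of co-existing
cell-state **ecosystems**, and an ecosystem-derived prognostic **risk
signature**.

The package is aimed at computational biologists studying intratumor
heterogeneity — the motivating system is acute myeloid leukemia, where
both leukemic blasts and immune cells occupy recurrent transcriptional
configurations that carry prognostic information — but nothing in the
implementation is tissue-specific.

## The model

**Cell states.** For each sample *s*, the gene × cell matrix of clamped
Pearson residuals is factorized by NMF at every rank K ∈ {3, …, 8}:

    X_s ≈ W H,   W ≥ 0 (gene × K),  H ≥ 0 (K × cell)

Each factor (a *program*) is summarized by its top-50 coefficient
genes. Programs survive only if they recur: ≥ 35/50 genes shared with a
program at another rank of the same sample, ≥ 10/50 shared with a
program of another sample, and ≤ 10/50 shared with any other retained
program of the same sample. Survivors are clustered (Ward linkage,
ward.D2 convention, on d = 1 − shared/50; cluster number by maximal mean
silhouette) and each cluster becomes a *meta-program*: the 50 genes with
the highest average NMF coefficient — the cell-state signature.

**Bulk translation.** A state's abundance in a bulk profile is its
ssGSEA enrichment (running-sum with weight rank^0.25). Associations use
Cox regression for overall survival, logistic/linear models for
clinical variables, reported as signed −log10 p and pooled across
cohorts by weighted z-combination with w_i = 1/√n_i.

**Ecosystems and risk.** States are clustered on 1 − Spearman ρ of
their compartment-relative abundances across samples; the cluster
containing a focal state defines the ecosystem, scored per sample as
the geometric mean of member abundances. From the pooled ecosystem
signature genes, a risk model is trained by 1000 × leave-out-10%
LASSO-Cox stability selection (genes selected in ≥ 900 rounds) followed
by stepwise Cox regression; the risk score is

    score_s = Σ_i Exp_is · β_i

with samples above the median score called high-risk, evaluated by
log-rank test, multivariate Cox and Harrell's C-index.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a 6-sample cohort with three planted 50-gene programs, rebuild
the states, then train a risk signature on a synthetic survival cohort
with two prognostic genes:

```python
from metastates import (CellStateModel, PrognosticModel, SyntheticSpec,
                        simulate_cells, simulate_survival_cohort)

spec = SyntheticSpec(n_samples=6, cells_per_sample=150, n_genes=300, seed=1)
counts, annotations, truth = simulate_cells(spec)
states = CellStateModel(counts, annotations).fit(seed=1)
print(states.summary())

bulk, survival, _ = simulate_survival_cohort(
    250, 30, {"B0000": 1.0, "B0001": -1.0}, seed=21)
risk = PrognosticModel(bulk, survival, list(bulk.index)).fit(
    n_iter=20, seed=21, cv_folds=5)
print(risk.summary())
ev = risk.evaluate()
print(f"log-rank p = {ev['logrank_p']:.3g}, C-index = {ev['c_index']:.3f}")
```

Output:

```
Cell-state discovery summary
============================================================
samples:               6
programs decomposed:   198
programs after QC:     121
robust programs:       18
meta-programs:         3
chosen cluster number: 3
best mean silhouette:  0.741 (k=3)
  MP1: 6 member programs, signature G0030, G0022, G0023, G0033, G0001, ...
  MP2: 6 member programs, signature G0080, G0056, G0089, G0067, G0074, ...
  MP3: 6 member programs, signature G0120, G0103, G0115, G0127, G0148, ...

Prognostic risk signature
============================================================
candidate genes:      30
stability iterations: 20
stable genes:         2
final signature:      2 genes

gene              beta    freq
B0001          -0.8174      20
B0000           0.7926      20

log-rank p = 1.65e-17, C-index = 0.749
```

Reading the output: six samples produce 33 programs each (ranks 3–8);
usage-based QC and the three recurrence criteria reduce 198 programs to
18 robust ones, which cluster cleanly into the 3 planted meta-programs
(mean silhouette 0.74 at k = 3). The risk signature recovers exactly
the two planted prognostic genes with coefficients near the simulated
±1 effects (on z-scored expression), and the median split separates
survival on the same cohort at p ≈ 10⁻¹⁷ with C ≈ 0.75.

A command-line interface mirrors the library (`metastates --help`):
`simulate-cells`, `discover`, `score`, `abundance`, `ssgsea`,
`associate`, `ecosystem`, `train-sig`, `apply-sig`.

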