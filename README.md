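# methylstate

Dual-state immune-cell deconvolution of bulk tumor methylomes and
recurrence prediction for colorectal cancer.

## The problem

Immune cells change their DNA methylation when they infiltrate a tumor:
a tumor-infiltrating dendritic cell (TIIC-DC) is epigenetically distinct
from the same cell type circulating in blood (PBMC-DC). Reference-based
deconvolution pipelines that use blood-derived references therefore
conflate two cell states with opposite clinical meaning. `methylstate`
implements a two-state deconvolution: sorted-cell reference methylomes
from both compartments (four immune types x {tumor-infiltrating,
blood-like}, plus epithelial and fibroblast stromal classes) define a
signature matrix of discriminating CpG sites, per-patient cell-state
fractions are estimated from bulk tumor methylomes, and the inferred
composition — optionally with clinical covariates (TNM stage, metastasis,
MSI) — feeds tree-ensemble classifiers that predict 5-year recurrence
under Monte Carlo cross-validation. The package is aimed at
computational-biology users working with targeted bisulfite panels and
array-style beta matrices.

## The model

Bulk methylation is assumed to mix linearly: for signature matrix
`S ∈ [0,1]^{m×k}` (CpGs × cell-state classes) and bulk beta vector `m`,

    m ≈ S w,   w ≥ 0,  Σ_k w_k = 1.

Signature CpGs are chosen per class by one-vs-rest Welch *t* tests
(BH-FDR ≤ 0.05, |Δβ| ≥ 0.2, ≤ 200 CpGs/class). `w` is estimated by
ν-support-vector regression with a linear kernel (ν ∈ {0.25, 0.5, 0.75},
best reconstruction wins; negative coefficients truncated and the vector
renormalized), with a nonnegative-least-squares oracle for verification.
Recurrence models are extremely-randomized-trees / random-forest /
gradient-boosting classifiers evaluated over 100 stratified 70/30 splits
shared across all 2^k − 1 cell-state combinations; performance is AUC
(rank formulation) and Cohen's κ. The signature is interpreted by a
beta-binomial Wald test for differential methylation between matched
TIIC/PBMC classes, CpG→regulatory-element mapping within ±1,250 bp, and
hypergeometric GO enrichment of RE target genes (BH-corrected). A
synthetic-data module generates toy genomes, two-state references, bulk
mixtures with known proportions and composition-driven recurrence labels,
so every stage is benchmarked against planted ground truth.

## Worked example

```python
import numpy as np
import methylstate as ms

cfg = ms.SimulationConfig()                      # 10 classes, 1000 CpGs
genome = ms.generate_toy_genome(cfg)
atlas, truth = ms.generate_reference_profiles(genome, cfg)
bulk, clinical, cohort_truth = ms.generate_bulk_cohort(atlas, genome, cfg, 150, seed=0)

sig = ms.select_signature_cpgs(atlas, mode="tiic+pbmc")
print(len(sig.cpg_ids))                          # 299 signature CpGs

table = ms.deconvolve_cohort(bulk, sig)
est, true = table.proportions, cohort_truth.true_proportions
print(round(np.corrcoef(est["TIIC-DC"], true["TIIC-DC"])[0, 1], 3))   # 0.985

splits = ms.monte_carlo_splits(150, clinical.recurrence, n_repeats=100, seed=0)
report = ms.run_combination_search(
    table, clinical,
    combinations=ms.enumerate_combinations(table.class_labels, sizes=[3]),
    splits=splits, seed=0)
print(report.best_combination())                 # ('PBMC-DC', 'TIIC-CD8T', 'TIIC-DC')
print(round(report.ranking.iloc[0]["mean_auc"], 3))                   # 0.755
```

The 299 signature CpGs include all 100 planted cross-compartment
(state) DMCs — the single-compartment modes select none of them — and
the best 3-class combination recovers exactly the cell states whose
fractions generated the recurrence labels, at a mean cross-validated
AUC of 0.755. The same pipeline is runnable from the shell:

```bash
methylstate simulate --out run/ --n-samples 150 --seed 0
methylstate signature --atlas run/atlas --mode tiic+pbmc --out run/sig
methylstate deconvolve --bulk run/bulk --signature run/sig --out run/props.tsv
methylstate run-all --out run_all/ --seed 0     # everything, incl. DMC + enrichment
```

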