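# nbprog

Prognostic modelling for childhood neuroblastoma from integrated clinical,
gene-expression and DNA-methylation data.

Neuroblastoma outcomes are usually summarised by two related but distinct
binary endpoints: the 5-year survival class (short- vs long-term survivor)
and the vital status at last follow-up (dead vs alive). The two labels are
strongly but not perfectly correlated (φ ≈ 0.85 in the motivating 88-patient
cohort): a patient can be a short-term survivor *and* alive (indeterminate
survival), or a long-term survivor who has died. `nbprog` treats the pair as
a composite clinical outcome and predicts both labels jointly.

## What is inside

**Two-step feature selection (TSFS).** Omics feature tables are first
screened by the Fisher score

S_i = Σ_j n_j (μ_ij − μ_i)² / Σ_j n_j ρ_ij²,

the ratio of between-class to within-class scatter of feature *i* over
classes *j* (population-variance convention). The top-*k* candidates are
then pruned for redundancy with the **maximal association coefficient
(MAC)**: for two vectors of length *n*, a grid budget MG = max(4, ⌊n^α⌋)
caps a family of s × t grid partitions (each axis split by exact 1-D
k-means); within each cell the absolute Pearson correlation is taken and
cell-area-weighted,

AC(s,t) = Σ_i w_i |p_i|,  w_i = area_i / Σ_j area_j,

and MAC = max over shapes of AC ∈ [0, 1]. Candidate pairs with
MAC ≥ Rth become edges of a redundancy graph; each feature's *redundant
score* is its degree, and the *m* highest-scoring features are removed.
(k, m) are chosen by stratified cross-validated accuracy with the selection
refit inside every training fold.

**Models.** Per-task RBF-SVM baselines (ACC and rank-based AUC averaged
over stratified 80/20 splits) and a multi-gate mixture-of-experts (MMoE)
network that predicts both labels at once: shared expert networks, one
softmax gate per task weighting the experts, and per-task towers, trained
with the summed binary cross-entropy. The joint model is scored by
*absolute accuracy* — the fraction of patients with **both** labels
predicted correctly.

**Synthetic cohorts.** A generator reproduces the statistical shape of the
study data — φ-correlated binary outcomes drawn from an exact 2×2 joint,
outcome-dependent clinical covariates, Gaussian expression and Beta-valued
methylation blocks with planted informative, redundant near-duplicate and
null features — so every part of the pipeline is testable at desk scale.

## Worked example

```sh
nbprog simulate --n-samples 88 --seed 0 --outdir cohort
nbprog select --matrix cohort/expression.csv --clinical cohort/clinical.csv \
    --task survival --k-grid 12,18 --m-grid 0,4,6 --rth 0.9 --seed 0 \
    --out selection.json --features-out features.txt
nbprog train --mode multi --matrix cohort/expression.csv \
    --clinical cohort/clinical.csv --features features.txt --seed 0 \
    --out report.json
```

prints

```
wrote 4 files to cohort (n=88, seed=0, config_hash=5b9f0d56ddb9)
selected 12 features (k=18, m=6, alpha=0.55, rth=0.9)
wrote report to report.json
```

and `report.json` contains

```json
{
  "mode": "multi",
  "seed": 0,
  "n_features": 12,
  "n_train": 70,
  "n_test": 18,
  "absolute_accuracy": 0.7777777777777778,
  "survival": {"acc": 0.7777777777777778, "auc": 0.9506172839506173},
  "vital":    {"acc": 0.9444444444444444, "auc": 0.9875},
  "config_hash": "72c54148dbb6"
}
```

Reading: the grid search kept 18 Fisher candidates and removed the 6 most
redundant (12 features enter the model); on the held-out 18 patients the
joint MMoE got the vital status right for 94% and both labels right for 78%
— absolute accuracy is never above the weaker per-task accuracy. Empty
cells and `NA`-style tokens in input tables are treated as missing
(configurable via `--na-values`); features missing in more than 5% of
samples are dropped and the rest mean-imputed.

The same steps are available as library calls (`nbprog.generate`,
`nbprog.tsfs`, `nbprog.train_mmoe`, `nbprog.run_experiment`); see
`docs/methods.md` for the model details and parameter guidance.

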