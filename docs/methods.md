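# Methods

This note records the statistical procedures implemented in `nbprog`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## The composite outcome

Each patient carries two binary labels: the 5-year survival class
(`survival_years < 5` → short-term, 0; otherwise long-term, 1 — a survival
time of exactly 5 years counts as long-term) and the vital status at last
follow-up (dead 0 / alive 1). The labels are constructed independently of
each other, so all four combinations occur, including the
"indeterminate-survival" case (short-term, alive). Their Pearson
correlation — identical to the φ coefficient of the 2×2 table — quantifies
how much the two prediction tasks share.

## Preprocessing

* Features whose missing fraction is **strictly greater** than the cap
  (default 5%) are dropped; exactly-at-cap features are retained, all-empty
  features always dropped. Remaining gaps are filled with the feature mean.
* Age at diagnosis is min–max scaled to [0, 1]. The scaling statistics are
  fit on the training split and applied to test splits with clamping;
  fitting on all data would leak test information into the transform.
* INSS stage, MYCN status and the other categorical clinical fields are
  one-hot encoded against a **fixed, configured vocabulary** (stages 1, 2,
  3, 4, 4S; MYCN amplified / not amplified), so the indicator layout never
  depends on which categories a particular split happens to contain. A
  value outside the vocabulary (e.g. "unknown" MYCN) maps to all-zero
  indicators rather than a guessed category.
* Early integration concatenates modality blocks column-wise after
  prefixing feature ids with the modality.

## Maximal association coefficient

`mac(x, y)` measures possibly nonlinear association by piecewise-linear
decomposition:

1. Grid budget MG = max(4, ⌊n^α⌋). α ∈ [0, 1] (default 0.55) trades
   resolution against cell occupancy; the floor of 4 guarantees at least a
   2×2 grid.
2. Shapes: s ∈ [2, MG/2], t = ⌊MG/s⌋, shapes with t < 2 skipped,
   duplicates merged — and every shape is also evaluated with the axes
   swapped, which makes `mac(x, y) == mac(y, x)` hold exactly (the pair is
   additionally evaluated in a canonical argument order so even the
   floating-point summation order is identical).
3. Each axis is binned by **exact 1-D k-means** (dynamic programming over
   the sorted values, O(k n²)), which is deterministic and needs no seed;
   cost ties break toward the smaller split index. With fewer distinct
   values than bins, the bin count shrinks. Bin edges are midpoints between
   consecutive cluster means, outer edges the data min/max; the cell area
   is the product of bin widths.
4. A cell contributes |Pearson| weighted by its share of the total
   contributing area. Cells with fewer than `min_cell_points` (default 2)
   points, no variation in either coordinate (detected exactly via
   min == max), or zero area are excluded from **both** the sum and the
   weight normalisation — this keeps MAC = 1 on perfectly linear data,
   where excluded singleton cells would otherwise dilute the score. A
   config flag (`count_invalid_cells`) switches to the alternative
   convention (degenerate occupied cells keep their weight, contributing 0).
5. MAC is the maximum over all shape evaluations; a constant input vector
   yields MAC = 0 by convention. MAC ∈ [0, 1], is symmetric, and is
   invariant to affine rescaling of either argument (partitions and
   per-cell |Pearson| both transform consistently).

`pairwise_mac` shares the 1-D partition work across all column pairs
(each column is partitioned once per bin count), which is what makes
graph construction over dozens of candidates cheap.

## Two-step feature selection

Step 1 ranks features by Fisher score with the **population-variance**
(divide-by-n_j) convention, chosen so that the n_j ρ_ij² term reads as the
within-class scatter; a zero denominator with positive numerator ranks
first (+∞), 0/0 scores 0, and ties break toward the smaller original
index. Step 2 connects candidate pairs with MAC ≥ Rth, scores each
candidate by its degree, and removes the m highest-degree candidates in
one **static** pass (degree descending; ties remove the lower-Fisher
feature first, then the larger index). An `iterative` flag recomputes
degrees on the residual graph after each removal; the static pass is the
default. Note the static pass has a known failure mode on groups of
mutually tied degrees: when redundant pairs all have degree 1, the removal
order degenerates to ascending Fisher score and can delete both members of
a weak pair while leaving another pair intact; the iterative variant
removes at most one member per isolated pair. Neither variant can tell a
parent from a near-exact copy whose Fisher score is statistically
indistinguishable — in that regime the selection keeps one arbitrary
representative of each redundant group, which preserves the information
but not the identity of the kept feature.

(k, m) are chosen by stratified k-fold (default 5) cross-validated
accuracy of a downstream classifier (default RBF-SVM), with the entire
two-step selection refit inside each training fold; the leakage-prone
alternative (select once on all data, then cross-validate) is available
behind `refit_per_fold=False` for comparison with pipelines that report
it. Ties prefer fewer final features, then smaller k. Shipped per-task /
per-modality (α, Rth) defaults: survival task — gene (0.7, 0.65),
methylation (0.55, 0.9); vital task — gene (0.35, 0.2), methylation
(0.6, 0.9).

## Models

**Single task.** RBF-SVM, C = 1, kernel bandwidth 1/(d · mean feature
variance). Performance is reported as ACC and rank-based (Mann–Whitney)
AUC with half-credit for ties, averaged over five stratified 80/20
train/test splits (seeds 0–4 by default). The experiment runner evaluates
the standard eight data combinations (clinical alone; clinical plus each
omics block under Fisher-only or two-step selection; and their
concatenations), always selecting and encoding on the training split only.

**Multi task.** The MMoE holds E expert networks (default 4, one hidden
ReLU layer of width 16), a softmax gate per task over the experts, and a
per-task tower (hidden width 8) ending in a sigmoid. The tower input is
the gate-probability-weighted sum of expert outputs; the loss is the
equally weighted sum of the two binary cross-entropies. Training is
full-batch Adam (learning rate 1e-3), at most 500 epochs, early-stopped
after 25 epochs without improvement on a stratified 20% validation split
(stratified on the 4-way joint label when feasible), restoring the
best-validation parameters. Everything is seeded: the same spec and data
give bit-identical predictions. The network is implemented directly in
numpy with hand-written backpropagation (verified against finite
differences in the test suite); at these sizes (tens of inputs, a few
thousand parameters) a framework would add dependency weight without
benefit. With one expert the gate is identically 1 and the model reduces
exactly to a shared-bottom two-head network. A non-finite training loss —
the exact cross-entropy becomes +∞ when saturated logits assign
probability 0 to an observed outcome — aborts with advice to lower the
learning rate.

The joint model is evaluated by per-task ACC/AUC and by **absolute
accuracy**, the fraction of patients with both labels correct, which is
bounded above by the weaker per-task accuracy. The package's multi-task
sanity benchmark compares the MMoE's absolute accuracy against the
*independence baseline*: the product of the accuracies of two single-task
SVMs trained independently **on the same feature set** the MMoE receives
(the intersection of the per-task selections). Matching the features
isolates what joint modelling adds — exploiting the error correlation the
φ ≈ 0.85 labels induce — from what a bigger per-task feature set adds.

## Synthetic cohorts

`generate(SynthConfig(...))` draws label pairs i.i.d. from the exact 2×2
joint with cells P11 = ab + c, P10 = a(1−b) − c, P01 = (1−a)b − c,
P00 = (1−a)(1−b) + c, c = φ√(ab(1−a)(1−b)); infeasible φ raises with the
feasible bound. Defaults mirror the motivating cohort: n = 88,
a = 42/88 long-term, b = 37/88 alive, φ = 0.85.

* Expression block (default 100 features): informative features are unit
  Gaussians shifted by δ (default 1.0) on the survival label, the vital
  label, or (δ/2 each) both; redundant features are a designated
  informative parent plus N(0, σ) noise (σ default 0.05); nulls are
  standard Gaussian.
* Methylation block (default 150 features): Beta-distributed in [0, 1]
  with class-dependent means (0.35 vs 0.65, precision 10); duplicates are
  clipped to [0, 1]; nulls centre on 0.5.
* Clinical table: age at diagnosis (lognormal days, higher for poor
  outcomes), INSS stage (stage 4 enriched in poor outcomes), MYCN status
  (amplification enriched in poor outcomes, 5% unknown), gender, race and
  risk group with cohort-like frequencies. Survival times respect the
  5-year threshold by construction — label-1 patients draw 5 + Exp(mean 2)
  years, label-0 patients Uniform(0.2, 5) — so rebuilding labels from the
  generated clinical table reproduces the generated label pair exactly.

What the generator does **not** emulate: genome-scale dimensionality
(tens of thousands of features), inter-feature correlation structure
beyond the planted duplicates (no co-expression blocks or CpG
neighbourhoods), batch effects, censoring (vital status is exact, not a
follow-up snapshot), and any real biology linking expression to
methylation. Passing tests therefore demonstrate that the algorithms
recover planted structure under their own assumptions, not that they
reproduce findings on clinical omics data.

## Test and benchmark sizes

The suite validates the MAC against an exhaustive brute-force
reimplementation at n ≤ 30 (where full partition enumeration is
tractable), the φ round-trip at 100,000 draws (Monte-Carlo error well
inside the ±0.01 tolerance), selection-recovery behaviour at n = 200 over
20 seeds, and the multi-task comparison at n = 300 over 20 seeds — sizes
chosen so the full suite completes in a few minutes on one core while
keeping the stochastic checks' seed-to-seed variance small relative to
their margins.

## Known limitations

* The static redundancy-removal pass degrades on degree-tied redundant
  pairs (see above); prefer `iterative=True` when redundancy groups are
  expected to be small and disjoint.
* MAC with the default α = 0.55 is conservative for n below ~20 (MG stays
  at the floor of 4, allowing only a 2×2 grid).
* The MMoE has no weight regularisation; at very small n it relies on
  early stopping alone, and feature selection upstream matters.
* `run_experiment` evaluates a fixed plan; it does not nest the (k, m)
  hyperparameter search inside each split (the selection values are taken
  from the plan's block specs).
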