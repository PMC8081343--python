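# Methods

## Model

`kernelstack` is a stacked learner for multi-omic phenotype prediction that
uses prior knowledge in the form of gene sets (pathways, signatures,
chromosomal regions). The pipeline has two levels:

**Level zero — one random forest per feature set.** Each gene set is mapped
onto the data by intersecting its genes with every data type's gene
universe; a gene present in, say, expression and copy number contributes the
qualified features `gene::expr` and `gene::cnv`. Optional *global* features
(clinical variables and other measurements that do not map to genes) are
appended to every set, acting as a uniform conditioning layer across all
base learners. A bagged CART ensemble is trained on each set's columns with
full out-of-bag (OOB) bookkeeping: per-tree bootstrap masks, per-tree
continuous predictions (regression values or positive-class leaf fractions),
and breadth-first leaf indices. Each forest's OOB fit statistic tau is the
balanced accuracy of its OOB majority vote (classification) or the negated
OOB RMSE (regression). Balanced accuracy was chosen over plain accuracy
because realistic cohorts are often imbalanced; the metric is configurable.

**Forest selection.** For every sample, the G (default 5) highest-tau
forests that predict it *correctly* are kept; the union over samples is the
selected set. "Correct" means the OOB majority vote equals the label; for
regression, a prediction counts as matching when its absolute error falls
within the sample's q-quantile (default q = 0.05) of the error distribution
across all sets. Samples with fewer than G correct forests contribute the
ones they have; samples with none contribute nothing (logged). Tau ties
break lexicographically by set name so selection is deterministic. This
filter reduces tens of thousands of candidate sets to a tractable handful
without evaluating a kernel for every set.

**Level one — forest kernels and multiple kernel learning.** Each selected
forest induces an empirical similarity kernel combining three views:

* K1 = exp(−‖p_i − p_j‖² / σ1): Gaussian similarity of per-tree prediction
  vectors, σ1 the maximum pairwise squared distance (so entries lie in
  (0, 1] and the most dissimilar pair maps to e⁻¹);
* K2: the same construction over breadth-first leaf-index vectors — samples
  landing in early-split versus late-split leaves look less alike;
* K3 = exp(c_ij − 1), c_ij the fraction of trees in which the two samples
  share a leaf (the classical forest proximity).

The combined kernel is the elementwise geometric mean (K1∘K2∘K3)^(1/3).
For the meta-learner's *training* kernels, every pairwise statistic is
restricted to the trees in which **both** samples were out of bag, giving
cross-validated level-one data in the stacked-learning sense. The σ
constants of the OOB variant are computed from the masked distances
themselves; the final model's full-forest σ constants are stored and reused
when evaluating train-versus-new cross-kernels, so train and test
similarities share one scale.

**PSD projection of OOB kernels.** The full-forest kernel is positive
semi-definite by construction (Hadamard products and positive powers of PSD
kernels). The OOB variant is *not*: because each sample pair is evaluated
over a different tree subset, the matrix is only asymptotically PSD as the
tree count grows (empirically, its minimum eigenvalue is ≈ −0.7 at 50
trees, ≈ −0.2 at 200, and crosses zero around a thousand trees on a
60-sample dataset). Since the meta-learner requires PSD inputs, the OOB
kernel construction ends with a projection onto the PSD cone (negative
eigenvalues clipped at zero) followed by a diagonal renormalization that
restores the unit diagonal. Matrices already PSD within 1e−8 pass through
unchanged, so the projection vanishes in the many-trees limit.

**Elastic-net MKL.** The meta-learner fits a representer-form predictor
f(x) = Σ_m Σ_j k_m(x, x_j) α_{m,j} + b by minimizing

    Σ_i L(y_i, f_i) + λ1 Σ_m ‖α_m‖_{K_m} + λ2 Σ_m ‖α_m‖²_{K_m},

with squared loss for regression and logistic loss (labels coded ±1) for
classification, and the RKHS block norm ‖α‖_K = √(αᵀKα). The λ1 term acts
as a group lasso over kernels (whole blocks vanish, giving sparse kernel
combinations); λ2 acts as a ridge (dense combinations); mixing them spans
both regimes. Kernel weights are recovered as w_m = ‖α*_m‖ / (λ1 +
λ2‖α*_m‖), zero for zero-norm blocks, rescaled to sum to one — these are
the feature-set importances.

## Solver

Each kernel is eigendecomposed once and the problem is rewritten in
β_m = K_m^{1/2} α_m, where the block penalty becomes the plain Euclidean
norm — a group elastic net over kernel blocks. The solver cycles over
blocks; each update majorizes the loss by its curvature bound (exact for
squared loss, the 1/4 Hessian bound for logistic) and solves the resulting
subproblem — quadratic plus λ1‖β‖ + λ2‖β‖² — exactly in the eigenbasis via
a one-dimensional monotone root-find on the block norm. Every step is a
majorize-minimize update, so the objective decreases monotonically; blocks
hit exact zeros when the subgradient condition ‖gradient block‖ ≤ λ1 holds.
Convergence is declared at a relative objective change below 1e−7 or 500
passes (a warning reports non-convergence, which occurs only at nearly
unregularized corners where the logistic optimum is weakly attained). The
saturation threshold λ_max = max_m √(gᵀK_m g), with g the loss gradient at
the intercept-only model, is exposed; λ1 above it yields the all-zero
solution. The test suite cross-checks the solver against an independent
generic convex minimizer (smoothed block norms with continuation) to a
relative objective gap below 1e−5 on both losses across sparse and dense
corners.

**Hyperparameter tuning.** (λ1, λ2) candidate pairs (default 50) are drawn
log-uniformly — λ1 on [0.01, 1]·λ_max so the sparsity penalty always
operates on the problem's natural scale (the customary regularization-path
range for under-determined problems; an absolute range lets the tuner pick
effectively unregularized candidates), λ2 on the absolute range
[1e−4, 1e2] — and ranked by V-fold cross-validation (default V = 5,
stratified for classification) on the OOB kernels: training folds use
principal submatrices, validation rows the corresponding cross blocks. The
fit metric is −RMSE for regression and, for classification, the *balanced
accuracy of the sign decision* on validation scores rather than a
threshold-free rank metric. This choice is deliberate: representer scores
of samples outside a fold shrink toward the intercept relative to training
scores (their kernel similarities to the training set are systematically
smaller), and a rank metric such as AUROC cannot see when that shrinkage
breaks the hard class decision. Because CV validation scores are produced
exactly the way real predictions are, the sign-decision metric penalizes
miscalibrated candidates directly. To
guard against overfitting the level-one data, the *chosen* pair is not the
CV optimum but the candidate at the 90th percentile of the fit
distribution (rank ⌈0.9·n⌉ ascending, ties to the lowest candidate index).
During the CV sweep the solver runs with a looser budget (tolerance 1e−5,
200 passes, warm starts along a λ1-descending path); rank-based selection
is insensitive to that last decimal. The final model refits on full-forest
kernels at the chosen λs with the strict budget. The forests themselves are
never retrained — they already saw the full training data; only the kernel
variant changes between tuning and the final fit.

## Importances

Feature-set weights w^FS are the MKL kernel weights (non-negative, sum 1).
Per-forest feature importances m(RF, i) are OOB permutation importances:
the increase in OOB error (1 − balanced accuracy, or RMSE) when feature i's
column is permuted, negatives floored at zero. Each forest's importances
are normalized to sum to one before aggregation so that forests of
different sizes contribute on a common scale (a raw mode is available
behind a flag). Feature weights are w^F_i = Σ_k w^FS_k · m(RF_k, i) over
the selected forests containing i, renormalized to sum to one. Data-type
shares sum w^F within each data type; global features form their own
pseudo-type. Only trees whose splits actually use a feature are
re-evaluated during permutation (others cannot change), which makes the
computation exact and fast.

## Synthetic data

The generator emulates the statistical structures the method exploits,
with two independent seeds: a structure seed (set sizes, gene membership)
and a data seed (sampled values), so a "fresh draw from the same
population" changes only the data seed.

* One **planted set** whose first `n_causal` genes carry label signal in the
  expression-like data type; all other sets hold disjoint pure-noise genes.
  Defaults: 120 samples, 50 sets of 10–50 genes, two continuous data types,
  10 causal genes at Cohen's d = 1.0 each. With these defaults the combined
  latent effect is √10 ≈ 3.2 standard deviations — the planted signal is
  essentially Bayes-separable while every individual feature stays only
  moderately informative, so the *set*, not any single gene, carries the
  signal.
* **Collinear decoys**: a passenger gene whose expression column correlates
  with the first causal driver at a stated level (0.99 emulates
  co-transcribed gene pairs). The decoy joins only the planted set, while
  several other sets become partially overlapping pathways around the
  driver, each carrying the driver plus two fresh causal genes of its own.
  No single set then explains the labels alone, so the meta-learner spreads
  weight over several driver-containing kernels -- the
  driver-in-more-pathways asymmetry that lets prior knowledge break
  collinearity ties, while the passenger accrues importance from exactly
  one forest.
* **Global features**: clinical-style columns ρ·latent + √(1−ρ²)·noise with
  the latent score the standardized label signal; ρ = 0 gives pure noise,
  ρ = 1 a perfectly informative composite index.

What the generator does **not** emulate: real marginal distributions
(counts, heavy tails, bimodality), correlated noise between genes within a
pathway, batch effects, label noise, or missing values. Passing tests
therefore demonstrate the machinery recovers planted structure under clean
Gaussian conditions, not performance on real cohorts.

## Numerical choices and degenerate inputs

* σ = 0 in K1/K2 (all samples identical in that statistic): the component
  is defined as the all-ones matrix, the limit of the Gaussian as distances
  vanish.
* Sample pairs with zero co-OOB trees fall back to the full-forest
  statistic with a warning; at the default 2000 trees the per-pair
  probability is ≈ (1−e⁻²)^2000, effectively never.
* Any sample never OOB triggers one deterministic re-seeded retrain, then a
  hard error advising more trees.
* Kernels entering the MKL solver are eigenvalue-clipped at zero if the
  minimum eigenvalue sits in (−1e−8, 0); anything lower raises.
* Vote ties in OOB majority voting resolve to the negative (lexicographically
  smaller) class, deterministically.
* Sample order is canonicalized (lexicographic by id) before any randomized
  step; per-set seeds derive from the master seed plus a SHA-256 hash of
  the set name, so results are independent of set ordering and of the
  joblib worker count.

## Problem sizes in the test suite

The automated suite scales the study down so it completes on one CPU:
pipeline tests use 120 samples, 50-set compendia, 200 trees per forest and
20 tuning candidates, skipping permutation importances where a property
consumes only kernel weights and predictions; the decoy test (which needs
feature weights) uses a 25-set compendium at 100 trees; the robustness test
that inflates the compendium to 500 noise sets uses 60 trees and 12
candidates. Kernel-validity checks sweep 50 seeded fixtures with up to 60
samples and 120 trees; solver-oracle checks use up to 30 samples and 4
kernels. Production defaults remain 2000 trees and 50 candidates.

## Known limitations

* Binary classification and regression only; no multi-class or
  survival-time support (binarize survival upstream).
* No missing-value handling; the reader rejects NaNs.
* Permutation importance is the only importance rule implemented;
  impurity-based alternatives are intentionally out of scope.
* The OOB kernel's PSD projection slightly perturbs pairwise similarities
  at small tree counts; with the default 2000 trees the projection is
  typically inactive.
* Model archives are Python pickles: portable across machines with the same
  library versions, but not a language-independent format.
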