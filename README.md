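# kernelstack

Stacked multiple-kernel learning over pathway-specific random-forest
kernels, for predicting phenotypes (binary classes or continuous responses)
from multi-omic data plus prior knowledge in the form of gene sets.

## Who this is for

Computational biologists who have several feature tables for the same
samples (expression, copy number, methylation, inferred activities,
clinical variables, ...) and a compendium of gene sets (MSigDB-style GMT
files), and who want a predictor that is also *interpretable*: which
pathways, which individual features, and which data types drive the
prediction.

## The method

One random forest is trained per gene set, on the union of that set's
features across all data types (early integration: a gene's expression,
copy-number and mutation features live in the same forest and can
interact). Forests are ranked by their out-of-bag (OOB) fit statistic τ,
and for each sample the top-G correctly-predicting forests are kept; the
union Δ* of these survives. Each selected forest is converted into an
empirical sample-similarity kernel

    K = (K1 ∘ K2 ∘ K3)^(1/3)

where K1(i,j) = exp(−‖p_i−p_j‖²/σ1) compares per-tree prediction vectors,
K2 does the same for breadth-first leaf-index vectors, and
K3(i,j) = exp(c_ij − 1) uses the fraction of trees in which samples i and j
share a leaf. For the meta-learner's training data every statistic is
restricted, per sample pair, to the trees where both samples were out of
bag — cross-validated "level-one" similarities in the stacked-learning
sense. The meta-learner solves an elastic-net multiple-kernel problem

    min_{α,b} Σ_i L(y_i, Σ_m Σ_j k_m(x_i,x_j) α_{m,j} + b)
              + λ1 Σ_m ‖α_m‖_{K_m} + λ2 Σ_m ‖α_m‖²_{K_m}

(logistic loss for classification, squared for regression;
‖α‖_K = √(αᵀKα)), with (λ1, λ2) tuned by V-fold CV with a 90th-percentile
overfit correction. Recovered kernel weights w_m are the feature-set
importances; combining them with per-forest OOB permutation importances
yields feature weights and data-type shares, each normalized to sum to 1.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a benchmark with one signal-carrying ("planted") pathway among 50
gene sets across two data types, train, and inspect the model:

```python
import kernelstack as ks
from sklearn.metrics import roc_auc_score

dataset, collection, truth = ks.generate(n_samples=120, n_sets=50, seed=1)
config = ks.StackedKernelConfig(
    forest=ks.ForestParams(n_trees=200), n_lambda_candidates=25, seed=1
)
model = ks.train(dataset, collection, config)

print(model.feature_set_weights.sort_values(ascending=False).head(3))
fresh, _, _ = ks.generate(n_samples=120, n_sets=50, seed=1, data_seed=50001)
pred = ks.predict(model, fresh)
print("held-out AUROC:", round(roc_auc_score(fresh.y_numeric(), pred["score"]), 3))
```

Output:

```
planted_set       1.0
noise_set_0038    0.0
noise_set_0009    0.0
dtype: float64
held-out AUROC: 0.963
```

On this seed the tuner lands in the sparse regime and the meta-learner puts
all of its weight on the planted pathway's kernel, zeroing every noise set;
the stacked model separates held-out samples with AUROC 0.96. The signal
genes carry a one-standard-deviation shift each, so no single feature comes
close to this on its own.

The same pipeline is available from the shell:

```bash
kernelstack simulate --out data/ --seed 1
kernelstack train config.yaml            # YAML names tables, labels, GMT, output dir
kernelstack predict run/model.pkl --table expr=data/expr.tsv \
    --table cnv=data/cnv.tsv --out predictions.tsv
kernelstack mkl-fit --kernel k1.tsv --kernel k2.tsv --labels labels.tsv \
    --lambda1 0.1 --lambda2 0.1 --out weights.tsv   # standalone MKL solver
```

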