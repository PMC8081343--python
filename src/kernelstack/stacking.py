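"""The stacked learner: forests per feature set, OOB kernels as level-one
data, an elastic-net MKL meta-learner, and derived importance tables.

Training pipeline:

1. Map every gene set onto the available multi-omic features (sets with no
   local features are dropped with a warning) and train one forest per set.
2. Rank forests by their OOB fit statistic tau and, for each sample, keep the
   top-G forests that predict it correctly (classification: OOB majority vote
   equals the label; regression: the absolute OOB error falls within the
   sample's q-quantile across sets). The union over samples is the selected
   set Delta*.
3. Build OOB kernels for the selected forests and tune (lambda1, lambda2) by
   V-fold cross-validation with a 90th-percentile overfit correction.
4. Refit the meta-learner on full-forest kernels at the chosen lambdas. The
   forests themselves are not retrained -- they already saw the full
   level-zero data; only the kernel variant changes.
5. Derive importances: feature-set weights are the MKL kernel weights;
   feature weights aggregate per-forest permutation importances weighted by
   their set's weight; data-type shares sum feature weights within each data
   type (globals form their own pseudo-type).

All randomness flows from one master seed; per-set seeds are derived from the
master seed and a hash of the set name, so results are independent of worker
count and set ordering.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datasets import (
    CLASSIFICATION,
    AvailableFeatures,
    FeatureSetCollection,
    OmicsDataset,
    map_feature_set,
    qualify,
    split_qualified,
)
from .forest import FittedForest, ForestParams, fit_forest, permutation_importance
from .kernels import rf_kernel_cross, rf_kernel_full, rf_kernel_oob
from .mkl import (
    DEFAULT_LAMBDA1_RATIO,
    DEFAULT_LAMBDA2_RANGE,
    LOGISTIC,
    SQUARED,
    MKLModel,
    TuningResult,
    mkl_fit,
    mkl_predict,
    tune_lambdas,
)

logger = logging.getLogger("kernelstack")

FORMAT_VERSION = 1

GLOBAL_TYPE = "global"


@dataclass
class StackedKernelConfig:
    """End-to-end training configuration.

    ``top_sets_per_sample`` (G) controls how many correctly-predicting
    forests each sample contributes to the selection; ``binarize_quantile``
    (q) is the per-sample absolute-error quantile that counts a regression
    prediction as "matching".
    """

    top_sets_per_sample: int = 5
    binarize_quantile: float = 0.05
    forest: ForestParams = field(default_factory=ForestParams)
    cv_folds: int = 5
    n_lambda_candidates: int = 50
    lambda1_ratio_range: tuple[float, float] = DEFAULT_LAMBDA1_RATIO
    lambda2_range: tuple[float, float] = DEFAULT_LAMBDA2_RANGE
    mkl_max_iter: int = 500
    mkl_tol: float = 1e-7
    raw_importances: bool = False    # skip within-forest importance normalization
    compute_importances: bool = True  # permutation importances + feature tables
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.top_sets_per_sample < 1:
            raise ValueError("top_sets_per_sample must be >= 1")
        if not 0 < self.binarize_quantile < 1:
            raise ValueError("binarize_quantile must be in (0, 1)")


@dataclass
class StackedKernelModel:
    """A trained stacked model with its importance tables."""

    config: StackedKernelConfig
    task: str
    classes: np.ndarray | None
    sample_ids: list[str]
    data_types: list[str]
    global_features: list[str]
    selected_forests: list[FittedForest]
    meta: MKLModel
    tuning: TuningResult
    full_sigmas: dict[str, tuple[float, float]]
    feature_set_weights: pd.Series
    feature_weights: pd.Series
    datatype_weights: pd.Series
    format_version: int = FORMAT_VERSION

    @property
    def selected_set_names(self) -> list[str]:
        return [f.set_name for f in self.selected_forests]


def derive_seed(master_seed: int, name: str, salt: str = "") -> int:
    """Stable per-set seed from the master seed and the set name."""
    digest = hashlib.sha256(f"{name}|{salt}".encode()).digest()
    return (master_seed + int.from_bytes(digest[:4], "little")) % (2**31 - 1)


def binarize_regression_errors(
    per_set_predictions: np.ndarray, labels: np.ndarray, q: float
) -> np.ndarray:
    """Flag, per sample, the sets whose absolute OOB error is within the
    sample's q-quantile of its error distribution across all sets."""
    errs = np.abs(per_set_predictions - np.asarray(labels, dtype=float)[:, None])
    thresh = np.quantile(errs, q, axis=1)
    return errs <= thresh[:, None]


def select_relevant_forests(
    forests: list[FittedForest],
    labels: np.ndarray,
    G: int,
    q: float,
    task: str,
) -> list[FittedForest]:
    """Per sample, keep the G highest-tau forests that predict it correctly;
    return the union, ordered by (descending tau, set name)."""
    n = len(labels)
    if task == CLASSIFICATION:
        correct = np.stack([f.oob_prediction == labels for f in forests], axis=1)
    else:
        preds = np.stack([f.oob_prediction for f in forests], axis=1)
        correct = binarize_regression_errors(preds, labels, q)

    order = sorted(range(len(forests)), key=lambda i: (-forests[i].tau, forests[i].set_name))
    selected: set[int] = set()
    uncovered = 0
    for s in range(n):
        hits = [i for i in order if correct[s, i]][:G]
        if not hits:
            uncovered += 1
        selected.update(hits)
    if uncovered:
        logger.info("%d sample(s) had no correctly-predicting forest", uncovered)
    if not selected:
        raise ValueError(
            "no forest predicts any sample correctly; increase "
            "top_sets_per_sample or binarize_quantile"
        )
    return [forests[i] for i in order if i in selected]


def _meta_labels(dataset: OmicsDataset) -> tuple[np.ndarray, str]:
    if dataset.task == CLASSIFICATION:
        y01 = dataset.y_numeric()
        return 2.0 * y01 - 1.0, LOGISTIC
    return dataset.y_numeric(), SQUARED


def train(
    dataset: OmicsDataset,
    collection: FeatureSetCollection,
    config: StackedKernelConfig | None = None,
) -> StackedKernelModel:
    """Run the full training pipeline and return a fitted stacked model."""
    config = config or StackedKernelConfig()
    available = []
    for name, genes in collection:
        af = map_feature_set(name, genes, dataset)
        if af.usable:
            available.append(af)
        else:
            logger.warning("feature set %s maps to no features; dropped", name)
    if len(available) < 2:
        raise ValueError(f"need >= 2 usable feature sets, have {len(available)}")
    logger.info("training %d forests (%d sets supplied)", len(available), len(collection))

    def _fit(af: AvailableFeatures) -> FittedForest:
        params = replace(config.forest, seed=derive_seed(config.seed, af.set_name))
        return fit_forest(af, dataset, params)

    forests = Parallel(n_jobs=config.n_jobs)(delayed(_fit)(af) for af in available)

    y_raw = dataset.labels.to_numpy()
    selected = select_relevant_forests(
        forests, y_raw, config.top_sets_per_sample, config.binarize_quantile,
        dataset.task,
    )
    logger.info("selected %d / %d forests", len(selected), len(forests))

    y_meta, loss = _meta_labels(dataset)
    oob_kernels = [rf_kernel_oob(f) for f in selected]
    tuning = tune_lambdas(
        oob_kernels, y_meta, loss,
        V=config.cv_folds,
        n_candidates=config.n_lambda_candidates,
        seed=derive_seed(config.seed, "lambda-tuning"),
        lambda1_ratio_range=config.lambda1_ratio_range,
        lambda2_range=config.lambda2_range,
    )
    l1, l2 = tuning.chosen
    logger.info("chosen lambdas: lambda1=%.4g lambda2=%.4g", l1, l2)

    full_kernels = [rf_kernel_full(f) for f in selected]
    full_sigmas = {k.source_set: (k.sigma1, k.sigma2) for k in full_kernels}
    meta = mkl_fit(
        full_kernels, y_meta, l1, l2, loss,
        max_iter=config.mkl_max_iter, tol=config.mkl_tol,
    )
    if meta.degenerate:
        logger.warning("meta-learner is intercept-only (all kernel weights zero)")

    fs_weights = pd.Series(meta.kernel_weights, index=[f.set_name for f in selected])
    if config.compute_importances:
        for f in selected:
            f.importances = permutation_importance(
                f, dataset, seed=derive_seed(config.seed, f.set_name, salt="perm")
            )
        f_weights, dt_weights = _aggregate_importances(
            selected, fs_weights, raw=config.raw_importances
        )
    else:
        f_weights = pd.Series(dtype=float)
        dt_weights = pd.Series(dtype=float)

    return StackedKernelModel(
        config=config,
        task=dataset.task,
        classes=dataset.classes if dataset.task == CLASSIFICATION else None,
        sample_ids=list(dataset.sample_ids),
        data_types=list(dataset.data_types),
        global_features=list(dataset.global_features),
        selected_forests=selected,
        meta=meta,
        tuning=tuning,
        full_sigmas=full_sigmas,
        feature_set_weights=fs_weights,
        feature_weights=f_weights,
        datatype_weights=dt_weights,
    )


def _aggregate_importances(
    selected: list[FittedForest], fs_weights: pd.Series, raw: bool = False
) -> tuple[pd.Series, pd.Series]:
    """Feature weights w_i = sum_k w_k^FS * m(RF_k, i), then renormalized.

    By default each forest's permutation importances are normalized to sum to
    one first, so forests of different sizes contribute on a common scale;
    ``raw=True`` uses the unnormalized importances instead.
    """
    acc: dict[str, float] = {}
    for f in selected:
        imp = np.asarray(f.importances, dtype=float)
        if not raw:
            total = imp.sum()
            imp = imp / total if total > 0 else imp
        w = float(fs_weights[f.set_name])
        for name, m in zip(f.feature_names, imp):
            acc[name] = acc.get(name, 0.0) + w * m
    f_weights = pd.Series(acc, dtype=float)
    total = f_weights.sum()
    if total > 0:
        f_weights = f_weights / total
    f_weights = f_weights.sort_values(ascending=False, kind="stable")

    types = [
        (GLOBAL_TYPE if split_qualified(name)[1] is None else split_qualified(name)[1])
        for name in f_weights.index
    ]
    dt_weights = f_weights.groupby(pd.Series(types, index=f_weights.index)).sum()
    dt_weights = dt_weights.sort_values(ascending=False, kind="stable")
    return f_weights, dt_weights


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _combined_new_matrix(
    model: StackedKernelModel, new_tables
) -> pd.DataFrame:
    """Qualify per-data-type tables for prediction, mirroring training."""
    if isinstance(new_tables, OmicsDataset):
        return new_tables.X
    if isinstance(new_tables, pd.DataFrame):
        return new_tables
    globals_set = set(model.global_features)
    blocks = []
    for dtype in sorted(new_tables):
        table = new_tables[dtype]
        renamed = {
            col: (col if col in globals_set else qualify(col, dtype))
            for col in table.columns
        }
        blocks.append(table.rename(columns=renamed).astype(float))
    X = pd.concat(blocks, axis=1)
    return X.loc[:, ~X.columns.duplicated()]


def predict(model: StackedKernelModel, new_tables) -> pd.DataFrame:
    """Predict on new samples via per-forest cross-kernels and the meta-learner.

    ``new_tables`` may be a dict of per-data-type tables (raw gene columns),
    a combined qualified feature matrix, or an :class:`OmicsDataset`.
    Returns a frame indexed by sample with a ``score`` column and, for
    classification, ``probability`` and ``predicted_class``.
    """
    X_new = _combined_new_matrix(model, new_tables)
    needed = sorted({f for forest in model.selected_forests for f in forest.feature_names})
    missing = [f for f in needed if f not in X_new.columns]
    if missing:
        raise ValueError(f"new samples are missing required features: {missing[:20]}")

    cross = []
    for forest in model.selected_forests:
        s1, s2 = model.full_sigmas[forest.set_name]
        Xf = X_new[forest.feature_names].to_numpy(dtype=np.float64)
        cross.append(rf_kernel_cross(forest, Xf, s1, s2))
    out = mkl_predict(model.meta, cross)

    frame = pd.DataFrame({"score": out["score"]}, index=X_new.index)
    if model.task == CLASSIFICATION:
        frame["probability"] = out["probability"]
        frame["predicted_class"] = np.where(
            out["class_sign"] > 0, model.classes[1], model.classes[0]
        )
    return frame


# ---------------------------------------------------------------------------
# importances export & serialization
# ---------------------------------------------------------------------------

def feature_set_importance(model: StackedKernelModel) -> pd.Series:
    return model.feature_set_weights.sort_values(ascending=False, kind="stable")


def feature_importance(model: StackedKernelModel) -> pd.Series:
    return model.feature_weights


def datatype_importance(model: StackedKernelModel) -> pd.Series:
    return model.datatype_weights


def write_importance_tables(model: StackedKernelModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fs = feature_set_importance(model)
    pd.DataFrame({
        "rank": np.arange(1, len(fs) + 1), "feature_set": fs.index, "weight": fs.values,
    }).to_csv(outdir / "feature_set_importance.tsv", sep="\t", index=False)

    fw = feature_importance(model)
    types = [
        GLOBAL_TYPE if split_qualified(n)[1] is None else split_qualified(n)[1]
        for n in fw.index
    ]
    pd.DataFrame({
        "rank": np.arange(1, len(fw) + 1), "feature": fw.index,
        "weight": fw.values, "data_type": types,
    }).to_csv(outdir / "feature_importance.tsv", sep="\t", index=False)

    dt = datatype_importance(model)
    pd.DataFrame({
        "rank": np.arange(1, len(dt) + 1), "data_type": dt.index, "weight": dt.values,
    }).to_csv(outdir / "datatype_importance.tsv", sep="\t", index=False)


def save_model(model: StackedKernelModel, path: str | Path) -> None:
    """Serialize the model (config, forests, meta-learner, sigmas, importances)
    to a single archive file."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh, protocol=4)


def load_model(path: str | Path) -> StackedKernelModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if getattr(model, "format_version", None) != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {getattr(model, 'format_version', None)!r}"
        )
    return model
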