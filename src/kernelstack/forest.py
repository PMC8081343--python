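"""Per-feature-set random forests with full out-of-bag bookkeeping.

Each base learner is a bagged ensemble of CART trees trained on the columns
of one feature set only. Beyond prediction the ensemble records everything
the downstream kernels need: which samples each tree held out (OOB masks),
per-tree continuous predictions (regression value or positive-class leaf
fraction), and breadth-first leaf indices.

Leaf indexing contract: tree nodes are numbered breadth-first starting from
the root (root = 0, then sequentially across each depth level). The leaf
similarity kernel depends on this numbering, so it is fixed here.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .datasets import CLASSIFICATION, REGRESSION, AvailableFeatures, OmicsDataset

logger = logging.getLogger("kernelstack")

_RESEED_OFFSET = 1_000_003  # additive seed shift for the single OOB-coverage retry


@dataclass
class ForestParams:
    """Randomization controls for one forest.

    ``features_per_split``: None uses the task default (sqrt of the feature
    count for classification, one third for regression); otherwise a float
    fraction in (0, 1] or an int count.
    ``subsample``: fraction of samples drawn per tree; with ``bootstrap`` the
    draw is with replacement (the default scheme).
    """

    n_trees: int = 2000
    subsample: float = 1.0
    bootstrap: bool = True
    features_per_split: float | int | None = None
    min_node_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def max_features(self, task: str):
        if self.features_per_split is not None:
            return self.features_per_split
        return "sqrt" if task == CLASSIFICATION else (1.0 / 3.0)


@dataclass
class FittedForest:
    """A fitted ensemble with OOB masks, per-tree predictions and BFS leaves."""

    set_name: str
    feature_names: list[str]
    task: str
    classes: np.ndarray | None          # sorted class pair (classification)
    trees: list                         # fitted sklearn decision trees
    bfs_maps: list[np.ndarray]          # per tree: sklearn node id -> BFS id
    oob_mask: np.ndarray                # trees x samples bool, True = withheld
    tree_predictions: np.ndarray        # samples x trees float
    leaf_matrix: np.ndarray             # samples x trees int (BFS leaf ids)
    oob_prediction: np.ndarray          # per-sample aggregated OOB prediction
    oob_probability: np.ndarray | None  # classification: mean OOB class-1 prob
    tau: float = field(default=np.nan)
    importances: np.ndarray | None = None   # per-feature permutation importance
    params: ForestParams | None = None

    @property
    def n_trees(self) -> int:
        return self.oob_mask.shape[0]

    @property
    def n_samples(self) -> int:
        return self.oob_mask.shape[1]

    def apply_trees(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-tree predictions and BFS leaf indices for new samples.

        Returns (pred, leaves), each samples x trees.
        """
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        n = X32.shape[0]
        pred = np.empty((n, self.n_trees))
        leaves = np.empty((n, self.n_trees), dtype=np.int64)
        for t, tree in enumerate(self.trees):
            pred[:, t] = _tree_predict(tree, X32, self.task)
            leaves[:, t] = self.bfs_maps[t][tree.apply(X32, check_input=False)]
        return pred, leaves


def bfs_node_ids(tree) -> np.ndarray:
    """Map sklearn's depth-first node ids to breadth-first ids (root = 0)."""
    left = tree.tree_.children_left
    right = tree.tree_.children_right
    bfs = np.full(left.shape[0], -1, dtype=np.int64)
    queue = deque([0])
    next_id = 0
    while queue:
        node = queue.popleft()
        bfs[node] = next_id
        next_id += 1
        if left[node] != -1:
            queue.append(left[node])
            queue.append(right[node])
    return bfs


def _tree_predict(tree, X: np.ndarray, task: str) -> np.ndarray:
    """Per-tree continuous prediction; X must be C-contiguous float32."""
    if task == REGRESSION:
        return tree.predict(X, check_input=False)
    # positive-class leaf fraction: continuous per-tree class probability
    return tree.predict_proba(X, check_input=False)[:, 1]


def _draw_indices(rng: np.random.Generator, n: int, params: ForestParams) -> np.ndarray:
    size = max(1, int(round(params.subsample * n)))
    if params.bootstrap:
        return rng.integers(0, n, size=size)
    return rng.choice(n, size=size, replace=False)


def fit_forest(
    features: AvailableFeatures,
    dataset: OmicsDataset,
    params: ForestParams,
) -> FittedForest:
    """Train one forest on the feature set's columns with OOB bookkeeping.

    Deterministic given ``params.seed``. If any sample ends up in-bag in every
    tree, the forest is retrained once with a shifted seed; a second failure
    raises (more trees make the event vanishingly rare).
    """
    cols = features.all_features
    if not cols:
        raise ValueError(f"feature set {features.set_name!r} has no features")
    X = dataset.X[cols].to_numpy(dtype=np.float64)
    y_raw = dataset.labels.to_numpy()
    task = dataset.task
    n = X.shape[0]

    if task == CLASSIFICATION:
        classes = dataset.classes
        counts = [(y_raw == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError(
                f"need >=2 samples per class, got counts {counts} for {classes}"
            )
        y_fit = (y_raw == classes[1]).astype(np.int64)
    else:
        classes = None
        if n < 5:
            raise ValueError("regression requires >= 5 samples")
        y_fit = y_raw.astype(np.float64)

    for attempt, seed in enumerate((params.seed, params.seed + _RESEED_OFFSET)):
        fitted = _fit_once(features.set_name, cols, X, y_fit, task, classes, params, seed)
        if fitted.oob_mask.any(axis=0).all():
            break
        if attempt == 1:
            raise RuntimeError(
                f"forest {features.set_name!r}: some samples never OOB after a "
                "re-seed retry; increase n_trees or lower subsample"
            )
        logger.warning(
            "forest %s: sample(s) never OOB with seed %d, retraining once",
            features.set_name, params.seed,
        )

    fitted.oob_prediction, fitted.oob_probability = oob_prediction(fitted)
    fitted.tau = fit_statistic(y_raw, _oob_labels(fitted), task, classes)
    return fitted


def _fit_once(set_name, cols, X, y_fit, task, classes, params, seed) -> FittedForest:
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)   # sklearn trees' native dtype
    y64 = y_fit.astype(np.float64)
    rng = np.random.default_rng(seed)
    tree_cls = DecisionTreeClassifier if task == CLASSIFICATION else DecisionTreeRegressor
    max_features = params.max_features(task)
    if isinstance(max_features, float) and max_features < 1.0 and p > 1:
        max_features = max(1, int(round(max_features * p)))
    elif max_features == 1.0:
        max_features = None

    trees, bfs_maps = [], []
    oob_mask = np.zeros((params.n_trees, n), dtype=bool)
    preds = np.empty((n, params.n_trees))
    leaves = np.empty((n, params.n_trees), dtype=np.int64)
    for t in range(params.n_trees):
        idx = _draw_indices(rng, n, params)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = tree_cls(
            max_features=max_features,
            min_samples_leaf=params.min_node_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        if task == CLASSIFICATION and len(np.unique(y_fit[idx])) < 2:
            # single-class bootstrap draw: redraw deterministically until mixed
            while len(np.unique(y_fit[idx])) < 2:
                idx = _draw_indices(rng, n, params)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
        tree.fit(X32[idx], y64[idx], check_input=False)
        bfs = bfs_node_ids(tree)
        trees.append(tree)
        bfs_maps.append(bfs)
        oob_mask[t] = oob
        preds[:, t] = _tree_predict(tree, X32, task)
        leaves[:, t] = bfs[tree.apply(X32, check_input=False)]

    return FittedForest(
        set_name=set_name,
        feature_names=list(cols),
        task=task,
        classes=classes,
        trees=trees,
        bfs_maps=bfs_maps,
        oob_mask=oob_mask,
        tree_predictions=preds,
        leaf_matrix=leaves,
        oob_prediction=np.empty(0),
        oob_probability=None,
        params=params,
    )


def oob_prediction(
    forest: FittedForest, tree_predictions: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Aggregate per-tree predictions over each sample's OOB trees.

    Regression: arithmetic mean over OOB trees. Classification: majority vote
    of per-tree hard classes (leaf fraction > 0.5 is a positive vote; vote
    ties resolve to the negative class), with the mean OOB positive-class
    probability retained alongside.
    """
    P = forest.tree_predictions if tree_predictions is None else tree_predictions
    mask = forest.oob_mask.T.astype(float)        # samples x trees
    counts = mask.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("some samples have no OOB trees")
    mean_oob = (P * mask).sum(axis=1) / counts
    if forest.task == REGRESSION:
        return mean_oob, None
    votes = ((P > 0.5).astype(float) * mask).sum(axis=1) / counts
    pred_class = np.where(votes > 0.5, forest.classes[1], forest.classes[0])
    return pred_class, mean_oob


def _oob_labels(forest: FittedForest) -> np.ndarray:
    return forest.oob_prediction


def fit_statistic(
    labels: np.ndarray, oob_pred: np.ndarray, task: str, classes=None
) -> float:
    """OOB fit statistic tau: balanced accuracy (classification, in [0, 1]) or
    negated RMSE (regression, higher is better)."""
    if len(labels) != len(oob_pred):
        raise ValueError("labels and predictions differ in length")
    if task == CLASSIFICATION:
        return float(balanced_accuracy_score(labels, oob_pred))
    return -float(np.sqrt(np.mean((labels.astype(float) - oob_pred) ** 2)))


def _oob_error(forest: FittedForest, P: np.ndarray, y_raw: np.ndarray) -> float:
    """OOB error under the tau metric family (1 - balanced accuracy, or RMSE)."""
    pred, _ = oob_prediction(forest, tree_predictions=P)
    if forest.task == CLASSIFICATION:
        return 1.0 - balanced_accuracy_score(y_raw, pred)
    return float(np.sqrt(np.mean((y_raw.astype(float) - pred) ** 2)))


def forest_predict(forest: FittedForest, X_new: np.ndarray) -> np.ndarray:
    """Full-forest prediction for new samples carrying the forest's columns.

    Regression: mean of per-tree predictions. Classification: majority vote
    of per-tree hard classes (ties to the negative class), matching the OOB
    aggregation rule.
    """
    pred, _ = forest.apply_trees(X_new)
    if forest.task == REGRESSION:
        return pred.mean(axis=1)
    votes = (pred > 0.5).mean(axis=1)
    return np.where(votes > 0.5, forest.classes[1], forest.classes[0])


def permutation_importance(
    forest: FittedForest, dataset: OmicsDataset, seed: int
) -> np.ndarray:
    """OOB permutation importance m(RF, i) per feature.

    For each feature the column is randomly permuted, per-tree predictions are
    recomputed, and the increase in OOB error over the unpermuted baseline is
    the importance. Negative values are floored at zero so downstream
    aggregation stays non-negative. Only trees whose splits actually use the
    feature are re-evaluated (others cannot change). Deterministic given seed.
    """
    X = np.ascontiguousarray(
        dataset.X[forest.feature_names].to_numpy(), dtype=np.float32
    )
    y_raw = dataset.labels.to_numpy()
    baseline = _oob_error(forest, forest.tree_predictions, y_raw)

    trees_using: dict[int, list[int]] = {j: [] for j in range(X.shape[1])}
    for t, tree in enumerate(forest.trees):
        feats = tree.tree_.feature
        for j in np.unique(feats[feats >= 0]):
            trees_using[int(j)].append(t)

    rng = np.random.default_rng(seed)
    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        perm = rng.permutation(X.shape[0])
        affected = trees_using[j]
        if not affected:
            continue  # feature never split on: permutation cannot change anything
        Xp = X.copy()
        Xp[:, j] = X[perm, j]
        P = forest.tree_predictions.copy()
        for t in affected:
            P[:, t] = _tree_predict(forest.trees[t], Xp, forest.task)
        imp[j] = max(0.0, _oob_error(forest, P, y_raw) - baseline)
    return imp
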