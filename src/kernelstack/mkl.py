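"""Elastic-net-regularized multiple kernel learning.

Fits a representer-form predictor ``f(x) = sum_m sum_j k_m(x, x_j) a_{m,j} + b``
by minimizing

    sum_i L(y_i, f_i) + lambda1 * sum_m ||a_m||_{K_m} + lambda2 * sum_m ||a_m||^2_{K_m}

with the RKHS block norm ``||a||_K = sqrt(a^T K a)``, squared loss for
regression and logistic loss (labels coded +/-1) for classification. The
lambda1 term acts like a group lasso over kernels (entire coefficient blocks
vanish), the lambda2 term like a ridge; mixing them reaches both sparse and
dense kernel combinations.

Solver: each kernel is eigendecomposed once and the problem is rewritten in
``beta_m = K_m^{1/2} a_m``, where the block penalty becomes the plain
Euclidean norm (a group elastic net over kernel blocks). Cyclic
block-coordinate minimization then updates one block at a time: the loss is
majorized by its curvature bound (exact for squared loss, the 1/4 Hessian
bound for logistic), and the resulting block subproblem -- quadratic plus
``lambda1 ||.|| + lambda2 ||.||^2`` -- is solved exactly in the eigenbasis
via a one-dimensional root-find on the block norm. Each update is a
majorize-minimize step, so the objective decreases monotonically.
Coefficients are mapped back through the pseudo-inverse square root, exact
because iterates never leave the range of ``K_m``.

Kernel weights are recovered as
``w_m = ||a_m||_K / (lambda1 + lambda2 ||a_m||_K)`` (zero-norm blocks get
zero weight) and rescaled to sum to one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold

from .kernels import KernelMatrix, clip_psd

logger = logging.getLogger("kernelstack")

SQUARED = "squared"
LOGISTIC = "logistic"

DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-7
DEFAULT_LAMBDA2_RANGE = (1e-4, 1e2)     # absolute range for the ridge term
DEFAULT_LAMBDA1_RATIO = (1e-2, 1.0)     # lambda1 sampled relative to lambda_max
DEFAULT_N_CANDIDATES = 50
DEFAULT_FOLDS = 5
TUNE_MAX_ITER = 200    # CV-phase pass cap: rank-based selection tolerates a
TUNE_TOL = 1e-5        # looser numerical budget than the final fit

_EIG_TOL = 1e-10   # relative cutoff for treating kernel eigenvalues as zero


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _loss_value(y: np.ndarray, f: np.ndarray, loss: str) -> float:
    if loss == SQUARED:
        return 0.5 * float(np.sum((y - f) ** 2))
    return float(np.sum(np.logaddexp(0.0, -y * f)))


def _loss_grad(y: np.ndarray, f: np.ndarray, loss: str) -> np.ndarray:
    if loss == SQUARED:
        return f - y
    return -y / (1.0 + np.exp(y * f))


_CURVATURE = {SQUARED: 1.0, LOGISTIC: 0.25}


# ---------------------------------------------------------------------------
# kernel blocks
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    """Eigendecomposition of one kernel: K = U diag(s^2) U^T."""

    U: np.ndarray          # n x n orthonormal eigenvectors
    s: np.ndarray          # sqrt of (clipped) eigenvalues
    lmax: float            # largest eigenvalue of K

    def alpha_from(self, beta: np.ndarray) -> np.ndarray:
        """Map eigenbasis block coordinates back to representer coefficients."""
        cutoff = np.sqrt(_EIG_TOL * max(self.lmax, 1.0))
        inv = np.where(self.s > cutoff, 1.0 / np.maximum(self.s, 1e-300), 0.0)
        return self.U @ (inv * beta)


def _make_block(K: np.ndarray) -> _Block:
    K = clip_psd(K)
    w, V = np.linalg.eigh(K)
    w = np.maximum(w, 0.0)
    return _Block(U=V, s=np.sqrt(w), lmax=float(w[-1]))


def _solve_block(
    s: np.ndarray, t: np.ndarray, cc: float, lambda1: float, lambda2: float
) -> np.ndarray:
    """Exact minimizer of (cc/2) ||s*beta - t||^2 + lambda1 ||beta|| + lambda2 ||beta||^2.

    Coordinates decouple given the block norm nu = ||beta||:
    beta_i = num_i * nu / (nu * a_i + lambda1) with num_i = cc s_i t_i and
    a_i = cc s_i^2 + 2 lambda2; nu solves a monotone scalar equation. The
    block collapses to zero exactly when ||num|| <= lambda1.
    """
    num = cc * s * t
    norm_num = np.linalg.norm(num)
    if norm_num <= lambda1:
        return np.zeros_like(t)
    a = cc * s * s + 2.0 * lambda2
    a = np.maximum(a, 1e-300)
    if lambda1 <= 1e-12 * norm_num:
        # negligible block-norm penalty: ridge-only closed form
        return num / a
    def h(nu: float) -> float:
        return float(np.sum((num / (nu * a + lambda1)) ** 2)) - 1.0
    hi = float(np.linalg.norm(num / a))
    # h(hi) <= 0 analytically; pad the bracket against round-off at equality
    tries = 0
    while h(hi) > 0 and tries < 60:
        hi *= 1.0 + 2.0**(-50 + tries)
        tries += 1
    from scipy.optimize import brentq
    nu = brentq(h, 0.0, hi, xtol=1e-13, rtol=1e-11, maxiter=200)
    return num * nu / (nu * a + lambda1)


def _optimal_intercept(y: np.ndarray, loss: str) -> float:
    if loss == SQUARED:
        return float(np.mean(y))
    p = float(np.mean(y > 0))
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1.0 - p))


def _fit_blocks(
    blocks: list[_Block],
    y: np.ndarray,
    lambda1: float,
    lambda2: float,
    loss: str,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    warn: bool = True,
    init: tuple[list[np.ndarray], float] | None = None,
) -> tuple[list[np.ndarray], float, float, bool]:
    """Cyclic exact block-coordinate solver in per-kernel eigenbases.

    Returns (betas, b, objective, converged); betas are eigenbasis block
    coordinates (map back with ``block.alpha_from``).
    """
    n = len(y)
    c = _CURVATURE[loss]
    if init is None:
        betas = [np.zeros(n) for _ in blocks]
        b = _optimal_intercept(y, loss)
    else:
        betas = [bm.copy() for bm in init[0]]
        b = init[1]
    f = np.full(n, b)
    for block, bm in zip(blocks, betas):
        if np.any(bm):
            f += block.U @ (block.s * bm)

    def objective() -> float:
        pen = sum(
            lambda1 * np.linalg.norm(bm) + lambda2 * float(bm @ bm) for bm in betas
        )
        return _loss_value(y, f, loss) + pen

    obj = objective()
    converged = False
    for _ in range(max_iter):
        # intercept: exact for squared loss, curvature-bound MM step otherwise
        if loss == SQUARED:
            shift = float(np.mean(y - (f - b))) - b
        else:
            g_b = float(np.sum(_loss_grad(y, f, loss)))
            shift = -g_b / (c * n)
        b += shift
        f += shift
        # block MM steps: quadratic majorizer solved exactly per block
        for m, block in enumerate(blocks):
            if block.lmax <= 0:
                continue
            g_tilde = block.U.T @ _loss_grad(y, f, loss)
            t = block.s * betas[m] - g_tilde / c
            new = _solve_block(block.s, t, c, lambda1, lambda2)
            delta = new - betas[m]
            if np.any(delta):
                f += block.U @ (block.s * delta)
                betas[m] = new
        new_obj = objective()
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        logger.log(
            logging.WARNING if warn else logging.DEBUG,
            "MKL solver did not reach tol=%.1e within %d passes (objective %.6g)",
            tol, max_iter, obj,
        )
    return betas, b, obj, converged


# ---------------------------------------------------------------------------
# public model
# ---------------------------------------------------------------------------

@dataclass
class MKLModel:
    """Fitted multiple-kernel predictor."""

    alphas: list[np.ndarray]          # per-kernel coefficient vectors (length N)
    bias: float
    lambda1: float
    lambda2: float
    loss: str
    kernel_ids: list[str]
    block_norms: np.ndarray           # ||a_m||_{K_m}
    objective: float
    converged: bool

    @property
    def degenerate(self) -> bool:
        """True when every coefficient block is zero (intercept-only model)."""
        return bool(np.all(self.block_norms == 0))

    @property
    def kernel_weights(self) -> np.ndarray:
        return kernel_weights(self)


def _kernel_arrays(kernels) -> tuple[list[np.ndarray], list[str]]:
    mats, ids = [], []
    for i, K in enumerate(kernels):
        if isinstance(K, KernelMatrix):
            mats.append(K.values)
            ids.append(K.source_set)
        else:
            mats.append(np.asarray(K, dtype=float))
            ids.append(f"kernel_{i}")
    return mats, ids


def _check_labels(y: np.ndarray, loss: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if loss == LOGISTIC:
        vals = set(np.unique(y))
        if not vals <= {-1.0, 1.0}:
            raise ValueError(f"logistic loss expects labels coded +/-1, got {sorted(vals)}")
    return y


def mkl_fit(
    kernels,
    labels,
    lambda1: float,
    lambda2: float,
    loss: str,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> MKLModel:
    """Fit the elastic-net MKL objective over square, aligned PSD kernels."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be non-negative")
    mats, ids = _kernel_arrays(kernels)
    if lambda1 == 0 and lambda2 == 0 and len(mats) > 1:
        raise ValueError("lambda1 = lambda2 = 0 is only allowed with a single kernel")
    y = _check_labels(np.asarray(labels), loss)
    n = len(y)
    for K in mats:
        if K.shape != (n, n):
            raise ValueError(f"kernel shape {K.shape} does not match {n} samples")
    blocks = [_make_block(K) for K in mats]
    betas, b, obj, converged = _fit_blocks(
        blocks, y, lambda1, lambda2, loss, max_iter=max_iter, tol=tol
    )
    alphas = [block.alpha_from(bm) for block, bm in zip(blocks, betas)]
    norms = np.array([float(np.linalg.norm(bm)) for bm in betas])
    return MKLModel(
        alphas=alphas, bias=b, lambda1=lambda1, lambda2=lambda2, loss=loss,
        kernel_ids=ids, block_norms=norms, objective=obj, converged=converged,
    )


def kernel_weights(model: MKLModel) -> np.ndarray:
    """Per-kernel weights: zero for zero-norm blocks, otherwise
    ``||a_m|| / (lambda1 + lambda2 ||a_m||)``, rescaled to sum to one."""
    norms = model.block_norms
    raw = np.where(
        norms == 0, 0.0, norms / (model.lambda1 + model.lambda2 * norms)
    )
    total = raw.sum()
    if total == 0:
        return np.zeros_like(raw)
    return raw / total


def mkl_objective(kernels, labels, alphas, bias, lambda1, lambda2, loss) -> float:
    """Evaluate the (unsmoothed) objective at arbitrary coefficients."""
    mats, _ = _kernel_arrays(kernels)
    y = _check_labels(np.asarray(labels), loss)
    f = np.full(len(y), float(bias))
    pen = 0.0
    for K, a in zip(mats, alphas):
        f += K @ a
        q = float(a @ K @ a)
        nrm = math.sqrt(max(q, 0.0))
        pen += lambda1 * nrm + lambda2 * q
    return _loss_value(y, f, loss) + pen


def lambda_max(kernels, labels, loss: str) -> float:
    """Smallest lambda1 at which the all-zero coefficient solution is optimal.

    Computed from the loss gradient at the intercept-only model:
    ``max_m sqrt(g^T K_m g)`` with ``g_i = L'(y_i, b0)``.
    """
    mats, _ = _kernel_arrays(kernels)
    y = _check_labels(np.asarray(labels), loss)
    b0 = _optimal_intercept(y, loss)
    g = _loss_grad(y, np.full(len(y), b0), loss)
    return max(math.sqrt(max(float(g @ K @ g), 0.0)) for K in mats)


def mkl_predict(model: MKLModel, cross_kernels) -> dict[str, np.ndarray]:
    """Predict from train x new cross-kernels, aligned to the model's kernels.

    Returns a dict with ``score`` (raw representer scores) and, for logistic
    models, ``probability`` (sigmoid of the score) and ``class_sign``
    (+1 / -1 by score sign, ties to +1).
    """
    mats, _ = _kernel_arrays(cross_kernels)
    if len(mats) != len(model.alphas):
        raise ValueError(
            f"model has {len(model.alphas)} kernels, got {len(mats)} cross-kernels"
        )
    n_train = len(model.alphas[0])
    scores = None
    for K, a in zip(mats, model.alphas):
        if K.shape[0] != n_train:
            raise ValueError(
                f"cross-kernel rows {K.shape[0]} do not match {n_train} training samples"
            )
        contrib = K.T @ a
        scores = contrib if scores is None else scores + contrib
    scores = (np.zeros(mats[0].shape[1]) if scores is None else scores) + model.bias
    out = {"score": scores}
    if model.loss == LOGISTIC:
        out["probability"] = 1.0 / (1.0 + np.exp(-scores))
        out["class_sign"] = np.where(scores >= 0, 1.0, -1.0)
    return out


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    candidates: list[tuple[float, float, float]]   # (lambda1, lambda2, mean CV fit)
    chosen: tuple[float, float]
    chosen_index: int
    metric: str
    folds: int
    seed: int


def _percentile_choice(fits: np.ndarray) -> int:
    """Index of the candidate at the 90th percentile of the fit distribution.

    Rank ceil(0.9 * n) in ascending fit order; among candidates tied at that
    fit value, the lowest candidate index wins (deterministic).
    """
    n = len(fits)
    rank = max(int(math.ceil(0.9 * n)) - 1, 0)
    target = np.sort(fits, kind="stable")[rank]
    return int(np.flatnonzero(fits == target)[0])


def tune_lambdas(
    oob_kernels,
    labels,
    loss: str,
    V: int = DEFAULT_FOLDS,
    n_candidates: int = DEFAULT_N_CANDIDATES,
    seed: int = 0,
    lambda1_ratio_range: tuple[float, float] = DEFAULT_LAMBDA1_RATIO,
    lambda2_range: tuple[float, float] = DEFAULT_LAMBDA2_RANGE,
    max_iter: int = TUNE_MAX_ITER,
    tol: float = TUNE_TOL,
) -> TuningResult:
    """Pick (lambda1, lambda2) by V-fold CV over log-uniform random candidates.

    lambda1 candidates are drawn log-uniformly on a range *relative to the
    saturation threshold* lambda_max (default [0.01, 1] * lambda_max, the
    customary path range for under-determined problems), so the sparsity
    penalty always operates on the problem's natural scale; lambda2
    candidates use an absolute log-uniform range. Train folds use the
    principal submatrix of each OOB kernel; validation rows use the
    corresponding cross sub-block. Folds are stratified for classification
    (each class must have at least V members). The chosen pair sits at the
    90th percentile of the candidate mean-fit distribution -- a deliberate
    step back from the CV optimum that guards against overfitting the
    level-one data.
    """
    if V < 2:
        raise ValueError("V must be >= 2")
    if n_candidates < 10:
        raise ValueError("n_candidates must be >= 10")
    mats, _ = _kernel_arrays(oob_kernels)
    y = _check_labels(np.asarray(labels), loss)
    n = len(y)

    rng = np.random.default_rng(seed)
    lmax = lambda_max(mats, y, loss)
    l1 = lmax * 10.0 ** rng.uniform(
        np.log10(lambda1_ratio_range[0]), np.log10(lambda1_ratio_range[1]),
        size=n_candidates,
    )
    l2 = 10.0 ** rng.uniform(
        np.log10(lambda2_range[0]), np.log10(lambda2_range[1]), size=n_candidates
    )
    pairs = np.column_stack([l1, l2])

    if loss == LOGISTIC:
        class_counts = np.unique(y, return_counts=True)[1]
        if class_counts.min() < V:
            raise ValueError(
                f"cannot stratify {V} folds: smallest class has {class_counts.min()} samples"
            )
        splitter = StratifiedKFold(n_splits=V, shuffle=True, random_state=seed % (2**32))
        folds = list(splitter.split(np.zeros(n), (y > 0).astype(int)))
        metric = "balanced_accuracy"
    else:
        splitter = KFold(n_splits=V, shuffle=True, random_state=seed % (2**32))
        folds = list(splitter.split(np.zeros(n)))
        metric = "neg_rmse"

    # within each fold, sweep candidates from strongest to weakest lambda1,
    # warm-starting each fit from the previous solution (a regularization path)
    sweep = sorted(range(n_candidates), key=lambda i: -pairs[i, 0])
    fold_fits = np.zeros((n_candidates, V))
    for v, (tr, va) in enumerate(folds):
        blocks = [_make_block(K[np.ix_(tr, tr)]) for K in mats]
        cross = [K[np.ix_(tr, va)] for K in mats]
        y_tr, y_va = y[tr], y[va]
        warm = None
        for ci in sweep:
            l1, l2 = pairs[ci]
            betas, b, _, _ = _fit_blocks(
                blocks, y_tr, l1, l2, loss, max_iter=max_iter, tol=tol,
                warn=False, init=warm,
            )
            warm = (betas, b)
            scores = np.full(len(va), b)
            for block, bm, Kc in zip(blocks, betas, cross):
                if np.any(bm):
                    scores += Kc.T @ block.alpha_from(bm)
            if loss == LOGISTIC:
                if len(np.unique(y_va)) < 2:
                    fold_fits[ci, v] = 0.5
                else:
                    # calibration-aware fit: the sign decision must already
                    # work on validation scores, mirroring real prediction
                    fold_fits[ci, v] = balanced_accuracy_score(
                        (y_va > 0).astype(int), (scores > 0).astype(int)
                    )
            else:
                fold_fits[ci, v] = -float(np.sqrt(np.mean((y_va - scores) ** 2)))

    mean_fits = fold_fits.mean(axis=1)
    idx = _percentile_choice(mean_fits)
    candidates = [
        (float(l1), float(l2), float(fit)) for (l1, l2), fit in zip(pairs, mean_fits)
    ]
    return TuningResult(
        candidates=candidates,
        chosen=(float(pairs[idx, 0]), float(pairs[idx, 1])),
        chosen_index=idx,
        metric=metric,
        folds=V,
        seed=seed,
    )
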