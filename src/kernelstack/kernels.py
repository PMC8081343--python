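"""Empirical random-forest kernels.

A fitted forest induces a sample-similarity kernel combining three views of
the ensemble:

* K1 -- Gaussian similarity over the per-tree prediction vectors,
  ``K1(i,j) = exp(-||p_i - p_j||^2 / sigma1)`` with ``sigma1`` the maximum
  pairwise squared distance, so entries land in (0, 1].
* K2 -- the same construction over breadth-first leaf-index vectors; early-
  vs late-split leaves carry depth information, so samples landing at very
  different depths look less alike.
* K3 -- ``exp(c_ij - 1)`` where ``c_ij`` is the fraction of trees in which
  the two samples share a leaf (the classical forest proximity).

The combined kernel is the elementwise geometric mean ``(K1*K2*K3)^(1/3)``,
positive semi-definite as a Hadamard product of PSD kernels raised to a
positive power.

The out-of-bag (OOB) variant restricts each pair's statistics to the trees
in which *both* samples were withheld, yielding cross-validated level-one
similarities for the meta-learner. The cross variant evaluates train-vs-new
similarities through all trees, reusing the training scaling constants so
train and test similarities share a scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forest import FittedForest

logger = logging.getLogger("kernelstack")

PSD_TOL = 1e-8

FULL = "full"
OOB = "oob"
CROSS = "cross"


@dataclass
class KernelMatrix:
    """A forest-derived similarity matrix (train x train, or train x new)."""

    values: np.ndarray
    variant: str                 # FULL, OOB or CROSS
    source_set: str
    sigma1: float                # K1 scaling constant (max squared distance)
    sigma2: float                # K2 scaling constant

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class CoOOBMask:
    """Pairwise counts of trees in which both samples are simultaneously OOB."""

    counts: np.ndarray           # n x n int
    oob_mask: np.ndarray         # trees x samples bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)


def co_oob_mask(forest: FittedForest) -> CoOOBMask:
    m = forest.oob_mask.astype(np.float64)          # trees x samples
    return CoOOBMask(counts=(m.T @ m).astype(np.int64), oob_mask=forest.oob_mask)


def _masked_sqdist(V: np.ndarray, mask: CoOOBMask | None) -> np.ndarray:
    """Pairwise squared distances of the rows of V (samples x trees).

    With a co-OOB mask, each pair's distance runs only over trees where both
    samples are OOB:  sum_t m_it m_jt (v_it - v_jt)^2, expanded into three
    matrix products.
    """
    if mask is None:
        sq = np.sum(V * V, axis=1)
        D = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    else:
        M = mask.oob_mask.T.astype(np.float64)      # samples x trees
        MV = M * V
        MV2 = M * V * V
        D = MV2 @ M.T + M @ MV2.T - 2.0 * (MV @ MV.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _gauss_from_sqdist(D: np.ndarray, sigma: float | None = None) -> tuple[np.ndarray, float]:
    """exp(-D / sigma) with sigma = max pairwise squared distance.

    sigma = 0 (all rows identical) degenerates to the all-ones matrix, the
    limit of the Gaussian as distances vanish.
    """
    if sigma is None:
        sigma = float(D.max())
    if sigma <= 0.0:
        return np.ones_like(D), 0.0
    return np.exp(-D / sigma), sigma


def k1(
    pred_vectors: np.ndarray,
    mask: CoOOBMask | None = None,
    sigma: float | None = None,
) -> tuple[np.ndarray, float]:
    """Prediction-similarity component; returns (matrix, sigma used)."""
    return _gauss_from_sqdist(_masked_sqdist(pred_vectors, mask), sigma)


def k2(
    leaf_matrix: np.ndarray,
    mask: CoOOBMask | None = None,
    sigma: float | None = None,
) -> tuple[np.ndarray, float]:
    """Leaf-index-similarity component over BFS leaf ids."""
    return _gauss_from_sqdist(_masked_sqdist(leaf_matrix.astype(np.float64), mask), sigma)


def _co_leaf_counts(L: np.ndarray, mask: CoOOBMask | None) -> np.ndarray:
    """Pairwise counts of trees in which two samples share a leaf."""
    n, T = L.shape
    counts = np.zeros((n, n))
    if mask is None:
        for t in range(T):
            counts += L[:, t, None] == L[None, :, t]
    else:
        M = mask.oob_mask  # trees x samples
        for t in range(T):
            eq = L[:, t, None] == L[None, :, t]
            m = M[t].astype(np.float64)
            counts += eq * np.outer(m, m)
    return counts


def k3(leaf_matrix: np.ndarray, mask: CoOOBMask | None = None) -> np.ndarray:
    """Leaf co-occurrence component exp(c_ij - 1), c_ij in [0, 1].

    With a mask, c_ij is the co-leaf fraction over co-OOB trees; pairs with
    zero co-OOB trees fall back to the full-forest fraction (with a warning;
    at default tree counts the event essentially never happens). Diagonal is
    exactly 1 (a sample always shares its own leaf).
    """
    co = _co_leaf_counts(leaf_matrix, mask)
    if mask is None:
        c = co / leaf_matrix.shape[1]
    else:
        denom = mask.counts.astype(np.float64)
        zero = denom == 0
        np.fill_diagonal(zero, False)
        c = np.divide(co, denom, out=np.zeros_like(co), where=denom > 0)
        if zero.any():
            n_pairs = int(zero.sum() // 2)
            logger.warning(
                "k3: %d sample pair(s) share no co-OOB trees; falling back to "
                "the full-forest co-leaf fraction for them", n_pairs,
            )
            c_full = _co_leaf_counts(leaf_matrix, None) / leaf_matrix.shape[1]
            c[zero] = c_full[zero]
    np.fill_diagonal(c, 1.0)
    return np.exp(c - 1.0)


def combine(K1: np.ndarray, K2: np.ndarray, K3: np.ndarray) -> np.ndarray:
    """Elementwise geometric mean (K1 * K2 * K3)^(1/3)."""
    if not (K1.shape == K2.shape == K3.shape):
        raise ValueError("component kernels must share a shape")
    return np.cbrt(K1 * K2 * K3)


def _build(forest: FittedForest, mask: CoOOBMask | None, variant: str) -> KernelMatrix:
    K1, s1 = k1(forest.tree_predictions, mask)
    K2, s2 = k2(forest.leaf_matrix, mask)
    K3 = k3(forest.leaf_matrix, mask)
    K = combine(K1, K2, K3)
    K = 0.5 * (K + K.T)  # enforce exact symmetry against round-off
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(values=K, variant=variant, source_set=forest.set_name,
                        sigma1=s1, sigma2=s2)


def rf_kernel_full(forest: FittedForest) -> KernelMatrix:
    """Combined kernel over all trees (used for the final meta-learner fit)."""
    return _build(forest, None, FULL)


def project_psd(K: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Project onto the PSD cone and restore the unit diagonal.

    Because each sample pair's masked statistics run over a *different* tree
    subset, the raw OOB kernel is not a Gram matrix: it is only
    asymptotically PSD as the tree count grows. The projection clips negative
    eigenvalues at zero and renormalizes ``K / sqrt(diag diag^T)`` so square
    kernels keep a unit diagonal; matrices already PSD (within ``tol``) pass
    through unchanged.
    """
    w, V = np.linalg.eigh(K)
    if w[0] >= -tol:
        return K
    Kc = (V * np.maximum(w, 0.0)) @ V.T
    d = np.sqrt(np.maximum(np.diag(Kc), 1e-300))
    Kc = Kc / np.outer(d, d)
    np.fill_diagonal(Kc, 1.0)
    return 0.5 * (Kc + Kc.T)


def rf_kernel_oob(forest: FittedForest) -> KernelMatrix:
    """Combined kernel restricted per pair to co-OOB trees (level-one data).

    The scaling constants are computed from the masked distances themselves
    (each pair over its own co-OOB trees, max over pairs). The pairwise
    masking means the raw matrix is only asymptotically PSD, so the final
    step projects it onto the PSD cone (see :func:`project_psd`).
    """
    km = _build(forest, co_oob_mask(forest), OOB)
    km.values = project_psd(km.values)
    return km


def rf_kernel_cross(
    forest: FittedForest,
    X_new: np.ndarray,
    sigma1: float,
    sigma2: float,
) -> KernelMatrix:
    """Train x new similarity through all trees, reusing training sigmas.

    ``X_new`` must carry the forest's feature columns in order. Because new
    samples may be farther apart than any training pair, entries can fall
    below exp(-1) but stay strictly positive.
    """
    if X_new.shape[1] != len(forest.feature_names):
        raise ValueError(
            f"expected {len(forest.feature_names)} feature columns, got {X_new.shape[1]}"
        )
    p_new, t_new = forest.apply_trees(X_new)
    P, L = forest.tree_predictions, forest.leaf_matrix.astype(np.float64)

    def cross_sqdist(A, B):
        sa = np.sum(A * A, axis=1)
        sb = np.sum(B * B, axis=1)
        return np.maximum(sa[:, None] + sb[None, :] - 2.0 * (A @ B.T), 0.0)

    D1 = cross_sqdist(P, p_new)
    D2 = cross_sqdist(L, t_new.astype(np.float64))
    K1c = np.ones_like(D1) if sigma1 <= 0 else np.exp(-D1 / sigma1)
    K2c = np.ones_like(D2) if sigma2 <= 0 else np.exp(-D2 / sigma2)

    T = forest.n_trees
    co = np.zeros_like(D1)
    for t in range(T):
        co += forest.leaf_matrix[:, t, None] == t_new[None, :, t]
    K3c = np.exp(co / T - 1.0)
    return KernelMatrix(values=np.cbrt(K1c * K2c * K3c), variant=CROSS,
                        source_set=forest.set_name, sigma1=sigma1, sigma2=sigma2)


def clip_psd(K: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Clip slightly negative eigenvalues (numerical noise) at zero.

    Raises if the minimum eigenvalue is below ``-tol`` -- that is a genuinely
    indefinite matrix, not round-off.
    """
    w, V = np.linalg.eigh(K)
    if w[0] < -tol:
        raise ValueError(f"kernel is not PSD: min eigenvalue {w[0]:.3e} < -{tol:.0e}")
    if w[0] >= 0:
        return K
    Kc = (V * np.maximum(w, 0.0)) @ V.T
    return 0.5 * (Kc + Kc.T)


def write_kernel_tsv(kernel: KernelMatrix, sample_ids, path) -> None:
    import pandas as pd

    pd.DataFrame(kernel.values, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", index_label="sample"
    )
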