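"""Independent reference computations used only by the test suite.

These deliberately avoid the implementation's code paths: brute-force double
loops for masked kernel statistics, and a generic smooth convex minimizer
(scipy L-BFGS-B with block-norm smoothing continuation) for the MKL
objective.
"""

import numpy as np
from scipy.optimize import minimize

from kernelstack.mkl import LOGISTIC, SQUARED


def brute_force_k3_masked(leaf_matrix: np.ndarray, oob_mask: np.ndarray) -> np.ndarray:
    """exp(c_ij - 1) with c_ij the co-leaf fraction over co-OOB trees,
    computed with explicit loops over pairs and trees (full-forest fallback
    for pairs with no co-OOB tree)."""
    n, T = leaf_matrix.shape
    K = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            co_trees = [t for t in range(T) if oob_mask[t, i] and oob_mask[t, j]]
            if co_trees:
                c = np.mean(
                    [leaf_matrix[i, t] == leaf_matrix[j, t] for t in co_trees]
                )
            else:
                c = np.mean(
                    [leaf_matrix[i, t] == leaf_matrix[j, t] for t in range(T)]
                )
            K[i, j] = np.exp(c - 1.0)
    return K


def brute_force_masked_sqdist(V: np.ndarray, oob_mask: np.ndarray) -> np.ndarray:
    """Pairwise squared distances over co-OOB trees, looped explicitly."""
    n, T = V.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            D[i, j] = sum(
                (V[i, t] - V[j, t]) ** 2
                for t in range(T)
                if oob_mask[t, i] and oob_mask[t, j]
            )
    return D


def mkl_oracle_objective(kernels, y, lambda1, lambda2, loss) -> float:
    """Minimum of the elastic-net MKL objective found by a generic smooth
    solver with smoothing continuation on the block norms."""
    Ks = [np.asarray(K, dtype=float) for K in kernels]
    y = np.asarray(y, dtype=float)
    n, M = len(y), len(Ks)

    def make(delta):
        def obj_grad(v):
            b = v[-1]
            alphas = v[:-1].reshape(M, n)
            f = np.full(n, b)
            for K, a in zip(Ks, alphas):
                f += K @ a
            if loss == SQUARED:
                lv = 0.5 * np.sum((y - f) ** 2)
                g = f - y
            elif loss == LOGISTIC:
                lv = float(np.sum(np.logaddexp(0.0, -y * f)))
                g = -y / (1.0 + np.exp(y * f))
            else:
                raise ValueError(loss)
            val = lv
            grad = np.zeros_like(v)
            grad[-1] = g.sum()
            for m, (K, a) in enumerate(zip(Ks, alphas)):
                Ka = K @ a
                q = float(a @ Ka)
                r = np.sqrt(max(q, 0.0) + delta**2)
                val += lambda1 * (r - delta) + lambda2 * q
                grad[m * n:(m + 1) * n] = K @ g + lambda1 * Ka / r + 2.0 * lambda2 * Ka
            return val, grad
        return obj_grad

    v = np.zeros(M * n + 1)
    res = None
    for delta in (1e-2, 1e-4, 1e-6, 1e-8, 1e-10):
        res = minimize(
            make(delta), v, jac=True, method="L-BFGS-B",
            options=dict(maxiter=50000, maxfun=200000, ftol=1e-18, gtol=1e-14),
        )
        v = res.x
    return float(res.fun)


def random_unit_diag_psd_kernels(rng, n, M):
    """Random PSD kernels with unit diagonal (well away from singular)."""
    Ks = []
    for _ in range(M):
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        d = np.sqrt(np.diag(K))
        Ks.append(K / np.outer(d, d))
    return Ks
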