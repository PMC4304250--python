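"""Non-negative matrix factorization with the Kullback-Leibler divergence
objective and multiplicative updates.

The expression matrix A (n genes x m samples, non-negative after exponential
scaling) is approximated as A ~ WH with W (n x k) and H (k x m) non-negative.
Columns of W and rows of H are metagenes; the argmax over metagenes of each
H column gives the sample's cluster under a single run.

The objective is the generalized KL divergence

    D(A || WH) = sum_ij [ A_ij log(A_ij / (WH)_ij) - A_ij + (WH)_ij ]

with the convention 0 * log 0 = 0.  Multiplicative updates (W then H, using
the updated W) keep the factors non-negative and never increase D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

EPS = 1e-12  # floor for denominators in updates and logs in the divergence


@dataclass
class Factorization:
    """Result of one NMF run."""

    W: np.ndarray
    H: np.ndarray
    k: int
    divergence: float
    n_iter: int
    seed: int
    converged: bool


def exponential_scale(log2_matrix) -> np.ndarray:
    """Map log2-scale data to the linear scale (elementwise 2**x).

    Guarantees strictly positive input for NMF regardless of the sign of the
    log2 values.  Accepts arrays or DataFrames; returns the same type.
    """
    values = np.asarray(log2_matrix, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    scaled = np.exp2(log2_matrix)
    return scaled


def kl_divergence(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(A || WH).

    Returns ``inf`` when (WH)_ij vanishes where A_ij > 0; terms with
    A_ij = 0 reduce to (WH)_ij.
    """
    A = np.asarray(A, dtype=float)
    WH = W @ H
    pos = A > 0
    if np.any(WH[pos] <= 0):
        return float("inf")
    total = float(WH.sum() - A.sum())
    total += float(np.sum(A[pos] * np.log(A[pos] / WH[pos])))
    return total


def update_step(
    A: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float = EPS
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative sweep: update W, then H using the updated W.

    W_ia <- W_ia * sum_u H_au A_iu/(WH)_iu / sum_v H_av
    H_au <- H_au * sum_i W_ia A_iu/(WH)_iu / sum_k W_ka

    Denominators are floored at ``eps`` to guard 0/0.
    """
    WH = W @ H
    W = W * ((A / np.maximum(WH, eps)) @ H.T) / np.maximum(H.sum(axis=1), eps)
    WH = W @ H
    H = H * (W.T @ (A / np.maximum(WH, eps))) / np.maximum(W.sum(axis=0)[:, None], eps)
    return W, H


def fit_nmf(
    A: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 1000,
    check_every: int = 10,
    stable_checks: int = 40,
    dtype=np.float64,
) -> Factorization:
    """Fit A ~ WH at rank ``k`` from a seeded random start.

    Factors are initialized uniform(0, 1] and rescaled so the initial
    reconstruction matches the mean of A.  Iteration stops when the sample
    connectivity pattern (argmax over metagenes of each H column) has been
    unchanged for ``stable_checks`` consecutive checks taken every
    ``check_every`` sweeps, or at ``max_iter`` sweeps.

    ``dtype`` controls the working precision; float32 roughly halves the
    cost of consensus sweeps, where only the connectivity pattern matters.
    The final divergence is always evaluated in float64.
    """
    A = np.asarray(A, dtype=dtype)
    if A.ndim != 2:
        raise ValueError("A must be a 2-d matrix")
    n, m = A.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"rank k={k} out of range for a {n}x{m} matrix")
    if np.any(A < 0):
        raise ValueError("A must be non-negative; apply exponential_scale first")

    rng = np.random.default_rng(seed)
    # uniform(0,1] entries; scale both factors so mean(WH) ~ mean(A)
    W = (1.0 - rng.random((n, k))).astype(dtype)
    H = (1.0 - rng.random((k, m))).astype(dtype)
    scale = dtype(np.sqrt(max(A.mean(), EPS) / max((W @ H).mean(), EPS)))
    W *= scale
    H *= scale

    eps = dtype(EPS)
    WH = np.empty((n, m), dtype=dtype)
    ratio = np.empty((n, m), dtype=dtype)
    numW = np.empty((n, k), dtype=dtype)
    numH = np.empty((k, m), dtype=dtype)

    labels = np.argmax(H, axis=0)
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # same sweep as update_step, with reused buffers
        np.matmul(W, H, out=WH)
        np.maximum(WH, eps, out=WH)
        np.divide(A, WH, out=ratio)
        np.matmul(ratio, H.T, out=numW)
        W *= numW
        W /= np.maximum(H.sum(axis=1), eps)
        np.matmul(W, H, out=WH)
        np.maximum(WH, eps, out=WH)
        np.divide(A, WH, out=ratio)
        np.matmul(W.T, ratio, out=numH)
        H *= numH
        H /= np.maximum(W.sum(axis=0), eps)[:, None]
        if it % check_every == 0:
            new_labels = np.argmax(H, axis=0)
            if np.array_equal(new_labels, labels):
                stable += 1
            else:
                stable = 0
                labels = new_labels
            if stable >= stable_checks:
                converged = True
                break

    W = W.astype(np.float64, copy=False)
    H = H.astype(np.float64, copy=False)
    return Factorization(
        W=W,
        H=H,
        k=k,
        divergence=kl_divergence(np.asarray(A, dtype=np.float64), W, H),
        n_iter=it,
        seed=seed,
        converged=converged,
    )
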