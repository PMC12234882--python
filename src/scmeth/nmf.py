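"""Masked non-negative matrix factorization.

Sparse single-cell methylation matrices are mostly missing, not mostly
zero; the factorization therefore minimizes squared error over *observed*
entries only.  Rank-2 alternating least squares with a closed-form
two-variable non-negative solve per row/column, fully vectorized, seeded
initialization, and a monotone objective trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NMFResult:
    W: np.ndarray          # rows x 2, non-negative
    H: np.ndarray          # 2 x cols, non-negative
    mask: np.ndarray       # True where observed
    objective: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def row_assignments(self) -> np.ndarray:
        return np.argmax(self.W, axis=1)

    @property
    def col_assignments(self) -> np.ndarray:
        return np.argmax(self.H, axis=0)

    def fitted(self) -> np.ndarray:
        return self.W @ self.H


def _nnls_rank2(A11, A12, A22, b1, b2):
    """Vectorized non-negative solve of the 2x2 normal equations per row.

    Falls back to the best of the two axis solutions (or zero) whenever the
    unconstrained optimum leaves the non-negative orthant or the system is
    singular.
    """
    eps = 1e-12
    det = A11 * A22 - A12 * A12
    safe = det > eps
    w1 = np.where(safe, (A22 * b1 - A12 * b2) / np.where(safe, det, 1.0), -1.0)
    w2 = np.where(safe, (A11 * b2 - A12 * b1) / np.where(safe, det, 1.0), -1.0)

    bad = ~safe | (w1 < 0) | (w2 < 0)
    if np.any(bad):
        c1 = np.clip(np.divide(b1, A11, out=np.zeros_like(b1),
                               where=A11 > eps), 0, None)
        c2 = np.clip(np.divide(b2, A22, out=np.zeros_like(b2),
                               where=A22 > eps), 0, None)
        # f(w) = 0.5 w'Aw - b'w (constant dropped); lower is better
        f1 = 0.5 * A11 * c1 ** 2 - b1 * c1
        f2 = 0.5 * A22 * c2 ** 2 - b2 * c2
        use1 = f1 <= f2
        w1 = np.where(bad, np.where(use1, c1, 0.0), w1)
        w2 = np.where(bad, np.where(use1, 0.0, c2), w2)
    return np.clip(w1, 0, None), np.clip(w2, 0, None)


def masked_nmf(X: np.ndarray, mask: np.ndarray | None = None, rank: int = 2,
               seed: int = 0, tol: float = 1e-6,
               max_iter: int = 500) -> NMFResult:
    """Rank-2 NMF of ``X`` penalizing only entries where ``mask`` is True.

    Masked (missing) entries never enter the objective, so their stored
    values are irrelevant to the fit.  The objective is non-increasing per
    iteration; convergence is declared when its relative change drops below
    ``tol``.
    """
    if rank != 2:
        raise NotImplementedError("only rank-2 factorization is supported")
    X = np.asarray(X, dtype=float)
    if mask is None:
        mask = np.ones(X.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != X.shape:
        raise ValueError("mask shape does not match matrix shape")
    empty_rows = np.flatnonzero(~mask.any(axis=1))
    empty_cols = np.flatnonzero(~mask.any(axis=0))
    if len(empty_rows) or len(empty_cols):
        raise ValueError(
            f"all-missing rows {empty_rows.tolist()} / columns "
            f"{empty_cols.tolist()}")

    n, m = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X[mask].mean(), 1e-9) / rank)
    W = rng.uniform(0.1, 1.0, size=(n, rank)) * scale
    H = rng.uniform(0.1, 1.0, size=(rank, m)) * scale

    Xm = np.where(mask, X, 0.0)
    M = mask.astype(float)

    def objective() -> float:
        R = (X - W @ H)
        return float(np.sum(R[mask] ** 2))

    trace = [objective()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # update W rows: A_i = sum_j m_ij h_j h_j', b_i = sum_j m_ij x_ij h_j
        h1, h2 = H[0], H[1]
        A11 = M @ (h1 * h1)
        A12 = M @ (h1 * h2)
        A22 = M @ (h2 * h2)
        b1 = Xm @ h1
        b2 = Xm @ h2
        W[:, 0], W[:, 1] = _nnls_rank2(A11, A12, A22, b1, b2)

        # update H columns (same system on the transpose)
        w1, w2 = W[:, 0], W[:, 1]
        A11 = M.T @ (w1 * w1)
        A12 = M.T @ (w1 * w2)
        A22 = M.T @ (w2 * w2)
        b1 = Xm.T @ w1
        b2 = Xm.T @ w2
        H[0], H[1] = _nnls_rank2(A11, A12, A22, b1, b2)

        obj = objective()
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break

    return NMFResult(W=W, H=H, mask=mask, objective=trace,
                     converged=converged, n_iter=it)


def prepare_beta_matrix(B: np.ndarray, mask: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Stack [beta; 1-beta], apply sentinels, normalize and log-transform.

    The complement block makes per-cell column sums independent of overall
    methylation level before normalization.  Observed zeros become 1e-12
    (sparse-storage sentinel), missing entries 0 with a False mask; columns
    are scaled to unit sum over observed entries, then log1p-transformed.
    """
    B = np.asarray(B, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    X = np.vstack([B, 1.0 - B])
    M = np.vstack([mask, mask])
    X = np.where(M, np.where(X == 0.0, 1e-12, X), 0.0)
    colsum = (X * M).sum(axis=0)
    colsum[colsum == 0] = 1.0
    X = X / colsum
    X = np.where(M, np.log1p(X), 0.0)
    return X, M
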