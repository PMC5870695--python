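"""Incomplete Cholesky factorization with zero fill-in, IC(0), plus the
triangular solves — the preconditioner of the IC(0)-CG solver.

The factor L keeps exactly the sparsity pattern of the lower triangle of A
(diagonal included).  If the factorization breaks down (non-positive pivot),
the caller retries on a diagonally shifted matrix.
"""
from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import LinearOperator


@njit(cache=True)
def _ic0_factor(indptr, indices, data):  # pragma: no cover - numba
    """In-place IC(0) on a lower-triangular CSR (sorted column indices,
    diagonal last in each row).  Returns the row of breakdown or -1."""
    n = len(indptr) - 1
    for i in range(n):
        r0, r1 = indptr[i], indptr[i + 1]
        # off-diagonal entries of row i
        for p in range(r0, r1 - 1):
            k = indices[p]
            # dot of row i [r0..p) and row k (off-diagonal part), common columns
            s = data[p]
            a = r0
            b0, b1 = indptr[k], indptr[k + 1] - 1  # exclude diag of row k
            b = b0
            while a < p and b < b1:
                ca, cb = indices[a], indices[b]
                if ca == cb:
                    s -= data[a] * data[b]
                    a += 1
                    b += 1
                elif ca < cb:
                    a += 1
                else:
                    b += 1
            dkk = data[indptr[k + 1] - 1]
            data[p] = s / dkk
        # diagonal
        s = data[r1 - 1]
        for p in range(r0, r1 - 1):
            s -= data[p] * data[p]
        if s <= 0.0:
            return i
        data[r1 - 1] = np.sqrt(s)
    return -1


@njit(cache=True)
def _forward_solve(indptr, indices, data, b):  # pragma: no cover - numba
    """Solve L y = b with L lower-triangular CSR (diag last per row)."""
    n = len(indptr) - 1
    y = b.copy()
    for i in range(n):
        s = y[i]
        for p in range(indptr[i], indptr[i + 1] - 1):
            s -= data[p] * y[indices[p]]
        y[i] = s / data[indptr[i + 1] - 1]
    return y


@njit(cache=True)
def _backward_solve(indptr, indices, data, b):  # pragma: no cover - numba
    """Solve L^T x = b using row access of L (column-oriented update)."""
    n = len(indptr) - 1
    x = b.copy()
    for i in range(n - 1, -1, -1):
        xi = x[i] / data[indptr[i + 1] - 1]
        x[i] = xi
        for p in range(indptr[i], indptr[i + 1] - 1):
            x[indices[p]] -= data[p] * xi
    return x


class IC0Preconditioner(LinearOperator):
    """IC(0) preconditioner M ~ A^{-1} for a sparse SPD matrix.

    On breakdown the factorization is retried on A + shift * mean(diag) * I,
    with the shift escalating tenfold (starting at 1e-3).
    """

    def __init__(self, A: sparse.spmatrix, shift: float = 1e-3, max_tries: int = 6):
        A = sparse.csr_matrix(A)
        n = A.shape[0]
        super().__init__(dtype=np.float64, shape=(n, n))
        mean_diag = float(A.diagonal().mean())
        s = 0.0
        for attempt in range(max_tries):
            L = sparse.tril(A, format="csr")
            if s > 0.0:
                L = (L + sparse.eye(n, format="csr") * (s * mean_diag)).tocsr()
            L.sort_indices()
            fail_row = _ic0_factor(L.indptr, L.indices, L.data)
            if fail_row < 0:
                self._L = L
                self.shift_used = s
                return
            s = shift if s == 0.0 else s * 10.0
        raise RuntimeError("IC(0) factorization failed even with diagonal shift")

    def _matvec(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=np.float64).ravel()
        y = _forward_solve(self._L.indptr, self._L.indices, self._L.data, r)
        return _backward_solve(self._L.indptr, self._L.indices, self._L.data, y)
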