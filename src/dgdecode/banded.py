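"""Symmetric banded matrix utilities for the decoder.

Matrices are stored in scipy's upper banded form: ``ab[u + i - j, j] =
A[i, j]`` for ``j - u <= i <= j``, where ``u`` is the number of
superdiagonals. The posterior precision of the MAP decoder is symmetric
positive definite and banded (bandwidth set by the membrane-filter
support), so Newton updates, log-determinants and the posterior variance
are all computed in banded form.

The diagonal of the inverse (posterior variance) uses a block-tridiagonal
recursive Green's function (selected inversion) scheme: the banded matrix
is partitioned into blocks of the bandwidth size, making it block
tridiagonal, and the diagonal blocks of the inverse are obtained by a
forward-backward sweep in O(n * u^2) time without ever forming the dense
inverse.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg


def dense_to_banded(A: np.ndarray, u: int) -> np.ndarray:
    """Upper banded storage of a symmetric matrix with u superdiagonals."""
    n = A.shape[0]
    ab = np.zeros((u + 1, n))
    for d in range(min(u, n - 1) + 1):
        ab[u - d, d:] = np.diagonal(A, d)
    return ab


def banded_to_dense(ab: np.ndarray) -> np.ndarray:
    u = ab.shape[0] - 1
    n = ab.shape[1]
    A = np.zeros((n, n))
    for d in range(min(u, n - 1) + 1):
        diag = ab[u - d, d:]
        A += np.diag(diag, d)
        if d:
            A += np.diag(diag, -d)
    return A


def banded_block(ab: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
    """Dense copy of the (r0:r1, c0:c1) block of a symmetric banded matrix."""
    u = ab.shape[0] - 1
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    d = cols - rows
    out = np.zeros((r1 - r0, c1 - c0))
    inside = np.abs(d) <= u
    i = np.minimum(rows, cols)
    j = np.maximum(rows, cols)
    out[inside] = ab[(u + i - j)[inside], j[inside]]
    return out


def banded_logdet(ab: np.ndarray) -> float:
    """log-determinant of a symmetric positive definite banded matrix."""
    cb = linalg.cholesky_banded(ab, lower=False, check_finite=False)
    return float(2.0 * np.log(cb[-1]).sum())


def banded_solve(ab: np.ndarray, b: np.ndarray) -> np.ndarray:
    return linalg.solveh_banded(ab, b, check_finite=False)


def banded_inverse_diagonal(ab: np.ndarray) -> np.ndarray:
    """Diagonal of the inverse of a symmetric positive definite banded matrix.

    Block-tridiagonal RGF sweep with block size equal to the bandwidth.
    """
    u = ab.shape[0] - 1
    n = ab.shape[1]
    if u == 0:
        return 1.0 / ab[0]
    b = u
    if n <= 2 * b:
        return np.diagonal(np.linalg.inv(banded_to_dense(ab))).copy()
    bounds = list(range(0, n, b)) + [n]
    m = len(bounds) - 1
    D = [banded_block(ab, bounds[i], bounds[i + 1], bounds[i], bounds[i + 1])
         for i in range(m)]
    E = [banded_block(ab, bounds[i + 1], bounds[i + 2], bounds[i], bounds[i + 1])
         for i in range(m - 1)]
    gL = [None] * m
    gL[0] = np.linalg.inv(D[0])
    for i in range(1, m):
        gL[i] = np.linalg.inv(D[i] - E[i - 1] @ gL[i - 1] @ E[i - 1].T)
    diag = np.empty(n)
    G_next = gL[m - 1]
    diag[bounds[m - 1]:bounds[m]] = np.diagonal(G_next)
    for i in range(m - 2, -1, -1):
        t = E[i] @ gL[i]
        G = gL[i] + t.T @ G_next @ t
        diag[bounds[i]:bounds[i + 1]] = np.diagonal(G)
        G_next = G
    return diag
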