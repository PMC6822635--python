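"""Matrix norms and proximal operators shared by all solvers.

The two regularizers that drive every method in this package are the
:math:`\\ell_{2,1}` norm (sum of Euclidean row norms — induces whole-row,
i.e. joint-feature, sparsity) and the nuclear norm (sum of singular values —
the convex surrogate for rank).  Their proximal operators are the row-wise
group soft threshold and singular value thresholding (SVT) respectively;
both are non-expansive, which is what makes the alternating solvers built
on top of them stable.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "l21_norm",
    "nuclear_norm",
    "prox_nuclear",
    "prox_row_l21",
    "hinge_sum",
    "soft_threshold",
]

#: Singular values below this fraction of the largest are treated as zero.
SV_RTOL = 1e-10


def _as_matrix(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 1 or M.shape[1] < 1:
        raise InvalidInputError(f"expected a 2-D matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("matrix contains non-finite entries")
    return M


def l21_norm(M) -> float:
    """Sum over rows of the Euclidean norm of each row."""
    M = _as_matrix(M)
    return float(np.linalg.norm(M, axis=1).sum())


def nuclear_norm(M) -> float:
    """Sum of singular values of ``M``."""
    M = _as_matrix(M)
    return float(np.linalg.svd(M, compute_uv=False).sum())


def prox_nuclear(M, t: float) -> np.ndarray:
    """Singular value thresholding: prox of ``t * ||.||_*``.

    Computes the SVD ``M = U diag(s) V^T`` and returns
    ``U diag(max(s - t, 0)) V^T``, the unique minimizer of
    ``0.5 ||Z - M||_F^2 + t ||Z||_*``.
    """
    M = _as_matrix(M)
    if t < 0:
        raise InvalidParameterError(f"threshold t must be >= 0, got {t}")
    if t == 0:
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(M)
    return (U[:, keep] * s[keep]) @ Vt[keep]


def prox_row_l21(M, t: float) -> np.ndarray:
    """Row-wise group soft threshold: prox of ``t * ||.||_{2,1}``.

    Each row ``r`` is mapped to ``r * max(1 - t/||r||, 0)``; rows that are
    exactly zero stay zero (no epsilon is added).
    """
    M = _as_matrix(M)
    if t < 0:
        raise InvalidParameterError(f"threshold t must be >= 0, got {t}")
    norms = np.linalg.norm(M, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(1.0 - t / norms[nz], 0.0)
    return M * scale[:, None]


def hinge_sum(margins) -> float:
    """Total hinge loss ``sum_i max(0, 1 - m_i)`` over a sequence of margins."""
    m = np.asarray(margins, dtype=float)
    if not np.all(np.isfinite(m)):
        raise InvalidInputError("margins contain non-finite entries")
    return float(np.maximum(0.0, 1.0 - m).sum())


def soft_threshold(M, t: float) -> np.ndarray:
    """Elementwise soft threshold ``sign(M) * max(|M| - t, 0)`` (l1 prox)."""
    M = np.asarray(M, dtype=float)
    if t < 0:
        raise InvalidParameterError(f"threshold t must be >= 0, got {t}")
    return np.sign(M) * np.maximum(np.abs(M) - t, 0.0)
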