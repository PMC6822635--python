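"""Sparse and robust principal-component decompositions of feature matrices.

Six related programs, all built around a regression reformulation of PCA
(an orthonormal basis ``A`` and loadings ``B`` with ``A^T A = I``):

* ``spca_fit`` — elastic-net sparse PCA: squared loss + ridge + per-component
  lasso on the loadings.
* ``jspca_fit`` — joint sparse PCA: column-wise l2,1 loss (robust to outlier
  samples) + row-wise l2,1 penalty (joint feature selection).
* ``jgspca_fit`` — group sparse PCA: squared loss + group-Frobenius penalty
  forcing whole feature groups to zero together.
* ``orpca_fit`` — outlier-robust 2D PCA on matrix trials: ridge-penalized
  regression loadings ``Q`` with an orthonormal reconstruction basis ``P``.
* ``rjspca_fit`` — robust joint sparse 2D PCA: adds a row-wise l2,1 penalty
  on ``Q`` so uninformative columns of the trial matrices are discarded.
* ``rpca_decompose`` — principal component pursuit, splitting a matrix into
  a low-rank part plus sparse gross corruptions.

Data orientation for the vector variants: ``X`` is ``p x n`` with columns
as samples.  The 2D variants consume a sequence of ``a x b`` trial matrices
directly.  All solvers are deterministic given their input and record a
monotone non-increasing objective trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError
from .prox import l21_norm, nuclear_norm, prox_nuclear, soft_threshold

__all__ = [
    "LoadingsModel",
    "TwoDProjection",
    "LowRankSparse",
    "spca_fit",
    "jspca_fit",
    "jgspca_fit",
    "orpca_fit",
    "rjspca_fit",
    "rpca_decompose",
    "project",
]

#: IRLS smoothing for l2,1 terms (Huberized below this radius).
IRLS_EPS = 1e-6
#: Relative row-norm threshold below which a feature counts as discarded.
DISCARD_RTOL = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LoadingsModel:
    """Orthonormal basis ``A`` (p x k) and sparse loadings ``B`` (p x k)."""

    A: np.ndarray
    B: np.ndarray
    lambda1: float
    lambda2: object
    objective_trace: np.ndarray
    converged: bool

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Reconstruction ``A B^T X`` of column-sample data ``X``."""
        return self.A @ (self.B.T @ np.asarray(X, dtype=float))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Reduced representation ``B^T X`` (k x n)."""
        return self.B.T @ np.asarray(X, dtype=float)

    @property
    def support(self) -> np.ndarray:
        """Indices of features (rows of B) with non-negligible loading."""
        norms = np.linalg.norm(self.B, axis=1)
        top = norms.max()
        if top == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(norms > DISCARD_RTOL * top)


@dataclass
class TwoDProjection:
    """Regression loadings ``Q`` and orthonormal basis ``P`` (both b x k)."""

    Q: np.ndarray
    P: np.ndarray
    lambda_a: float
    lambda_b: float
    objective_trace: np.ndarray
    converged: bool

    @property
    def discarded_features(self) -> np.ndarray:
        """Column indices of the trial matrices discarded by row sparsity."""
        norms = np.linalg.norm(self.Q, axis=1)
        top = norms.max()
        if top == 0:
            return np.arange(len(norms))
        return np.flatnonzero(norms < DISCARD_RTOL * top)


@dataclass
class LowRankSparse:
    """Principal-component-pursuit split ``X = L + S``."""

    L: np.ndarray
    S: np.ndarray
    lam: float
    iterations: int
    primal_residual: float


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _procrustes(M: np.ndarray) -> np.ndarray:
    """argmax_{A^T A = I} <M, A> — the polar factor of M."""
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return U @ Vt


def _top_eigvecs(C: np.ndarray, k: int) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    return V[:, np.argsort(w)[::-1][:k]]


def _huber(t: np.ndarray) -> np.ndarray:
    # smoothed absolute value used in the recorded IRLS objectives:
    # h(t) = t for t >= eps, t^2/(2 eps) + eps/2 below — the function the
    # clamped IRLS weights exactly majorize, so the trace is provably monotone
    t = np.asarray(t, dtype=float)
    return np.where(t >= IRLS_EPS, t, t * t / (2 * IRLS_EPS) + IRLS_EPS / 2)


def _check_Xkp(X, k):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"X must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite entries")
    if not 1 <= k <= min(X.shape):
        raise InvalidParameterError(
            f"k must be in [1, min(p, n)] = [1, {min(X.shape)}], got {k}"
        )
    return X


# ---------------------------------------------------------------------------
# sparse PCA (elastic-net form)
# ---------------------------------------------------------------------------

def spca_fit(X, k: int, lambda1: float = 0.0, lambda2=0.0,
             max_iter: int = 200, tol: float = 1e-6) -> LoadingsModel:
    """Sparse PCA by alternating elastic-net regressions and Procrustes.

    Minimizes ``sum_i ||x_i - A B^T x_i||^2 + lambda1 sum_j ||b_j||^2
    + sum_j lambda2_j ||b_j||_1`` subject to ``A^T A = I``.  The B-step is
    one pass of exact coordinate descent per component on the Gram matrix
    ``C = X X^T``; the A-step is the polar factor of ``C B``.
    """
    X = _check_Xkp(X, k)
    p = X.shape[0]
    lam2 = np.broadcast_to(np.asarray(lambda2, dtype=float), (k,)).copy()
    if lambda1 < 0 or np.any(lam2 < 0):
        raise InvalidParameterError("penalties must be nonnegative")
    C = X @ X.T
    A = _top_eigvecs(C, k)
    B = A.copy()
    diagC = np.diag(C).copy()

    def objective(A, B):
        R = X - A @ (B.T @ X)
        return (float((R * R).sum()) + lambda1 * float((B * B).sum())
                + float((lam2 * np.abs(B).sum(axis=0)).sum()))

    trace = [objective(A, B)]
    converged = False
    for _ in range(max_iter):
        B_old = B.copy()
        # B-step: coordinate descent per component (components decouple)
        for j in range(k):
            c = C @ A[:, j]
            beta = B[:, j]
            for _sweep in range(50):
                max_delta = 0.0
                for u in range(p):
                    rho = c[u] - C[u] @ beta + diagC[u] * beta[u]
                    denom = diagC[u] + lambda1
                    if denom <= 0:
                        new = 0.0
                    else:
                        new = np.sign(rho) * max(abs(rho) - lam2[j] / 2, 0.0) / denom
                    max_delta = max(max_delta, abs(new - beta[u]))
                    beta[u] = new
                if max_delta < 1e-8:
                    break
            B[:, j] = beta
        # A-step: Procrustes on C B
        A = _procrustes(C @ B)
        trace.append(objective(A, B))
        if np.max(np.abs(B - B_old)) < tol:
            converged = True
            break
    return LoadingsModel(A=A, B=B, lambda1=lambda1, lambda2=lam2,
                         objective_trace=np.asarray(trace), converged=converged)


# ---------------------------------------------------------------------------
# joint sparse PCA (l2,1 loss and penalty, IRLS)
# ---------------------------------------------------------------------------

def jspca_fit(X, k: int, lam: float = 0.0, max_iter: int = 300,
              tol: float = 1e-6) -> LoadingsModel:
    """Joint sparse PCA: ``||X - A B^T X||_{2,1} + lam ||B||_{2,1}``.

    The loss sums residual norms over sample columns, which caps the
    influence of gross outlier samples; the penalty sums row norms of the
    loadings, selecting features jointly across all components.  Solved by
    IRLS with clamped weights ``1 / (2 max(||.||, eps))``: the B-step is a
    ridge-type closed form, the A-step a weighted Procrustes.  The recorded
    objective uses the eps-smoothed norm the weights exactly majorize, so
    the trace is monotone by construction.
    """
    X = _check_Xkp(X, k)
    if lam < 0:
        raise InvalidParameterError("lam must be >= 0")
    p = X.shape[0]
    C0 = X @ X.T
    A = _top_eigvecs(C0, k)
    B = A.copy()

    def objective(A, B):
        R = X - A @ (B.T @ X)
        return (float(_huber(np.linalg.norm(R, axis=0)).sum())
                + lam * float(_huber(np.linalg.norm(B, axis=1)).sum()))

    trace = [objective(A, B)]
    converged = False
    for _ in range(max_iter):
        R = X - A @ (B.T @ X)
        w = 1.0 / (2.0 * np.maximum(np.linalg.norm(R, axis=0), IRLS_EPS))
        d = 1.0 / (2.0 * np.maximum(np.linalg.norm(B, axis=1), IRLS_EPS))
        Cw = (X * w) @ X.T
        # B-step: (Cw + lam D) B = Cw A; lstsq covers the singular lam=0 case
        B = np.linalg.lstsq(Cw + lam * np.diag(d), Cw @ A, rcond=None)[0]
        # A-step: weighted Procrustes
        A = _procrustes(Cw @ B)
        obj = objective(A, B)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    return LoadingsModel(A=A, B=B, lambda1=0.0, lambda2=lam,
                         objective_trace=np.asarray(trace), converged=converged)


# ---------------------------------------------------------------------------
# joint group sparse PCA
# ---------------------------------------------------------------------------

def jgspca_fit(X, k: int, lam: float = 0.0, groups: Sequence = None,
               max_iter: int = 300, tol: float = 1e-8) -> LoadingsModel:
    """Group sparse PCA: squared loss + ``lam sum_g eta_g ||B_g||_F``.

    ``groups`` partitions the feature indices; ``eta_g = sqrt(|g|)`` scales
    each group's penalty by its size.  The B-step is proximal gradient
    (group soft threshold) with the exact Lipschitz step ``1 / (2 lmax(C))``,
    so entire groups hit exact zeros; the A-step is Procrustes.
    """
    X = _check_Xkp(X, k)
    if lam < 0:
        raise InvalidParameterError("lam must be >= 0")
    p = X.shape[0]
    if groups is None:
        groups = [[i] for i in range(p)]
    groups = [np.asarray(g, dtype=int) for g in groups]
    flat = np.concatenate(groups) if groups else np.array([], dtype=int)
    if len(flat) != p or len(np.unique(flat)) != p or flat.min() < 0 or flat.max() >= p:
        raise InvalidParameterError("groups must partition the feature indices")
    eta = np.array([np.sqrt(len(g)) for g in groups])

    C = X @ X.T
    L = 2.0 * float(np.linalg.eigvalsh(C)[-1])
    step = 1.0 / L if L > 0 else 1.0
    A = _top_eigvecs(C, k)
    B = A.copy()

    def objective(A, B):
        R = X - A @ (B.T @ X)
        pen = sum(eta[i] * np.linalg.norm(B[g]) for i, g in enumerate(groups))
        return float((R * R).sum()) + lam * float(pen)

    trace = [objective(A, B)]
    converged = False
    for _ in range(max_iter):
        # B-step: one proximal-gradient step on the quadratic (Hessian 2C)
        grad = 2.0 * (C @ (B - A))
        Z = B - step * grad
        for i, g in enumerate(groups):
            blk = Z[g]
            nrm = np.linalg.norm(blk)
            thr = step * lam * eta[i]
            Z[g] = blk * max(1.0 - thr / nrm, 0.0) if nrm > 0 else 0.0
        B = Z
        A = _procrustes(C @ B)
        obj = objective(A, B)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    return LoadingsModel(A=A, B=B, lambda1=0.0, lambda2=lam,
                         objective_trace=np.asarray(trace), converged=converged)


# ---------------------------------------------------------------------------
# 2D variants on matrix trials
# ---------------------------------------------------------------------------

def _scatter(trials) -> tuple:
    trials = [np.asarray(T, dtype=float) for T in trials]
    if not trials:
        raise InvalidInputError("need at least one trial")
    b = trials[0].shape[1]
    for T in trials:
        if T.ndim != 2 or T.shape[1] != b:
            raise InvalidInputError("all trials must share their column count")
        if not np.all(np.isfinite(T)):
            raise InvalidInputError("trial contains non-finite entries")
    Sc = np.zeros((b, b))
    total = 0.0
    for T in trials:
        Sc += T.T @ T
        total += float((T * T).sum())
    return trials, Sc, total


def orpca_fit(trials, k: int, lambda_a: float = 0.0, max_iter: int = 200,
              tol: float = 1e-6) -> TwoDProjection:
    """Outlier-robust 2D PCA with ridge-relaxed loadings.

    Minimizes ``sum_j ||X_j - X_j Q P^T||_F^2 + lambda_a ||Q||_F^2`` with
    ``P^T P = I``.  Q-step is the ridge closed form
    ``(S + lambda_a I)^{-1} S P`` with ``S = sum_j X_j^T X_j``; P-step is
    the polar factor of ``S Q``.  With ``lambda_a = 0`` this is classical
    2D PCA (the top-k eigenvectors of the column scatter).
    """
    if lambda_a < 0:
        raise InvalidParameterError("lambda_a must be >= 0")
    trials, Sc, total = _scatter(trials)
    b = Sc.shape[0]
    if not 1 <= k <= b:
        raise InvalidParameterError(f"k must be in [1, {b}], got {k}")
    P = _top_eigvecs(Sc, k)
    Q = P.copy()

    def objective(Q, P):
        # sum ||X_j - X_j Q P^T||^2 = total - 2 tr(Q^T S P) + tr(Q^T S Q)
        return (total - 2.0 * float(np.trace(Q.T @ Sc @ P))
                + float(np.trace(Q.T @ Sc @ Q))
                + lambda_a * float((Q * Q).sum()))

    trace = [objective(Q, P)]
    converged = False
    reg = Sc + lambda_a * np.eye(b)
    for _ in range(max_iter):
        Q = np.linalg.lstsq(reg, Sc @ P, rcond=None)[0]
        P = _procrustes(Sc @ Q)
        obj = objective(Q, P)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    return TwoDProjection(Q=Q, P=P, lambda_a=lambda_a, lambda_b=0.0,
                          objective_trace=np.asarray(trace), converged=converged)


def rjspca_fit(trials, k: int, lambda_a: float = 0.0, lambda_b: float = 0.0,
               max_iter: int = 200, tol: float = 1e-6) -> TwoDProjection:
    """Robust joint sparse 2D PCA: adds ``lambda_b ||Q||_{2,1}`` to ORPCA.

    The row-sparsity penalty zeroes whole rows of ``Q``, i.e. discards
    whole columns (features) of the trial matrices jointly across all
    components.  The Q-step becomes IRLS ridge with the clamped diagonal
    reweighting ``D = diag(1 / (2 max(||q_i||, eps)))``; the recorded
    objective uses the matching eps-smoothed row norm, so the trace is
    monotone.  Rows whose norm falls below ``1e-6 x`` the largest are
    reported via :attr:`TwoDProjection.discarded_features`.
    """
    if lambda_a < 0 or lambda_b < 0:
        raise InvalidParameterError("penalties must be >= 0")
    trials, Sc, total = _scatter(trials)
    b = Sc.shape[0]
    if not 1 <= k <= b:
        raise InvalidParameterError(f"k must be in [1, {b}], got {k}")
    P = _top_eigvecs(Sc, k)
    Q = P.copy()

    def objective(Q, P):
        return (total - 2.0 * float(np.trace(Q.T @ Sc @ P))
                + float(np.trace(Q.T @ Sc @ Q))
                + lambda_a * float((Q * Q).sum())
                + lambda_b * float(_huber(np.linalg.norm(Q, axis=1)).sum()))

    trace = [objective(Q, P)]
    converged = False
    for _ in range(max_iter):
        d = 1.0 / (2.0 * np.maximum(np.linalg.norm(Q, axis=1), IRLS_EPS))
        Q = np.linalg.lstsq(Sc + lambda_a * np.eye(b) + lambda_b * np.diag(d),
                            Sc @ P, rcond=None)[0]
        P = _procrustes(Sc @ Q)
        obj = objective(Q, P)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    return TwoDProjection(Q=Q, P=P, lambda_a=lambda_a, lambda_b=lambda_b,
                          objective_trace=np.asarray(trace), converged=converged)


def project(model: TwoDProjection, trial) -> np.ndarray:
    """Reduced representation ``X Q`` of one trial; reconstruction is
    ``X Q P^T``."""
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.Q.shape[0]:
        raise InvalidInputError(
            f"trial has {X.shape} but model expects {model.Q.shape[0]} columns"
        )
    return X @ model.Q


# ---------------------------------------------------------------------------
# principal component pursuit
# ---------------------------------------------------------------------------

def rpca_decompose(X, lam: Optional[float] = None, max_iter: int = 1000,
                   tol: float = 1e-7, sparse_mode: str = "l1") -> LowRankSparse:
    """Robust PCA / principal component pursuit: ``X = L + S``.

    Solves ``min ||L||_* + lam ||S||_1  s.t.  X = L + S`` by the inexact
    augmented Lagrangian method: singular value thresholding on ``L``,
    elementwise soft thresholding on ``S`` (or a column-wise group soft
    threshold when ``sparse_mode='l21cols'``), then a dual update.  The
    default ``lam = 1/sqrt(max(m, n))`` is the standard universal choice.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"X must be 2-D, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite entries")
    if sparse_mode not in ("l1", "l21cols"):
        raise InvalidParameterError(f"unknown sparse_mode {sparse_mode!r}")
    m, n = X.shape
    if lam is None:
        lam = 1.0 / np.sqrt(max(m, n))
    if lam <= 0:
        raise InvalidParameterError("lam must be > 0")
    normX = np.linalg.norm(X)
    if normX == 0:
        return LowRankSparse(L=np.zeros_like(X), S=np.zeros_like(X),
                             lam=lam, iterations=0, primal_residual=0.0)
    norm_two = np.linalg.norm(X, 2)
    norm_inf = np.abs(X).max() / lam
    Y = X / max(norm_two, norm_inf)
    mu = 1.25 / norm_two
    mu_bar = mu * 1e7
    rho = 1.5
    L = np.zeros_like(X)
    S = np.zeros_like(X)
    it = 0
    res = np.inf
    for it in range(1, max_iter + 1):
        L = prox_nuclear(X - S + Y / mu, 1.0 / mu)
        G = X - L + Y / mu
        if sparse_mode == "l1":
            S = soft_threshold(G, lam / mu)
        else:
            col = np.linalg.norm(G, axis=0)
            scale = np.zeros_like(col)
            nz = col > 0
            scale[nz] = np.maximum(1.0 - (lam / mu) / col[nz], 0.0)
            S = G * scale[None, :]
        Z = X - L - S
        Y = Y + mu * Z
        mu = min(mu * rho, mu_bar)
        res = np.linalg.norm(Z) / normX
        if res < tol:
            break
    return LowRankSparse(L=L, S=S, lam=lam, iterations=it,
                         primal_residual=float(res))
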