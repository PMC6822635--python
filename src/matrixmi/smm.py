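"""Support matrix machines: a vectorized SVM baseline and the robust SMM.

The robust support matrix machine (RSMM) classifies trials that are
naturally matrices (channels x feature columns) without vectorizing them.
For a binary problem with labels ``y_i = +/-1`` it solves

    min_{W, b}  gamma ||W||_{2,1} + tau ||W||_*
                + C sum_i max(0, 1 - y_i (tr(W^T X_i) + b))

— a hinge loss with a "spectral elastic net" penalty: the l2,1 term selects
rows (channels) jointly, the nuclear norm exploits the correlation between
rows and columns by keeping the regression matrix low rank.  Multiclass
problems are handled one-vs-rest with a shared (gamma, tau, C).

The solver is consensus ADMM with three blocks: the hinge subproblem
(a proximal linear SVM solved by dual coordinate descent with exact 1-D
minimization over the unpenalized offset b), singular value thresholding,
and the row-wise group soft threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.svm import SVC

from .exceptions import InvalidInputError, InvalidParameterError
from .preprocessing import FeatureTensor
from .prox import hinge_sum, l21_norm, nuclear_norm, prox_nuclear, prox_row_l21

__all__ = [
    "SMMModel",
    "svm_baseline_fit",
    "rsmm_fit_binary",
    "rsmm_fit_multiclass",
    "smm_predict",
    "smm_decision_values",
    "rsmm_objective",
]


@dataclass
class SMMModel:
    """Per-class regression matrices and offsets with their hyperparameters."""

    classes: np.ndarray
    W: np.ndarray          # (n_classes, p, q)
    b: np.ndarray          # (n_classes,)
    gamma: float
    tau: float
    C: float
    solver_trace: list = field(default_factory=list)

    @property
    def matrix_shape(self) -> tuple:
        return self.W.shape[1:]


def _check_features(features: FeatureTensor, min_classes: int = 2):
    classes = np.unique(features.labels)
    if len(classes) < min_classes:
        raise InvalidInputError(
            f"need >= {min_classes} classes, got {len(classes)}"
        )
    return classes


def rsmm_objective(W, b, X, y, gamma, tau, C) -> float:
    """The RSMM objective at (W, b) for +/-1 labels ``y``."""
    margins = y * (np.einsum("pq,npq->n", W, X) + b)
    return gamma * l21_norm(W) + tau * nuclear_norm(W) + C * hinge_sum(margins)


# ---------------------------------------------------------------------------
# vectorized SVM baseline
# ---------------------------------------------------------------------------

def svm_baseline_fit(features: FeatureTensor, C: float = 1.0) -> SMMModel:
    """Classical soft-margin linear SVM on vectorized feature matrices.

    Since ``tr(W^T X) = vec(W)^T vec(X)``, this is the exact vector
    counterpart of the matrix-form SVM; it serves as the reference the
    matrix methods are compared against.  One-vs-rest for > 2 classes.
    """
    if C <= 0:
        raise InvalidParameterError(f"C must be > 0, got {C}")
    classes = _check_features(features)
    Xv = features.flatten()
    p, q = features.matrix_shape
    W = np.zeros((len(classes), p, q))
    b = np.zeros(len(classes))
    if len(classes) == 2:
        y = np.where(features.labels == classes[1], 1, -1)
        clf = SVC(kernel="linear", C=C, tol=1e-8).fit(Xv, y)
        w = clf.coef_[0].reshape(p, q)
        W[1], b[1] = w, clf.intercept_[0]
        W[0], b[0] = -w, -clf.intercept_[0]
    else:
        for j, cls in enumerate(classes):
            y = np.where(features.labels == cls, 1, -1)
            clf = SVC(kernel="linear", C=C, tol=1e-8).fit(Xv, y)
            W[j] = clf.coef_[0].reshape(p, q)
            b[j] = clf.intercept_[0]
    return SMMModel(classes=classes, W=W, b=b, gamma=0.0, tau=0.0, C=C)


# ---------------------------------------------------------------------------
# hinge subproblem:  min_w  rho/2 ||w - v||^2 + C sum hinge(y (w.x + b))
# ---------------------------------------------------------------------------

def _best_offset(scores: np.ndarray, y: np.ndarray) -> float:
    # exact minimizer over b of sum_i max(0, 1 - y_i (s_i + b)):
    # convex piecewise linear, so the minimum sits at a breakpoint b = y_i - s_i
    cand = y - scores
    losses = [np.maximum(0.0, 1.0 - y * (scores + bc)).sum() for bc in cand]
    return float(cand[int(np.argmin(losses))])


def _prox_hinge_svm(Xv, y, v, b0, rho, C, alpha0=None, inner_tol=1e-8,
                    max_rounds=50):
    """Proximal hinge minimization by dual coordinate descent + exact b.

    Warm-startable through ``alpha0`` (the dual variables of a previous
    call); the primal is reconstructed as ``w = v + (1/rho) sum a_i y_i x_i``.
    """
    n = len(y)
    sq = (Xv * Xv).sum(axis=1)
    alpha = np.zeros(n) if alpha0 is None else np.clip(alpha0, 0.0, C)
    w = v + (Xv.T @ (alpha * y)) / rho
    b = b0

    def primal():
        return (0.5 * rho * float(((w - v) ** 2).sum())
                + C * float(np.maximum(0.0, 1.0 - y * (Xv @ w + b)).sum()))

    prev = primal()
    for _ in range(max_rounds):
        for i in range(n):
            if sq[i] == 0:
                continue
            g = 1.0 - y[i] * (Xv[i] @ w + b)
            new = min(max(alpha[i] + rho * g / sq[i], 0.0), C)
            if new != alpha[i]:
                w = w + ((new - alpha[i]) * y[i] / rho) * Xv[i]
                alpha[i] = new
        b = _best_offset(Xv @ w, y)
        cur = primal()
        if abs(prev - cur) <= inner_tol * max(1.0, abs(prev)):
            break
        prev = cur
    return w, b, alpha


# ---------------------------------------------------------------------------
# robust SMM
# ---------------------------------------------------------------------------

def _rsmm_binary_arrays(X, y, gamma, tau, C, rho=1.0, max_iter=500,
                        tol=1e-4):
    n, p, q = X.shape
    # center the trials and absorb the mean into b: makes the decision
    # function exactly invariant to a constant shift of every trial and
    # conditions the hinge subproblem
    Xmean = X.mean(axis=0)
    X = X - Xmean
    Xv = X.reshape(n, p * q)
    d = p * q
    Z = np.zeros((p, q))
    W0 = np.zeros((p, q))
    W1 = np.zeros((p, q))
    W2 = np.zeros((p, q))
    U0 = np.zeros((p, q))
    U1 = np.zeros((p, q))
    U2 = np.zeros((p, q))
    b = 0.0
    trace = []
    scale = np.sqrt(3 * d)
    converged = False
    best_obj = np.inf
    best_W = Z
    best_b = b
    alpha = None
    for it in range(max_iter):
        w0, b, alpha = _prox_hinge_svm(Xv, y, (Z - U0).ravel(), b, rho, C,
                                       alpha0=alpha, max_rounds=25)
        W0 = w0.reshape(p, q)
        W1 = prox_nuclear(Z - U1, tau / rho) if tau > 0 else Z - U1
        W2 = prox_row_l21(Z - U2, gamma / rho) if gamma > 0 else Z - U2
        Z_old = Z
        Z = (W0 + U0 + W1 + U1 + W2 + U2) / 3.0
        U0 = U0 + W0 - Z
        U1 = U1 + W1 - Z
        U2 = U2 + W2 - Z
        r = np.sqrt(((W0 - Z) ** 2).sum() + ((W1 - Z) ** 2).sum()
                    + ((W2 - Z) ** 2).sum())
        s = rho * np.sqrt(3.0) * np.linalg.norm(Z - Z_old)
        # the candidate iterate carries exact structure from its prox block:
        # exact low rank when tau > 0, exact row sparsity when only gamma > 0
        if tau > 0:
            cand = W1
        elif gamma > 0:
            cand = W2
        else:
            cand = W0
        obj = rsmm_objective(cand, b, X, y, gamma, tau, C)
        # splitting iterates are mildly nonmonotone; keep the incumbent
        if obj < best_obj:
            best_obj, best_W, best_b = obj, cand, b
        trace.append({"objective": best_obj, "objective_raw": obj,
                      "primal": r / scale, "dual": s / scale})
        if max(r, s) / scale < tol:
            converged = True
            break
        # residual balancing keeps the primal and dual residuals comparable
        if r > 10.0 * s:
            rho *= 2.0
            U0, U1, U2 = U0 / 2.0, U1 / 2.0, U2 / 2.0
        elif s > 10.0 * r:
            rho /= 2.0
            U0, U1, U2 = U0 * 2.0, U1 * 2.0, U2 * 2.0
    best_b = best_b - float(np.vdot(best_W, Xmean))
    return best_W, best_b, trace, converged


def rsmm_fit_binary(features: FeatureTensor, gamma: float = 0.1,
                    tau: float = 0.1, C: float = 1.0, rho: float = 1.0,
                    max_iter: int = 500, tol: float = 1e-4) -> SMMModel:
    """Fit the robust support matrix machine on a two-class feature set.

    Labels are mapped to -1 (lower class id) / +1 (higher class id); the
    returned model stores ``(+W, +b)`` for the positive class and the
    negation for the negative class so that prediction is a uniform argmax.
    """
    if gamma < 0 or tau < 0:
        raise InvalidParameterError("gamma and tau must be >= 0")
    if C <= 0:
        raise InvalidParameterError("C must be > 0")
    classes = _check_features(features)
    if len(classes) != 2:
        raise InvalidInputError(f"rsmm_fit_binary needs 2 classes, got {len(classes)}")
    y = np.where(features.labels == classes[1], 1.0, -1.0)
    Z, b, trace, converged = _rsmm_binary_arrays(
        features.features, y, gamma, tau, C, rho=rho, max_iter=max_iter, tol=tol
    )
    W = np.stack([-Z, Z])
    return SMMModel(classes=classes, W=W, b=np.array([-b, b]),
                    gamma=gamma, tau=tau, C=C, solver_trace=[trace])


def rsmm_fit_multiclass(features: FeatureTensor, gamma: float = 0.1,
                        tau: float = 0.1, C: float = 1.0, rho: float = 1.0,
                        max_iter: int = 500, tol: float = 1e-4) -> SMMModel:
    """One-vs-rest robust SMM: one binary problem per class, shared
    (gamma, tau, C)."""
    import warnings

    if gamma < 0 or tau < 0:
        raise InvalidParameterError("gamma and tau must be >= 0")
    if C <= 0:
        raise InvalidParameterError("C must be > 0")
    classes = _check_features(features)
    if len(classes) == 2:
        return rsmm_fit_binary(features, gamma, tau, C, rho=rho,
                               max_iter=max_iter, tol=tol)
    p, q = features.matrix_shape
    W = np.zeros((len(classes), p, q))
    b = np.zeros(len(classes))
    traces = []
    for j, cls in enumerate(classes):
        n_cls = int((features.labels == cls).sum())
        if n_cls < 2:
            warnings.warn(f"class {cls!r} has only {n_cls} sample(s); "
                          "fitting anyway", stacklevel=2)
        y = np.where(features.labels == cls, 1.0, -1.0)
        Z, bj, trace, _ = _rsmm_binary_arrays(
            features.features, y, gamma, tau, C, rho=rho,
            max_iter=max_iter, tol=tol
        )
        W[j], b[j] = Z, bj
        traces.append(trace)
    return SMMModel(classes=classes, W=W, b=b, gamma=gamma, tau=tau, C=C,
                    solver_trace=traces)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def smm_decision_values(model: SMMModel, features: FeatureTensor) -> np.ndarray:
    """Decision matrix ``tr(W_j^T X_i) + b_j`` of shape (n_trials, n_classes)."""
    if features.matrix_shape != model.matrix_shape:
        raise InvalidInputError(
            f"feature shape {features.matrix_shape} != model shape "
            f"{model.matrix_shape}"
        )
    return np.einsum("kpq,npq->nk", model.W, features.features) + model.b


def smm_predict(model: SMMModel, features: FeatureTensor) -> np.ndarray:
    """Argmax over per-class decision values; ties go to the lowest class id."""
    scores = smm_decision_values(model, features)
    return model.classes[np.argmax(scores, axis=1)]


def rsmm_grid_search(features: FeatureTensor, grid=None, C: float = 1.0,
                     n_folds: int = 3, seed: int = 0):
    """Pick (gamma, tau) by cross-validated accuracy over a log grid.

    A convenience helper, not a mandated part of the pipeline; the default
    grid spans 10^-3 .. 10^2.
    """
    from .evaluation import stratified_kfold

    if grid is None:
        grid = [10.0 ** e for e in range(-3, 3)]
    folds = stratified_kfold(features.labels, n_folds, seed)
    all_idx = np.arange(features.n_trials)
    best = None
    for gamma in grid:
        for tau in grid:
            accs = []
            for val in folds:
                train = np.setdiff1d(all_idx, val)
                model = rsmm_fit_multiclass(features.subset(train),
                                            gamma=gamma, tau=tau, C=C)
                pred = smm_predict(model, features.subset(val))
                accs.append(float(np.mean(pred == features.labels[val])))
            score = float(np.mean(accs))
            if best is None or score > best[0]:
                best = (score, gamma, tau)
    return {"accuracy": best[0], "gamma": best[1], "tau": best[2]}
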