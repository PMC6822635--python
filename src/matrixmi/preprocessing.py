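"""Preprocessing for matrix-variate EEG trials.

Covers the front half of a motor-imagery pipeline: statistical sample
sizing with finite-population correction, segmentation of a long recording
into near-equal stationary windows, Neyman-style allocation of a sampling
budget across windows, a zero-phase band-pass filter bank, common spatial
patterns (CSP) with channel selection, Hjorth-style time-domain-parameter
(TDP) features, and mutual-information ranking of filter-bank features
(the selection stage of FBCSP).

All trial data flows through :class:`TrialSet`: a labeled collection of
equal-shape ``channels x time`` matrices with a sampling rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.signal

from .exceptions import (
    DegenerateAllocationError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "TrialSet",
    "SampleSizeSpec",
    "WindowPlan",
    "CSPModel",
    "FilterBankSpec",
    "FeatureTensor",
    "compute_sample_size",
    "segment_signal",
    "allocate_samples",
    "bandpass_filterbank",
    "csp_fit",
    "csp_transform",
    "select_channels",
    "tdp_features",
    "fbcsp_select",
]

#: Additive guard inside log-variance features.
LOG_EPS = 1e-12
#: Ridge added to a numerically singular pooled covariance in CSP.
CSP_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrialSet:
    """Labeled collection of equal-shape ``channels x time`` trial matrices.

    Parameters
    ----------
    trials : ndarray, shape (n_trials, channels, T)
        Trial data. A sequence of 2-D matrices is also accepted and stacked.
    labels : ndarray, shape (n_trials,)
        Class identifier per trial.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str, optional
        Defaults to ``ch0 .. ch{c-1}``.
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.trials.ndim == 2 and len(self.trials) == 0:
            # empty set: allow (0, c, T) or an empty list
            self.trials = self.trials.reshape(0, 0, 0)
        if self.trials.ndim != 3:
            raise InvalidInputError(
                f"trials must stack to (n, channels, T), got shape {self.trials.shape}"
            )
        if len(self.labels) != len(self.trials):
            raise InvalidInputError(
                f"{len(self.trials)} trials but {len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        elif self.n_trials > 0 and len(self.channel_names) != self.n_channels:
            raise InvalidInputError("channel_names length != number of channels")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(self.trials[idx], self.labels[idx], self.fs,
                        list(self.channel_names))


@dataclass
class SampleSizeSpec:
    """Result of the sample-size calculation ``n0 = Z^2 p (1-p) / e^2``."""

    p: float
    Z: float
    e: float
    N: Optional[int]
    n0: float
    n: int  # ceil of the (possibly finite-population-corrected) size


@dataclass
class WindowPlan:
    """Allocation of a sampling budget across signal windows.

    ``window_lengths`` is optional metadata (the segmentation that produced
    the per-window statistics); ``fractions`` sum to 1 and ``counts`` to
    the allocated budget.
    """

    window_lengths: Optional[np.ndarray]
    N_i: np.ndarray
    Var: np.ndarray
    fractions: np.ndarray
    counts: np.ndarray


@dataclass
class CSPModel:
    """Common-spatial-pattern filters for one class pair.

    ``filters`` rows are spatial filters sorted by eigenvalue (class-1 view)
    descending; they jointly whiten the pooled covariance:
    ``F (S1 + S2) F^T = I``. ``eigenvalues[i]`` is the fraction of pooled
    variance component ``i`` captures for ``class_pair[0]``; the class-2
    fraction is ``1 - eigenvalues[i]``.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    class_pair: tuple


@dataclass
class FilterBankSpec:
    """Band edges (Hz) and IIR order for the band-pass filter bank."""

    bands: Sequence[tuple] = (
        (4, 8), (8, 12), (12, 16), (16, 20), (20, 24),
        (24, 28), (28, 32), (32, 36), (36, 40),
    )
    filter_order: int = 4


@dataclass
class FeatureTensor:
    """Per-trial feature matrices aligned with labels.

    ``features`` has shape ``(n_trials, rows, cols)`` where rows index
    channels or CSP components and cols index feature kinds (e.g. derivative
    order for TDP, band for a stacked filter bank).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 3:
            raise InvalidInputError(
                f"features must stack to (n, rows, cols), got {self.features.shape}"
            )
        if len(self.labels) != len(self.features):
            raise InvalidInputError("features and labels misaligned")
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[2])]

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def matrix_shape(self) -> tuple:
        return self.features.shape[1:]

    def flatten(self) -> np.ndarray:
        """Vectorize each feature matrix: shape (n_trials, rows*cols)."""
        return self.features.reshape(self.n_trials, -1)

    def subset(self, idx) -> "FeatureTensor":
        idx = np.asarray(idx)
        return FeatureTensor(self.features[idx], self.labels[idx],
                             list(self.feature_names))


# ---------------------------------------------------------------------------
# sample sizing and windowing
# ---------------------------------------------------------------------------

def compute_sample_size(p: float, Z: float, e: float,
                        N: Optional[int] = None) -> SampleSizeSpec:
    """Sample size for estimating a proportion at a given confidence.

    ``n0 = Z^2 p (1 - p) / e^2``; with a finite population of size ``N`` the
    correction ``n = n0 / (1 + (n0 - 1)/N)`` applies.  ``n`` is reported
    rounded up (conservative).
    """
    if not 0 <= p <= 1:
        raise InvalidParameterError(f"p must be in [0, 1], got {p}")
    if not e > 0:
        raise InvalidParameterError(f"margin of error e must be > 0, got {e}")
    if not Z > 0:
        raise InvalidParameterError(f"Z must be > 0, got {Z}")
    if N is not None and N < 1:
        raise InvalidParameterError(f"population size N must be >= 1, got {N}")
    n0 = Z * Z * p * (1.0 - p) / (e * e)
    if N is None:
        n = math.ceil(n0)
    else:
        n = math.ceil(n0 / (1.0 + (n0 - 1.0) / N))
    return SampleSizeSpec(p=p, Z=Z, e=e, N=N, n0=n0, n=n)


def segment_signal(total_length: int, n_windows: int) -> np.ndarray:
    """Contiguous near-equal window lengths; the remainder goes to the last.

    ``segment_signal(4097, 4) -> [1024, 1024, 1024, 1025]``.
    """
    if n_windows < 1:
        raise InvalidParameterError(f"n_windows must be >= 1, got {n_windows}")
    if n_windows > total_length:
        raise InvalidParameterError(
            f"cannot cut {total_length} samples into {n_windows} windows"
        )
    base = total_length // n_windows
    lengths = np.full(n_windows, base, dtype=int)
    lengths[-1] += total_length - base * n_windows
    return lengths


def allocate_samples(N_i, Var, budget: int) -> WindowPlan:
    """Allocate a sampling budget across windows by size-and-variance weight.

    Window ``i`` receives the fraction
    ``N_i sqrt(sum_j Var_{i,j}^2) / sum_k N_k sqrt(sum_j Var_{k,j}^2)``
    of the budget; integer counts use largest-remainder rounding so they
    sum exactly to the budget.
    """
    N_i = np.asarray(N_i, dtype=float)
    Var = np.atleast_2d(np.asarray(Var, dtype=float))
    if np.any(N_i <= 0):
        raise InvalidParameterError("all window sizes N_i must be > 0")
    if np.any(Var < 0):
        raise InvalidParameterError("variances must be nonnegative")
    if budget < 0:
        raise InvalidParameterError("budget must be >= 0")
    if len(N_i) != Var.shape[0]:
        raise InvalidInputError("N_i and Var row count disagree")
    weights = N_i * np.sqrt((Var ** 2).sum(axis=1))
    total = weights.sum()
    if total == 0:
        raise DegenerateAllocationError(
            "all window variances are zero: allocation weights undefined"
        )
    fractions = weights / total
    raw = fractions * budget
    counts = np.floor(raw).astype(int)
    short = budget - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return WindowPlan(window_lengths=None, N_i=N_i, Var=Var,
                      fractions=fractions, counts=counts)


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

def bandpass_filterbank(ts: TrialSet, spec: FilterBankSpec = None) -> list:
    """Zero-phase band-pass filter the trials once per band.

    Returns one :class:`TrialSet` per band, shapes preserved.  Uses a
    forward-backward Butterworth filter (``sosfiltfilt``) so no phase lag
    is introduced.
    """
    if spec is None:
        spec = FilterBankSpec()
    nyq = ts.fs / 2.0
    out = []
    for (low, high) in spec.bands:
        if not (0 < low < high < nyq):
            raise InvalidParameterError(
                f"band ({low}, {high}) Hz invalid for fs={ts.fs} Hz"
            )
        sos = scipy.signal.butter(spec.filter_order, [low, high],
                                  btype="bandpass", fs=ts.fs, output="sos")
        filtered = (scipy.signal.sosfiltfilt(sos, ts.trials, axis=2)
                    if ts.n_trials else ts.trials.copy())
        out.append(TrialSet(filtered, ts.labels.copy(), ts.fs,
                            list(ts.channel_names)))
    return out


# ---------------------------------------------------------------------------
# common spatial patterns
# ---------------------------------------------------------------------------

def _class_covariance(trials: np.ndarray) -> np.ndarray:
    # per-trial X X^T / trace(X X^T), averaged — the trace normalization makes
    # the result invariant to global amplitude scaling
    covs = []
    for X in trials:
        C = X @ X.T
        tr = np.trace(C)
        if tr <= 0:
            raise InvalidInputError("trial with zero total variance in csp_fit")
        covs.append(C / tr)
    return np.mean(covs, axis=0)


def csp_fit(ts: TrialSet, class_pair) -> CSPModel:
    """Fit CSP filters discriminating two classes by variance ratio.

    Solves the generalized eigenproblem ``S1 w = lambda (S1 + S2) w`` on
    trace-normalized average class covariances; eigenvalues lie in [0, 1]
    and filters are sorted by eigenvalue descending (top filters maximize
    class-1 variance share, bottom filters class-2's).
    """
    a, b = class_pair
    present = set(np.unique(ts.labels).tolist())
    if a not in present or b not in present:
        raise InvalidInputError(f"class pair {class_pair} not both present")
    Xa = ts.trials[ts.labels == a]
    Xb = ts.trials[ts.labels == b]
    if len(Xa) < 2 or len(Xb) < 2:
        raise InvalidInputError("csp_fit needs >= 2 trials per class")
    S1 = _class_covariance(Xa)
    S2 = _class_covariance(Xb)
    pooled = S1 + S2
    evals_pooled = np.linalg.eigvalsh(pooled)
    if evals_pooled[0] < CSP_RIDGE * evals_pooled[-1]:
        pooled = pooled + CSP_RIDGE * evals_pooled[-1] * np.eye(len(pooled))
    w, V = scipy.linalg.eigh(S1, pooled)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, 1.0)
    # scipy normalizes v^T B v = 1, so rows of V^T whiten the pooled covariance
    filters = V[:, order].T
    return CSPModel(filters=filters, eigenvalues=w, class_pair=(a, b))


def csp_transform(model: CSPModel, ts: TrialSet, m: int) -> FeatureTensor:
    """Log-variance features from the ``m`` top and ``m`` bottom CSP filters.

    Per trial the 2m selected filters are applied and the feature is the log
    of each component's share of the projected variance — a ``2m x 1``
    feature matrix per trial.
    """
    c = model.filters.shape[0]
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    if 2 * m > c:
        raise InvalidParameterError(f"2m={2*m} exceeds {c} available filters")
    F = np.vstack([model.filters[:m], model.filters[c - m:]])
    feats = np.empty((ts.n_trials, 2 * m, 1))
    for i, X in enumerate(ts.trials):
        Y = F @ X
        v = Y.var(axis=1)
        feats[i, :, 0] = np.log(v / max(v.sum(), LOG_EPS) + LOG_EPS)
    return FeatureTensor(feats, ts.labels.copy(), feature_names=["logvar"])


def select_channels(model: CSPModel, n_ch: int):
    """Rank channels by their weight in the two extreme CSP filters.

    Each extreme filter (first = class-1-dominant, last = class-2-dominant)
    is normalized to unit length — the generalized-eigenvector scaling would
    otherwise inflate coefficients on low-variance channels — and weighted
    by its discriminative strength ``2|lambda - 1/2|``.  A channel's score
    is its maximum weighted absolute coefficient across the two; returns the
    top ``n_ch`` channel indices, lower index winning ties.
    """
    c = model.filters.shape[1]
    if not 1 <= n_ch <= c:
        raise InvalidParameterError(f"n_ch must be in [1, {c}], got {n_ch}")
    scores = np.zeros(c)
    for idx in (0, -1):
        f = model.filters[idx]
        nrm = np.linalg.norm(f)
        if nrm == 0:
            continue
        strength = 2.0 * abs(model.eigenvalues[idx] - 0.5)
        scores = np.maximum(scores, strength * np.abs(f) / nrm)
    order = np.lexsort((np.arange(c), -scores))
    return np.asarray(order[:n_ch])


# ---------------------------------------------------------------------------
# time-domain parameters (Hjorth-style features)
# ---------------------------------------------------------------------------

def tdp_features(ts: TrialSet, K: int) -> FeatureTensor:
    """Log variance of each channel's signal and its first K derivatives.

    The derivative is the first difference scaled by the sampling rate; the
    feature matrix per trial is ``channels x (K + 1)``.  K = 2 recovers the
    information in the classical Hjorth activity/mobility/complexity triple.
    """
    if K < 0:
        raise InvalidParameterError(f"K must be >= 0, got {K}")
    if ts.n_samples <= K + 1:
        raise InvalidInputError(
            f"trial length {ts.n_samples} too short for K={K} derivatives"
        )
    feats = np.empty((ts.n_trials, ts.n_channels, K + 1))
    for i, X in enumerate(ts.trials):
        d = X
        for k in range(K + 1):
            feats[i, :, k] = np.log(d.var(axis=1) + LOG_EPS)
            if k < K:
                d = np.diff(d, axis=1) * ts.fs
    names = [f"logvar_d{k}" for k in range(K + 1)]
    return FeatureTensor(feats, ts.labels.copy(), feature_names=names)


# ---------------------------------------------------------------------------
# mutual-information feature ranking (FBCSP selection stage)
# ---------------------------------------------------------------------------

def _histogram_mi(x: np.ndarray, y: np.ndarray) -> float:
    """MI (bits) between a scalar feature and a discrete label.

    Equal-width histogram with ceil(sqrt(n)) bins on the feature axis.
    """
    n = len(x)
    bins = max(int(math.ceil(math.sqrt(n))), 2)
    classes, yi = np.unique(y, return_inverse=True)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    xi = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)
    joint = np.zeros((bins, len(classes)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def fbcsp_select(ft: FeatureTensor, k: int):
    """Rank flattened features by mutual information with the label.

    Returns the indices of the top ``k`` columns of the flattened feature
    matrix (histogram MI estimator, ties broken by lower index).
    """
    if k <= 0:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    X = ft.flatten()
    if k > X.shape[1]:
        raise InvalidParameterError(f"k={k} exceeds {X.shape[1]} features")
    if len(np.unique(ft.labels)) < 2:
        raise InvalidInputError("fbcsp_select needs >= 2 classes")
    mi = np.array([_histogram_mi(X[:, j], ft.labels) for j in range(X.shape[1])])
    order = np.lexsort((np.arange(X.shape[1]), -mi))
    return np.asarray(order[:k])
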