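"""Synthetic matrix-variate trial generators.

These generators emulate the statistical structure that motor-imagery EEG
methods assume, so every pipeline stage is testable without external
recordings: class-dependent spatial covariance (the signature CSP exploits),
band-limited rhythms, a low-rank background, sparse artifact spikes, and a
controllable fraction of gross outlier trials (whole-trial amplitude
scaling, the failure mode the robust losses target).

Everything is a pure function of its spec plus a seed.  Per-trial
sub-streams are derived from ``(seed, trial_index)`` so enlarging a trial
set never perturbs earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InvalidParameterError
from .preprocessing import TrialSet

__all__ = [
    "SyntheticSpec",
    "default_class_covariances",
    "gen_trials",
    "gen_lowrank_sparse",
    "gen_row_informative",
]


def default_class_covariances(channels: int, n_classes: int = 2,
                              contrast: float = 4.0) -> list:
    """Diagonal-dominant SPD covariances with class-swapped high-variance
    channel blocks — a construction CSP separates cleanly."""
    covs = []
    block = max(channels // (n_classes + 1), 1)
    for c in range(n_classes):
        d = np.ones(channels)
        d[c * block:(c + 1) * block] = contrast
        covs.append(np.diag(d))
    return covs


@dataclass
class SyntheticSpec:
    """Study conditions for :func:`gen_trials`.

    Defaults describe a small but realistic motor-imagery session: 10
    channels at 250 Hz, 2-second trials, 60 trials per class, two classes
    whose spatial covariances swap a high-variance channel block, mu/beta
    band rhythms, a rank-2 common background, sparse artifact spikes, and
    10% outlier trials amplified tenfold.
    """

    n_per_class: int = 60
    channels: int = 10
    samples: int = 500
    fs: float = 250.0
    class_covs: Optional[list] = None
    rhythm_bands: Optional[list] = None      # one (low, high) Hz per class
    rhythm_amplitude: float = 1.0
    background_rank: int = 2
    background_amplitude: float = 0.5
    artifact_density: float = 0.005
    artifact_amplitude: float = 8.0
    outlier_fraction: float = 0.1
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.outlier_fraction < 1:
            raise InvalidParameterError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.artifact_density <= 1:
            raise InvalidParameterError("artifact_density must be in [0, 1]")
        if self.class_covs is None:
            self.class_covs = default_class_covariances(self.channels)
        if self.rhythm_bands is None:
            self.rhythm_bands = [(10.0, 12.0), (20.0, 24.0)][:len(self.class_covs)]
            while len(self.rhythm_bands) < len(self.class_covs):
                self.rhythm_bands.append((8.0 + 4 * len(self.rhythm_bands),
                                          12.0 + 4 * len(self.rhythm_bands)))

    @property
    def n_classes(self) -> int:
        return len(self.class_covs)


def _sqrtm_spd(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    if w.min() <= 0:
        raise InvalidParameterError("class covariance is not positive definite")
    return (V * np.sqrt(w)) @ V.T


def gen_trials(spec: SyntheticSpec):
    """Generate a labeled :class:`TrialSet` plus ground-truth metadata.

    Each trial is ``Sigma_c^{1/2} E`` (spatially colored noise, ``E`` iid
    standard normal) plus an optional class-band rhythm, low-rank
    background and sparse spikes; outlier trials are scaled whole.  Returns
    ``(TrialSet, meta)`` where ``meta`` carries the outlier flags and the
    class covariances actually used.
    """
    covs = [np.asarray(C, dtype=float) for C in spec.class_covs]
    for C in covs:
        if C.shape != (spec.channels, spec.channels) or not np.allclose(C, C.T):
            raise InvalidParameterError("class covariances must be symmetric c x c")
    roots = [_sqrtm_spd(C) for C in covs]
    mixing = []  # fixed per-class rhythm spatial pattern
    master = np.random.default_rng([spec.seed, 0xC1A55])
    for _ in covs:
        v = master.standard_normal(spec.channels)
        mixing.append(v / np.linalg.norm(v))
    bg_master = np.random.default_rng([spec.seed, 0xB6])
    bg_U = bg_master.standard_normal((spec.channels, max(spec.background_rank, 1)))

    n_total = spec.n_per_class * spec.n_classes
    trials = np.empty((n_total, spec.channels, spec.samples))
    labels = np.empty(n_total, dtype=int)
    outlier_flags = np.zeros(n_total, dtype=bool)
    t = np.arange(spec.samples) / spec.fs

    idx = 0
    for cls in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            rng = np.random.default_rng([spec.seed, idx])
            X = roots[cls] @ rng.standard_normal((spec.channels, spec.samples))
            if spec.rhythm_amplitude > 0:
                low, high = spec.rhythm_bands[cls]
                freq = rng.uniform(low, high)
                phase = rng.uniform(0, 2 * np.pi)
                osc = np.sin(2 * np.pi * freq * t + phase)
                X = X + spec.rhythm_amplitude * np.outer(mixing[cls], osc)
            if spec.background_rank > 0 and spec.background_amplitude > 0:
                coef = rng.standard_normal((spec.background_rank, spec.samples))
                X = X + spec.background_amplitude * (
                    bg_U[:, :spec.background_rank] @ coef
                ) / np.sqrt(spec.background_rank)
            if spec.artifact_density > 0 and spec.artifact_amplitude > 0:
                mask = rng.random((spec.channels, spec.samples)) < spec.artifact_density
                signs = rng.choice([-1.0, 1.0], size=mask.sum())
                X[mask] += spec.artifact_amplitude * signs
            if rng.random() < spec.outlier_fraction:
                X = X * spec.outlier_scale
                outlier_flags[idx] = True
            trials[idx] = X
            labels[idx] = cls
            idx += 1
    ts = TrialSet(trials, labels, spec.fs)
    meta = {"outlier_flags": outlier_flags, "class_covs": covs,
            "rhythm_bands": list(spec.rhythm_bands), "seed": spec.seed}
    return ts, meta


def gen_lowrank_sparse(m: int, n: int, rank: int, density: float,
                       amplitude: float, seed: int):
    """Low-rank-plus-sparse fixture: ``X = L0 + S0``.

    ``L0 = U V^T`` with iid standard-normal factors of width ``rank``;
    ``S0`` has Bernoulli(``density``) support with entries ``+/-amplitude``.
    Returns ``(X, L0, S0)``.
    """
    if rank > min(m, n) or rank < 0:
        raise InvalidParameterError(f"rank must be in [0, {min(m, n)}]")
    if not 0 <= density <= 1:
        raise InvalidParameterError("density must be in [0, 1]")
    rng = np.random.default_rng([seed, 0x10])
    if rank == 0:
        L0 = np.zeros((m, n))
    else:
        U = rng.standard_normal((m, rank))
        V = rng.standard_normal((n, rank))
        L0 = U @ V.T
    mask = rng.random((m, n)) < density
    S0 = np.zeros((m, n))
    S0[mask] = amplitude * rng.choice([-1.0, 1.0], size=mask.sum())
    return L0 + S0, L0, S0


def gen_row_informative(p: int, n: int, k_informative: int, snr: float,
                        n_outliers: int, seed: int):
    """Planted row-support fixture for joint-feature-selection recovery.

    ``k_informative`` rows carry a shared latent factor scaled to the given
    SNR (signal sd over unit noise sd); all rows carry unit noise;
    ``n_outliers`` sample columns are replaced by gross noise (sd 10).
    Returns ``(X, true_support)`` with ``X`` of shape ``p x n`` (columns
    are samples).
    """
    if k_informative > p or k_informative < 0:
        raise InvalidParameterError(f"k_informative must be in [0, {p}]")
    if n_outliers > n:
        raise InvalidParameterError("n_outliers exceeds n")
    rng = np.random.default_rng([seed, 0x20])
    X = rng.standard_normal((p, n))
    support = np.arange(k_informative)
    if k_informative > 0 and snr > 0:
        z = rng.standard_normal(n)
        load = rng.choice([-1.0, 1.0], size=k_informative)
        X[support] += np.sqrt(snr) * np.outer(load, z)
    if n_outliers > 0:
        cols = rng.choice(n, size=n_outliers, replace=False)
        X[:, cols] = 10.0 * rng.standard_normal((p, n_outliers))
    return X, support
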