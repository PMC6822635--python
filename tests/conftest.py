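"""Shared fixtures and oracles for the test suite."""

import numpy as np
import pytest

from matrixmi import gen_row_informative
from matrixmi.preprocessing import FeatureTensor


def support_f1(estimated, true) -> float:
    """F1 of an estimated feature-index set against the planted one."""
    est = set(np.asarray(estimated).tolist())
    tru = set(np.asarray(true).tolist())
    tp = len(est & tru)
    if tp == 0:
        return 0.0
    return 2.0 * tp / (len(est) + len(tru))


def rank1_trials(rep: int, n: int, p: int = 8, q: int = 6, noise: float = 0.6,
                 outlier_fraction: float = 0.0, stream: int = 0) -> FeatureTensor:
    """Two-class matrix trials with a rank-1 discriminative pattern.

    Class mean is ``+/- M`` for a fixed unit-norm rank-1 ``M``; optional
    outlier trials are whole-trial amplitude x10 (labels kept correct).
    The pattern depends only on ``rep`` so train/test sets share it;
    ``stream`` separates the noise draws of train and test sets.
    """
    pattern_rng = np.random.default_rng([rep, 7])
    u = pattern_rng.standard_normal(p)
    v = pattern_rng.standard_normal(q)
    M = np.outer(u, v)
    M /= np.linalg.norm(M)
    rng = np.random.default_rng([rep, 7, stream])
    X, y = [], []
    for _ in range(n):
        lab = 1 if rng.random() < 0.5 else -1
        T = lab * M + noise * rng.standard_normal((p, q))
        if rng.random() < outlier_fraction:
            T = T * 10.0
        X.append(T)
        y.append(lab)
    return FeatureTensor(np.stack(X), np.array(y))


def column_support_trials(seed: int, p: int = 20, a: int = 50,
                          n_clean: int = 54, n_out: int = 6,
                          k_informative: int = 2, snr: float = 9.0):
    """Matrix trials (a x p) with a planted informative column block.

    Clean trials come from the row-informative generator with its sample
    columns grouped into trials; outlier trials are gross noise (sd 10).
    Returns ``(trials, planted_column_indices)``.
    """
    X, sup = gen_row_informative(p, a * n_clean, k_informative, snr, 0, seed)
    rng = np.random.default_rng([seed, 99])
    trials = [X[:, i * a:(i + 1) * a].T / np.sqrt(a) for i in range(n_clean)]
    trials += [10.0 * rng.standard_normal((a, p)) / np.sqrt(a)
               for _ in range(n_out)]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order], sup


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
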