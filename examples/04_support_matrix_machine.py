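"""Robust support matrix machine vs a vectorized SVM on matrix trials.

Trials carry a rank-1 discriminative pattern; 10% of training trials are
amplitude-x10 outliers.  Averaged over replicates the matrix machine's
spectral elastic net (l2,1 + nuclear norm) generalizes at least as well as
the plain SVM, and a stronger nuclear penalty truncates the regression
matrix to the pattern's true rank.
"""

import numpy as np

from matrixmi import rsmm_fit_binary, smm_predict, svm_baseline_fit
from matrixmi.preprocessing import FeatureTensor


def rank1_trials(rep, n, p=8, q=6, noise=0.6, outlier_fraction=0.0, stream=0):
    pattern_rng = np.random.default_rng([rep, 7])
    M = np.outer(pattern_rng.standard_normal(p), pattern_rng.standard_normal(q))
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


acc_rsmm, acc_svm = [], []
for rep in range(10):
    train = rank1_trials(rep, 60, outlier_fraction=0.1, stream=0)
    test = rank1_trials(rep, 200, stream=1)
    rsmm = rsmm_fit_binary(train, gamma=0.1, tau=0.1, C=1.0, max_iter=300)
    svm = svm_baseline_fit(train, C=1.0)
    acc_rsmm.append(np.mean(smm_predict(rsmm, test) == test.labels))
    acc_svm.append(np.mean(smm_predict(svm, test) == test.labels))
print(f"mean test accuracy over 10 replicates "
      f"(10% x10-amplitude training outliers):")
print(f"  rsmm: {np.mean(acc_rsmm):.3f}   svm: {np.mean(acc_svm):.3f}")

# a stronger nuclear penalty exposes the rank-1 structure of the pattern
train = rank1_trials(3, 40, noise=0.3)
strong = rsmm_fit_binary(train, gamma=0.01, tau=4.0, C=10.0)
sv = np.linalg.svd(strong.W[1], compute_uv=False)
print(f"\nwith tau=4: training accuracy "
      f"{np.mean(smm_predict(strong, train) == train.labels):.2f}, "
      f"rank(W) = {np.sum(sv > 1e-10 * sv[0])} "
      f"(singular values {np.round(sv[:3], 3).tolist()} ...)")
print("singular value thresholding inside the ADMM keeps W near the true "
      "rank-1 discriminative pattern")
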