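"""Sample sizing, windowing, filter bank, CSP and feature extraction."""

import numpy as np
import pytest
import scipy.linalg

from matrixmi import (
    FilterBankSpec,
    TrialSet,
    allocate_samples,
    bandpass_filterbank,
    compute_sample_size,
    csp_fit,
    csp_transform,
    fbcsp_select,
    segment_signal,
    select_channels,
    tdp_features,
)
from matrixmi.exceptions import (
    DegenerateAllocationError,
    InvalidInputError,
    InvalidParameterError,
)
from matrixmi.preprocessing import FeatureTensor


def make_cov_trials(S1, S2, n_per_class, T, seed, fs=250.0):
    """Trials drawn with exact per-class spatial covariance factors."""
    rng = np.random.default_rng(seed)
    r1 = np.linalg.cholesky(S1)
    r2 = np.linalg.cholesky(S2)
    trials, labels = [], []
    for _ in range(n_per_class):
        trials.append(r1 @ rng.standard_normal((len(S1), T)))
        labels.append(0)
        trials.append(r2 @ rng.standard_normal((len(S2), T)))
        labels.append(1)
    return TrialSet(np.stack(trials), np.array(labels), fs)


class TestSampleSize:
    def test_worked_values_99pct_confidence(self):
        # Z=2.58, p=0.5, e=0.01: n0 = 2.58^2 * 0.25 / 1e-4 = 16641
        spec = compute_sample_size(0.5, 2.58, 0.01)
        assert spec.n0 == pytest.approx(16641.0)
        assert spec.n == 16641
        corrected = compute_sample_size(0.5, 2.58, 0.01, N=4097)
        assert corrected.n == 3288  # ceil(16641 / (1 + 16640/4097))

    def test_zero_variance_proportion(self):
        assert compute_sample_size(0.0, 2.58, 0.01).n0 == 0.0

    def test_finite_population_converges_to_uncorrected(self):
        spec = compute_sample_size(0.5, 2.58, 0.01)
        big_N = int(1e6 * spec.n0)
        corrected = compute_sample_size(0.5, 2.58, 0.01, N=big_N)
        assert abs(corrected.n - spec.n0) / spec.n0 < 1e-3

    @pytest.mark.parametrize("p,Z,e", [(-0.1, 2.58, 0.01), (1.5, 2.58, 0.01),
                                       (0.5, 2.58, 0.0)])
    def test_invalid_parameters(self, p, Z, e):
        with pytest.raises(InvalidParameterError):
            compute_sample_size(p, Z, e)


class TestWindowing:
    @pytest.mark.parametrize("total,k,expected", [
        (4097, 4, [1024, 1024, 1024, 1025]),
        (10, 1, [10]),
        (7, 3, [2, 2, 3]),
    ])
    def test_near_equal_windows_remainder_last(self, total, k, expected):
        np.testing.assert_array_equal(segment_signal(total, k), expected)

    def test_lengths_always_sum_to_total(self):
        for total in (17, 100, 4097):
            for k in (1, 2, 5, 7):
                assert segment_signal(total, k).sum() == total

    def test_too_many_windows_rejected(self):
        with pytest.raises(InvalidParameterError):
            segment_signal(3, 4)


class TestAllocation:
    def test_symmetric_case_splits_evenly(self):
        plan = allocate_samples([10, 10, 10, 10], np.ones((4, 3)), 100)
        np.testing.assert_array_equal(plan.counts, [25, 25, 25, 25])

    def test_weight_formula_direct_evaluation(self):
        # N=[2,1] with equal row sums-of-squares of variances -> 2:1 split
        Var = np.array([[2.0, 0.0], [0.0, 2.0]])
        plan = allocate_samples([2, 1], Var, 90)
        np.testing.assert_allclose(plan.fractions, [2 / 3, 1 / 3])
        np.testing.assert_array_equal(plan.counts, [60, 30])

    def test_zero_variance_window_gets_nothing(self):
        Var = np.array([[0.0, 0.0], [1.0, 1.0]])
        plan = allocate_samples([5, 5], Var, 10)
        assert plan.fractions[0] == 0.0
        assert plan.counts.sum() == 10

    def test_counts_sum_to_budget_with_rounding(self, rng):
        for _ in range(10):
            Var = rng.random((5, 3))
            plan = allocate_samples(rng.integers(1, 20, 5), Var, 97)
            assert plan.counts.sum() == 97

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(DegenerateAllocationError):
            allocate_samples([1, 1], np.zeros((2, 2)), 10)


class TestFilterBank:
    def _sine_trials(self, freq, fs=250.0, T=1000):
        t = np.arange(T) / fs
        X = np.tile(np.sin(2 * np.pi * freq * t), (3, 1))
        return TrialSet(X[None], np.array([0]), fs)

    def test_passband_preserves_power(self):
        ts = self._sine_trials(10.0)
        out = bandpass_filterbank(ts, FilterBankSpec(bands=[(8, 12)]))[0]
        p_in = (ts.trials ** 2).sum()
        p_out = (out.trials ** 2).sum()
        assert p_out >= 0.9 * p_in

    def test_stopband_attenuates(self):
        ts = self._sine_trials(10.0)
        out = bandpass_filterbank(ts, FilterBankSpec(bands=[(20, 24)]))[0]
        assert (out.trials ** 2).sum() <= 0.01 * (ts.trials ** 2).sum()

    def test_zero_signal_stays_zero(self):
        ts = TrialSet(np.zeros((2, 3, 200)), np.zeros(2), 250.0)
        out = bandpass_filterbank(ts, FilterBankSpec(bands=[(8, 12)]))[0]
        np.testing.assert_allclose(out.trials, 0.0, atol=1e-12)

    def test_default_bank_has_nine_bands_and_preserves_shape(self):
        ts = self._sine_trials(10.0)
        outs = bandpass_filterbank(ts)
        assert len(outs) == 9
        assert all(o.trials.shape == ts.trials.shape for o in outs)

    def test_band_beyond_nyquist_rejected(self):
        ts = self._sine_trials(10.0, fs=50.0)
        with pytest.raises(InvalidParameterError):
            bandpass_filterbank(ts, FilterBankSpec(bands=[(20, 30)]))


class TestCSP:
    def test_analytic_two_channel_problem(self):
        # S1=diag(4,1), S2=diag(1,4): after trace normalization the
        # generalized eigenproblem has eigenvalues 0.8 and 0.2 with
        # coordinate-axis filters
        ts = make_cov_trials(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]),
                             400, 500, seed=1)
        model = csp_fit(ts, (0, 1))
        np.testing.assert_allclose(model.eigenvalues, [0.8, 0.2], atol=0.02)
        # each filter aligns with a coordinate axis
        for row in model.filters:
            assert np.abs(row).max() / np.linalg.norm(row) > 0.99

    def test_filters_whiten_pooled_covariance(self, rng):
        A1 = rng.standard_normal((4, 4))
        A2 = rng.standard_normal((4, 4))
        ts = make_cov_trials(A1 @ A1.T + 0.5 * np.eye(4),
                             A2 @ A2.T + 0.5 * np.eye(4), 50, 300, seed=2)
        model = csp_fit(ts, (0, 1))
        # reconstruct the pooled (trace-normalized, averaged) covariance
        from matrixmi.preprocessing import _class_covariance
        pooled = (_class_covariance(ts.trials[ts.labels == 0])
                  + _class_covariance(ts.trials[ts.labels == 1]))
        W = model.filters @ pooled @ model.filters.T
        np.testing.assert_allclose(W, np.eye(4), atol=1e-6)

    def test_eigenvalues_match_bruteforce_generalized_solve(self, rng):
        A1 = rng.standard_normal((3, 3))
        A2 = rng.standard_normal((3, 3))
        ts = make_cov_trials(A1 @ A1.T + 0.2 * np.eye(3),
                             A2 @ A2.T + 0.2 * np.eye(3), 30, 200, seed=3)
        model = csp_fit(ts, (0, 1))
        from matrixmi.preprocessing import _class_covariance
        S1 = _class_covariance(ts.trials[ts.labels == 0])
        S2 = _class_covariance(ts.trials[ts.labels == 1])
        w = np.sort(scipy.linalg.eigvalsh(S1, S1 + S2))[::-1]
        np.testing.assert_allclose(model.eigenvalues, w, atol=1e-9)

    def test_identical_distributions_give_half_eigenvalues(self):
        S = np.diag([2.0, 1.0, 0.5])
        ts = make_cov_trials(S, S, 300, 400, seed=4)
        model = csp_fit(ts, (0, 1))
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=0.03)

    def test_scale_invariance(self):
        ts = make_cov_trials(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]),
                             30, 200, seed=5)
        scaled = TrialSet(ts.trials * 37.5, ts.labels, ts.fs)
        m1 = csp_fit(ts, (0, 1))
        m2 = csp_fit(scaled, (0, 1))
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-9)
        # filters equal up to sign
        for r1, r2 in zip(m1.filters, m2.filters):
            assert min(np.linalg.norm(r1 - r2), np.linalg.norm(r1 + r2)) < 1e-6

    def test_eigenvalue_pairs_sum_to_one(self):
        ts = make_cov_trials(np.diag([4.0, 1.0, 2.0]),
                             np.diag([1.0, 4.0, 2.0]), 40, 300, seed=6)
        model = csp_fit(ts, (0, 1))
        flipped = csp_fit(ts, (1, 0))
        np.testing.assert_allclose(np.sort(model.eigenvalues)
                                   + np.sort(flipped.eigenvalues)[::-1],
                                   1.0, atol=1e-9)

    def test_single_class_rejected(self):
        ts = make_cov_trials(np.eye(2), np.eye(2), 5, 100, seed=7)
        with pytest.raises(InvalidInputError):
            csp_fit(ts, (0, 5))


class TestCSPTransformAndChannels:
    def _fitted(self, seed=8):
        ts = make_cov_trials(np.diag([4.0, 1.0, 1.0, 1.0]),
                             np.diag([1.0, 4.0, 1.0, 1.0]), 60, 300, seed=seed)
        return ts, csp_fit(ts, (0, 1))

    def test_features_separate_classes(self):
        ts, model = self._fitted()
        ft = csp_transform(model, ts, 1)
        f0 = ft.features[ts.labels == 0, 0, 0]
        f1 = ft.features[ts.labels == 1, 0, 0]
        assert f0.mean() > f1.mean()

    def test_all_filters_used_at_boundary(self):
        ts, model = self._fitted()
        ft = csp_transform(model, ts, 2)
        assert ft.matrix_shape == (4, 1)

    def test_zero_variance_trial_guarded(self):
        ts, model = self._fitted()
        dead = TrialSet(np.zeros((1, 4, 300)), np.array([0]), ts.fs)
        ft = csp_transform(model, dead, 1)
        assert np.all(np.isfinite(ft.features))

    def test_invalid_m(self):
        ts, model = self._fitted()
        with pytest.raises(InvalidParameterError):
            csp_transform(model, ts, 0)
        with pytest.raises(InvalidParameterError):
            csp_transform(model, ts, 3)

    def test_planted_channel_ranked_first(self):
        # only channel 2 differs between classes
        S1 = np.diag([1.0, 1.0, 5.0, 1.0])
        S2 = np.diag([1.0, 1.0, 0.2, 1.0])
        ts = make_cov_trials(S1, S2, 80, 300, seed=9)
        model = csp_fit(ts, (0, 1))
        assert select_channels(model, 1)[0] == 2

    def test_all_channels_and_tiebreak(self):
        ts, model = self._fitted()
        assert sorted(select_channels(model, 4).tolist()) == [0, 1, 2, 3]
        from matrixmi.preprocessing import CSPModel
        tied = CSPModel(filters=np.ones((3, 3)), eigenvalues=np.array([1, .5, 0]),
                        class_pair=(0, 1))
        np.testing.assert_array_equal(select_channels(tied, 2), [0, 1])


class TestTDP:
    def test_constant_signal_hits_epsilon_floor(self):
        ts = TrialSet(np.ones((1, 2, 100)), np.array([0]), 100.0)
        ft = tdp_features(ts, 0)
        np.testing.assert_allclose(ft.features, np.log(1e-12), atol=1e-6)

    def test_sine_derivative_variance_ratio(self):
        # d/dt sin(w t) = w cos(w t): derivative variance ~ w^2 x variance,
        # so the TDP feature difference is ~ 2 log(w)
        fs, f = 1000.0, 20.0
        omega = 2 * np.pi * f
        t = np.arange(4000) / fs
        X = np.sin(omega * t)[None, :]
        ts = TrialSet(X[None], np.array([0]), fs)
        ft = tdp_features(ts, 1)
        diff = ft.features[0, 0, 1] - ft.features[0, 0, 0]
        assert diff == pytest.approx(2 * np.log(omega), abs=0.05)

    def test_white_noise_matches_bruteforce(self, rng):
        X = rng.standard_normal((3, 500))
        fs = 250.0
        ts = TrialSet(X[None], np.array([0]), fs)
        ft = tdp_features(ts, 2)
        d = X
        for k in range(3):
            np.testing.assert_allclose(ft.features[0, :, k],
                                       np.log(d.var(axis=1) + 1e-12),
                                       rtol=1e-10)
            d = np.diff(d, axis=1) * fs

    def test_feature_shape(self, rng):
        ts = TrialSet(rng.standard_normal((4, 5, 100)), np.zeros(4), 100.0)
        assert tdp_features(ts, 3).matrix_shape == (5, 4)


class TestFBCSPSelect:
    def test_label_copy_feature_ranked_first(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        feats = rng.standard_normal((n, 3, 1))
        feats[:, 1, 0] = labels  # exact copy of the label
        ft = FeatureTensor(feats, labels)
        assert fbcsp_select(ft, 1)[0] == 1

    def test_independent_feature_has_low_mi(self, rng):
        from matrixmi.preprocessing import _histogram_mi
        x = rng.standard_normal(5000)
        y = rng.integers(0, 2, 5000)
        assert _histogram_mi(x, y) <= 0.05

    def test_k_equals_total_returns_all(self, rng):
        labels = rng.integers(0, 2, 100)
        ft = FeatureTensor(rng.standard_normal((100, 2, 2)), labels)
        assert sorted(fbcsp_select(ft, 4).tolist()) == [0, 1, 2, 3]

    def test_invalid_k(self, rng):
        ft = FeatureTensor(rng.standard_normal((50, 2, 1)),
                           rng.integers(0, 2, 50))
        with pytest.raises(InvalidParameterError):
            fbcsp_select(ft, 0)
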