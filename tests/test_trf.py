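"""Ridge TRF estimation and snippet cross-validation."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from speechtrack.envelope import EnvelopeSeries
from speechtrack.preprocess import SCALP_LABELS, EEGRecording
from speechtrack.synthetic import KernelSpec, gen_linear_eeg, gen_speechlike_envelope
from speechtrack.trf import (
    SnippetScheme,
    TemporalResponseFunction,
    build_design_matrix,
    crosscorr_tracking,
    fit_trf_ridge,
    lag_shifts,
    predict_accuracy,
    snippet_crossval,
)

RATE = 512.0


def rand_env(n, seed=0, rate=RATE):
    return EnvelopeSeries(np.random.default_rng(seed).random(n), rate)


def recording(data, rate=RATE):
    data = np.atleast_2d(data)
    return EEGRecording(data, rate, SCALP_LABELS[: data.shape[0]])


def naive_design(values, ks):
    n = values.size
    X = np.zeros((n, ks.size))
    for j, k in enumerate(ks):
        for t in range(n):
            if 0 <= t - k < n:
                X[t, j] = values[t - k]
    return X


class TestDesignMatrix:
    def test_impulse_propagates_along_lags(self):
        env = np.zeros(200)
        env[100] = 1.0
        X, lags = build_design_matrix(env, 0.0, 0.01, rate=RATE)
        assert X.shape[1] == 6
        for j in range(6):
            col = np.flatnonzero(X[:, j])
            np.testing.assert_array_equal(col, [100 + j])

    def test_prediction_lag_count(self):
        X, lags = build_design_matrix(rand_env(500), 0.0, 0.4)
        assert X.shape[1] == 205
        np.testing.assert_allclose(np.diff(lags), 1 / RATE)

    @pytest.mark.parametrize("lag_range", [(0.0, 0.05), (-0.03, 0.06)])
    def test_equals_shift_and_stack_oracle(self, lag_range):
        env = rand_env(300, seed=3)
        X, _ = build_design_matrix(env, *lag_range)
        ks = lag_shifts(*lag_range, RATE)
        np.testing.assert_array_equal(X, naive_design(env.values, ks))

    def test_too_short_envelope(self):
        with pytest.raises(ValueError, match="shorter"):
            build_design_matrix(rand_env(100), 0.0, 0.4)


def zscore(X):
    return (X - X.mean(0)) / X.std(0)


class TestRidgeFit:
    def test_noiseless_identifiability_lambda_zero(self):
        env = rand_env(400, seed=1)
        X, _ = build_design_matrix(env, 0.0, 0.02)
        w_true = np.linspace(1.0, -1.0, X.shape[1])
        y = zscore(X) @ w_true
        res = fit_trf_ridge(env, recording(y), lam=0.0, lags=(0.0, 0.02))
        np.testing.assert_allclose(res.weights[0], w_true, rtol=1e-6, atol=1e-9)

    def test_huge_lambda_shrinks_to_zero(self):
        env = rand_env(400, seed=2)
        eeg = recording(np.random.default_rng(3).standard_normal(400))
        ols = fit_trf_ridge(env, eeg, lam=0.0, lags=(0.0, 0.02))
        shrunk = fit_trf_ridge(env, eeg, lam=1e9, lags=(0.0, 0.02))
        assert np.abs(shrunk.weights).max() < 1e-6 * np.abs(ols.weights).max()

    def test_ten_sample_toy_matches_normal_equations(self):
        env = rand_env(10, seed=4)
        Y = np.random.default_rng(5).standard_normal((2, 10))
        lam = 10.0
        res = fit_trf_ridge(env, recording(Y), lam=lam, lags=(0.0, 3.5 / RATE))
        X, _ = build_design_matrix(env, 0.0, 3.5 / RATE)
        Z = zscore(X)
        w = np.linalg.solve(
            Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (Y.T - Y.T.mean(0))
        )
        np.testing.assert_allclose(res.weights, w.T, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_ridge_equals_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 100))
        L = int(rng.integers(2, 8))
        env = EnvelopeSeries(rng.random(n), RATE)
        Y = rng.standard_normal((3, n))
        lam = float(rng.uniform(0.1, 50))
        res = fit_trf_ridge(env, recording(Y), lam=lam, lags=(0.0, (L - 0.5) / RATE))
        X, _ = build_design_matrix(env, 0.0, (L - 0.5) / RATE)
        Z = zscore(X)
        w = np.linalg.solve(
            Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (Y.T - Y.T.mean(0))
        )
        np.testing.assert_allclose(res.weights, w.T, atol=1e-10)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            TemporalResponseFunction(rand_env(100), recording(np.zeros(90)))


class TestSnippetCrossval:
    def small_case(self, noise=0.0, seed=0):
        env = gen_speechlike_envelope(30.0, RATE, seed=seed)
        rec, truth = gen_linear_eeg(
            env, KernelSpec(), response_snr_db=np.inf, n_channels=4, seed=seed
        )
        if noise:
            rng = np.random.default_rng(seed + 1)
            rec = EEGRecording(
                rec.data + noise * rng.standard_normal(rec.data.shape),
                rec.rate, rec.labels, rec.reference,
            )
        return env, rec, truth

    def test_deterministic_given_seed(self):
        env, rec, _ = self.small_case()
        scheme = SnippetScheme(n_snippets=5, duration=5.0, seed=7)
        a = snippet_crossval(env, rec, scheme, lags=(0.0, 0.1))
        b = snippet_crossval(env, rec, scheme, lags=(0.0, 0.1))
        np.testing.assert_array_equal(a.snippet_starts, b.snippet_starts)
        np.testing.assert_array_equal(a.trf.weights, b.trf.weights)
        assert a.accuracy.r_mean == b.accuracy.r_mean

    def test_noiseless_prediction_near_perfect(self):
        env, rec, _ = self.small_case()
        cv = snippet_crossval(
            env, rec, SnippetScheme(n_snippets=8, duration=6.0, seed=1)
        )
        assert cv.accuracy.r_mean >= 0.99

    def test_independent_noise_gives_null_correlations(self):
        env = gen_speechlike_envelope(30.0, RATE, seed=11)
        rng = np.random.default_rng(12)
        rec = recording(rng.standard_normal((2, env.n_samples)))
        cv = snippet_crossval(
            env, rec, SnippetScheme(n_snippets=8, duration=6.0, seed=2)
        )
        # null per-fold correlations are O(1/sqrt(n)) with n = 6 s * 512 Hz
        assert np.abs(np.nanmean(cv.accuracy.r_per_snippet)) < 2 / np.sqrt(6 * RATE)

    def test_matches_bruteforce_fold_computation(self):
        """The prefix-sum Gram accumulation must equal explicit per-fold
        design-matrix concatenation exactly."""
        env, rec, _ = self.small_case(noise=0.5, seed=3)
        scheme = SnippetScheme(n_snippets=6, duration=4.0, seed=5)
        lags = (-0.02, 0.05)
        cv = snippet_crossval(env, rec, scheme, lam=10.0, lags=lags)

        X, lag_grid = build_design_matrix(env, *lags)
        dur = int(scheme.duration * RATE)
        starts = cv.snippet_starts
        Y = rec.data.T
        kern_sum = 0.0
        r = np.empty((starts.size, rec.n_channels))
        for f, s in enumerate(starts):
            rows = np.concatenate(
                [
                    np.arange(sj, sj + dur)
                    for sj in starts
                    if abs(sj - s) >= dur
                ]
            )
            Xr, Yr = X[rows], Y[rows]
            mu, sd = Xr.mean(0), Xr.std(0)
            Z = (Xr - mu) / sd
            w = np.linalg.solve(
                Z.T @ Z + 10.0 * np.eye(Z.shape[1]), Z.T @ (Yr - Yr.mean(0))
            )
            kern_sum += (w / sd[:, None]).T
            Zi = (X[s : s + dur] - mu) / sd
            pred = Zi @ w
            obs = Y[s : s + dur]
            for c in range(rec.n_channels):
                r[f, c] = sp_stats.pearsonr(pred[:, c], obs[:, c]).statistic
        np.testing.assert_allclose(cv.trf.kernel, kern_sum / starts.size, rtol=1e-8)
        np.testing.assert_allclose(cv.accuracy.r_per_snippet, r, atol=1e-10)

    def test_converges_to_full_fit_on_noiseless_data(self):
        env, rec, _ = self.small_case(seed=6)
        cv = snippet_crossval(
            env, rec, SnippetScheme(n_snippets=20, duration=6.0, seed=4),
            lags=(0.0, 0.1),
        )
        full = fit_trf_ridge(env, rec, lags=(0.0, 0.1))
        r = np.corrcoef(cv.trf.kernel.ravel(), full.kernel.ravel())[0, 1]
        assert r > 0.99

    def test_story_too_short(self):
        env, rec, _ = self.small_case()
        with pytest.raises(ValueError, match="short"):
            snippet_crossval(env, rec, SnippetScheme(n_snippets=50, duration=31.0))


class TestPredictAccuracy:
    def test_perfect_and_inverted_prediction(self):
        env = rand_env(600, seed=1)
        trf = fit_trf_ridge(env, recording(np.random.default_rng(2)
                                           .standard_normal((6, 600))),
                            lags=(0.0, 0.05))
        pred = trf.predict(env)
        acc = predict_accuracy(trf, env, recording(pred))
        assert acc.r_mean == pytest.approx(1.0, abs=1e-12)
        acc_neg = predict_accuracy(trf, env, recording(-pred))
        assert acc_neg.r_mean == pytest.approx(-1.0, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        env = gen_speechlike_envelope(30.0, RATE, seed=3)
        rec, _ = gen_linear_eeg(env, response_snr_db=0.0, n_channels=6, seed=4)
        trf = fit_trf_ridge(env, rec)
        a = predict_accuracy(trf, env, rec)
        scaled = EEGRecording(
            5.0 * rec.data + 3.0, rec.rate, rec.labels, rec.reference
        )
        b = predict_accuracy(trf, env, scaled)
        assert a.r_mean == pytest.approx(b.r_mean, abs=1e-12)

    def test_null_correlation_small(self):
        hits = 0
        n = 10_000
        for seed in range(40):
            rng = np.random.default_rng(seed)
            env = EnvelopeSeries(rng.random(n), RATE)
            trf = fit_trf_ridge(
                env, recording(rng.standard_normal(n)), lags=(0.0, 0.02)
            )
            other = recording(rng.standard_normal(n))
            if abs(predict_accuracy(trf, env, other,
                                    cluster=SCALP_LABELS[:1]).r_mean) < 0.05:
                hits += 1
        assert hits >= 35  # ~95% of seeds

    def test_constant_eeg_flagged(self):
        env = rand_env(300, seed=9)
        trf = fit_trf_ridge(env, recording(np.random.default_rng(1)
                                           .standard_normal(300)), lags=(0.0, 0.02))
        with pytest.warns(UserWarning, match="constant"):
            acc = predict_accuracy(trf, env, recording(np.ones(300)),
                                   cluster=SCALP_LABELS[:1])
        assert np.isnan(acc.r_mean)


class TestCrossCorrelation:
    def test_detects_imposed_shift(self):
        env = gen_speechlike_envelope(25.0, RATE, seed=1)
        shift = int(0.1 * RATE)
        eeg = recording(np.roll(env.values, shift))
        lags, corr = crosscorr_tracking(env, eeg)
        peak_lag = lags[np.argmax(corr[0])]
        assert abs(peak_lag - 0.1) <= 1.01 / RATE

    def test_identity_has_unit_correlation_at_zero_lag(self):
        env = rand_env(2000, seed=2)
        lags, corr = crosscorr_tracking(env, recording(env.values))
        j = int(np.argmin(np.abs(lags)))
        assert corr[0, j] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_lag_pearson_oracle(self):
        env = rand_env(800, seed=3)
        eeg = recording(np.random.default_rng(4).standard_normal((2, 800)))
        lags, corr = crosscorr_tracking(env, eeg, lags=(-0.02, 0.03))
        ks = lag_shifts(-0.02, 0.03, RATE)
        n = 800
        for j, k in enumerate(ks):
            if k >= 0:
                x, y = env.values[: n - k] if k else env.values, eeg.data[:, k:]
            else:
                x, y = env.values[-k:], eeg.data[:, : n + k]
            for c in range(2):
                expected = sp_stats.pearsonr(x, y[c]).statistic
                assert corr[c, j] == pytest.approx(expected, abs=1e-10)
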