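"""Ridge TRF estimation, cross-validation, permutation baseline."""

import numpy as np
import pytest

from phonotrf.trf import (
    DEFAULT_LAMBDA_GRID,
    cross_validate,
    fisher_mean,
    lag_design_matrix,
    lag_samples,
    permutation_baseline,
    ridge_fit,
)


class TestLagDesign:
    def test_shift_by_hand(self):
        D = lag_design_matrix(np.array([1.0, 0.0, 0.0]), fs=1000.0,
                              lag_window_ms=(0.0, 1.0))
        assert np.array_equal(D, [[1, 0], [0, 1], [0, 0]])

    def test_zero_window_is_identity(self, rng):
        X = rng.random((20, 3))
        D = lag_design_matrix(X, fs=100.0, lag_window_ms=(0.0, 0.0))
        assert np.array_equal(D, X)

    def test_lag_major_column_order(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0], [4.0, 40.0]])
        D = lag_design_matrix(X, fs=1000.0, lag_window_ms=(0.0, 2.0))
        assert D.shape == (4, 6)
        # columns 0..1 are lag 0 (both predictors), 2..3 lag 1, ...
        assert np.array_equal(D[:, 0:2], X)
        assert np.array_equal(D[1:, 2:4], X[:-1])

    def test_negative_lag_is_anticipatory(self):
        x = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        D = lag_design_matrix(x, fs=1000.0, lag_window_ms=(-1.0, 0.0))
        # at lag -1 the column holds x[t+1]
        assert np.array_equal(D[:, 0], [0, 1, 0, 0, 0])

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError):
            lag_design_matrix(np.zeros(5), fs=100, lag_window_ms=(10.0, -10.0))

    def test_default_window_length_at_100hz(self):
        assert lag_samples((-150, 400), 100.0).size == 56


def _ridge_oracle(D, Y, lam):
    """Pseudoinverse solution of the same penalized objective (augmented
    rows), computed via SVD — independent of the solve path under test."""
    mu, sd = D.mean(0), D.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (D - mu) / sd
    scale = np.mean(np.sum(Z ** 2, axis=0))
    aug = np.vstack([Z, np.sqrt(lam * scale) * np.eye(Z.shape[1])])
    Yc = Y - Y.mean(0)
    target = np.vstack([Yc, np.zeros((Z.shape[1], Y.shape[1]))])
    W = np.linalg.pinv(aug) @ target
    return W / sd[:, None]


class TestRidgeFit:
    def test_lambda_zero_equals_ols(self, rng):
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 2))
        model = ridge_fit(X, Y, lam=0.0, lag_window_ms=None)
        W_ols = np.linalg.lstsq(
            np.column_stack([np.ones(60), X]), Y, rcond=None)[0]
        assert np.allclose(model.weights.reshape(5, 2), W_ols[1:], rtol=1e-8,
                           atol=1e-10)

    def test_large_lambda_shrinks_to_zero(self, rng):
        X = rng.standard_normal((50, 4))
        Y = rng.standard_normal((50, 1))
        model = ridge_fit(X, Y, lam=1e12, lag_window_ms=None)
        assert np.abs(model.weights).max() < 1e-6

    def test_exact_recovery_noise_free(self, rng):
        X = rng.standard_normal((200, 4))
        w_true = rng.standard_normal((4, 3))
        Y = X @ w_true
        model = ridge_fit(X, Y, lam=0.0, lag_window_ms=None)
        assert np.allclose(model.weights.reshape(4, 3), w_true, atol=1e-6)

    def test_agrees_with_pinv_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 200))
            p = int(rng.integers(2, 6))
            lam = 10.0 ** rng.uniform(-4, 3)
            X = rng.standard_normal((n, p))
            Y = rng.standard_normal((n, 2))
            model = ridge_fit(X, Y, lam, lag_window_ms=None)
            W_oracle = _ridge_oracle(X, Y, lam)
            assert np.allclose(model.weights.reshape(p, 2), W_oracle,
                               rtol=1e-5, atol=1e-8)

    def test_predict_round_trip(self, rng):
        fs = 100.0
        X = rng.standard_normal((500, 2))
        Y = rng.standard_normal((500, 3))
        model = ridge_fit(X, Y, 1.0, fs=fs, lag_window_ms=(-50.0, 100.0))
        yhat = model.predict(X)
        assert yhat.shape == Y.shape
        # in-sample fit must beat the intercept-only predictor
        assert np.mean((yhat - Y) ** 2) < np.mean((Y - Y.mean(0)) ** 2)


def _simulated_pair(rng, n=6000, fs=100.0, snr_db=10.0):
    from phonotrf.synth import make_kernels, pink_noise

    X = (rng.random((n, 2)) < 0.3).astype(float)
    kernels = make_kernels(2, fs, (-150, 400), rng)
    D = lag_design_matrix(X, fs, (-150, 400))
    y = D @ kernels.reshape(-1)
    noise = pink_noise(n, rng)
    y = y + noise * y.std() / 10 ** (snr_db / 20)
    return X, y[:, None], kernels


class TestCrossValidate:
    fs = 100.0

    def test_recovers_coupling(self, rng):
        X, Y, _ = _simulated_pair(rng)
        cv = cross_validate(X, Y, self.fs)
        assert cv.accuracy[0] > 0.3
        assert cv.per_fold.shape == (10, 1)
        assert np.all(np.isin(cv.best_lambda, DEFAULT_LAMBDA_GRID))

    def test_null_accuracy_near_zero(self, rng):
        X = (rng.random((8000, 2)) < 0.3).astype(float)
        Y = rng.standard_normal((8000, 1))
        cv = cross_validate(X, Y, self.fs)
        assert abs(cv.accuracy[0]) < 0.1

    def test_deterministic(self, rng):
        X, Y, _ = _simulated_pair(rng)
        a = cross_validate(X, Y, self.fs)
        b = cross_validate(X, Y, self.fs)
        assert np.array_equal(a.per_fold, b.per_fold)
        assert np.array_equal(a.best_lambda, b.best_lambda)

    def test_affine_invariance_of_accuracy(self, rng):
        X, Y, _ = _simulated_pair(rng)
        a = cross_validate(X, Y, self.fs)
        b = cross_validate(X, 3.7 * Y + 11.0, self.fs)
        assert np.allclose(a.per_fold, b.per_fold, atol=1e-10)

    def test_accuracy_decreases_with_noise(self, rng):
        """Spearman over an SNR ladder: more noise, lower accuracy."""
        from scipy.stats import spearmanr

        accs, snrs = [], [20, 10, 0, -10]
        for snr in snrs:
            r = []
            for rep in range(3):
                local = np.random.default_rng(1000 * snr + rep + 12345)
                X, Y, _ = _simulated_pair(local, n=4000, snr_db=snr)
                r.append(cross_validate(X, Y, self.fs).accuracy[0])
            accs.append(np.mean(r))
        rho, _ = spearmanr(snrs, accs)
        assert rho == pytest.approx(1.0)

    def test_empty_grid_rejected(self, rng):
        X, Y, _ = _simulated_pair(rng, n=6000)
        with pytest.raises(ValueError):
            cross_validate(X, Y, self.fs, lambda_grid=())

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((100, 1)), np.zeros((100, 1)), self.fs)


class _ZeroShiftRng:
    """Stub generator whose integers() always returns 0 (degenerate shift)."""

    def integers(self, lo, hi, endpoint=False):
        return 0


class TestPermutationBaseline:
    fs = 100.0

    def test_zero_shift_equals_observed(self, rng, monkeypatch):
        X, Y, _ = _simulated_pair(rng)
        obs = cross_validate(X, Y, self.fs)
        monkeypatch.setattr(np.random, "default_rng",
                            lambda *_a, **_k: _ZeroShiftRng())
        base = permutation_baseline(X, Y, self.fs, rng=None)
        assert np.allclose(base.per_fold, obs.per_fold, atol=1e-12)

    def test_baseline_destroys_coupling(self, rng):
        X, Y, _ = _simulated_pair(rng)
        obs = cross_validate(X, Y, self.fs)
        base = permutation_baseline(X, Y, self.fs, rng=7)
        assert base.kind == "baseline"
        assert obs.accuracy[0] - base.accuracy[0] > 0.2

    def test_seeded_reproducibility(self, rng):
        X, Y, _ = _simulated_pair(rng)
        a = permutation_baseline(X, Y, self.fs, rng=3)
        b = permutation_baseline(X, Y, self.fs, rng=3)
        assert np.array_equal(a.per_fold, b.per_fold)

    def test_too_short_for_shift_rejected(self, rng):
        X = rng.random((500, 1))
        with pytest.raises(ValueError):
            permutation_baseline(X, X, self.fs, min_shift_s=5.0)


def test_fisher_mean_bounds():
    r = np.array([[0.5, -0.2], [0.7, 0.0]])
    m = fisher_mean(r, axis=0)
    assert (np.abs(m) <= 1).all()
    assert m[0] == pytest.approx(np.tanh(np.mean(np.arctanh([0.5, 0.7]))))
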