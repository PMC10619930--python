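"""Forward TRF encoding models by regularized lagged regression.

A temporal response function (TRF) is a linear kernel ``w(lag, predictor,
electrode)`` mapping stimulus predictors to the EEG across a window of time
lags (default -150 to 400 ms).  Kernels are estimated by ridge regression on
the lag-expanded design matrix; model quality is the cross-validated Pearson
correlation between predicted and observed EEG (prediction accuracy), and a
permutation baseline repeats the procedure with circularly time-shifted
predictors to embody the no-relationship null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

DEFAULT_LAG_WINDOW_MS = (-150.0, 400.0)

#: One grid point per decade from 1e-7 to 1e7.
DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-7, 8))


def lag_samples(lag_window_ms, fs: float) -> np.ndarray:
    """Integer lag offsets (in samples) covering the window, inclusive."""
    lo, hi = lag_window_ms
    if lo > hi:
        raise ValueError(f"reversed lag window: {lag_window_ms}")
    return np.arange(int(round(lo / 1000 * fs)), int(round(hi / 1000 * fs)) + 1)


def lag_design_matrix(
    X: np.ndarray, fs: float, lag_window_ms=DEFAULT_LAG_WINDOW_MS
) -> np.ndarray:
    """Lag-expanded design matrix, lag-major column order.

    Column ``(l, p)`` (lag index ``l`` outermost) at row ``t`` equals
    predictor ``p`` at time ``t - l``; out-of-range rows are zero.  A
    negative lag means the response precedes the predictor sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1] and X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    n, p = X.shape
    lags = lag_samples(lag_window_ms, fs)
    L = lags.size
    l_max = int(lags[-1])
    pad_front = max(l_max, 0)
    pad_back = max(-int(lags[0]), 0)
    Xp = np.zeros((pad_front + n + pad_back, p))
    Xp[pad_front:pad_front + n] = X
    # windows[i, :, w] = Xp[i + w]; with w = l_max - l and
    # i = t + pad_front - l_max this indexes X[t - l]
    windows = np.lib.stride_tricks.sliding_window_view(Xp, L, axis=0)
    start = pad_front - l_max
    D = windows[start:start + n, :, ::-1]   # lag ascending along last axis
    return np.ascontiguousarray(D.transpose(0, 2, 1)).reshape(n, L * p)


@dataclass
class TRFModel:
    """Estimated TRF kernel with its regularization parameter."""

    weights: np.ndarray          # (lags, predictors, electrodes)
    intercept: np.ndarray        # (electrodes,)
    lag_window_ms: tuple[float, float]
    lam: float
    fs: float

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    def kernel(self, predictor: int, electrode: int = 0) -> np.ndarray:
        return self.weights[:, predictor, electrode]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict EEG (samples x electrodes) from raw predictors."""
        D = lag_design_matrix(X, self.fs, self.lag_window_ms)
        flat = self.weights.reshape(-1, self.weights.shape[2])
        return D @ flat + self.intercept


def _ridge_solve(
    D: np.ndarray, Y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge weights in original units plus intercept.

    Columns are z-scored internally; the penalty is ``lam`` times the
    identity scaled by the mean diagonal of the z-scored Gram matrix.
    """
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (D - mu) / sd_safe
    ymu = Y.mean(axis=0)
    G = Z.T @ Z
    scale = float(np.mean(np.diag(G))) or 1.0
    A = G + lam * scale * np.eye(G.shape[0])
    B = Z.T @ (Y - ymu)
    try:
        W = linalg.solve(A, B, assume_a="pos")
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "singular normal equations; use lambda > 0 for collinear designs"
        ) from err
    W = W / sd_safe[:, None]
    intercept = ymu - mu @ W
    return W, intercept


def ridge_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    fs: float = 1.0,
    lag_window_ms: tuple[float, float] | None = None,
    n_predictors: int | None = None,
) -> TRFModel:
    """Fit a TRF by ridge regression.

    ``X`` is either a raw predictor matrix (pass ``lag_window_ms`` to expand
    it) or an already lag-expanded design matrix (``lag_window_ms=None``, in
    which case ``n_predictors`` fixes the (lags, predictors) factorization;
    default one lag).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lag_window_ms is not None:
        p = np.atleast_2d(X).shape[1]
        D = lag_design_matrix(X, fs, lag_window_ms)
        n_lags = lag_samples(lag_window_ms, fs).size
        window = tuple(lag_window_ms)
    else:
        D = np.atleast_2d(np.asarray(X, dtype=float))
        p = n_predictors or D.shape[1]
        n_lags = D.shape[1] // p
        window = (0.0, (n_lags - 1) / fs * 1000.0)
    if D.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    W, intercept = _ridge_solve(D, Y, lam)
    return TRFModel(W.reshape(n_lags, p, Y.shape[1]), intercept, window, lam, fs)


def _pearson_cols(yhat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; 0 where either side is constant."""
    yh = yhat - yhat.mean(axis=0)
    yy = y - y.mean(axis=0)
    num = (yh * yy).sum(axis=0)
    den = np.sqrt((yh ** 2).sum(axis=0) * (yy ** 2).sum(axis=0))
    out = np.zeros(y.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def fisher_mean(r: np.ndarray, axis=0) -> np.ndarray:
    """Fisher-z average of correlation coefficients."""
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    return np.tanh(z.mean(axis=axis))


@dataclass
class CVResult:
    """Cross-validated prediction accuracy per electrode."""

    accuracy: np.ndarray         # (electrodes,) Fisher-z mean of fold r
    per_fold: np.ndarray         # (folds, electrodes)
    best_lambda: np.ndarray      # (folds,)
    kind: str = "observed"       # "observed" | "baseline"


def _contiguous_blocks(n: int, folds: int) -> list[np.ndarray]:
    return [np.asarray(b) for b in np.array_split(np.arange(n), folds)]


def _block_stats(D: np.ndarray, Y: np.ndarray, blocks, needed) -> list:
    """Per-block sufficient statistics (Gram, cross-product, sums)."""
    out = [None] * len(blocks)
    for b in needed:
        Db, Yb = D[blocks[b]], Y[blocks[b]]
        out[b] = (Db.T @ Db, Db.T @ Yb, Db.sum(axis=0), Yb.sum(axis=0),
                  len(blocks[b]))
    return out


def _fit_score_fold(
    D: np.ndarray,
    Y: np.ndarray,
    blocks: list[np.ndarray],
    fold: int,
    lambda_grid,
    valid: np.ndarray,
    stats: list | None = None,
) -> tuple[float, float, np.ndarray]:
    """Train on ~80%, tune lambda on the validation block, score the test
    block.  Returns (best lambda, mean validation r, test r per electrode).

    Works from per-block sufficient statistics: the train Gram/cross-product
    are block sums, centering and column standardisation are applied in
    Gram space (equivalent to z-scoring the train design)."""
    folds = len(blocks)
    vi = (fold + 1) % folds
    train_b = [b for b in range(folds) if b not in (fold, vi)]
    if stats is None:
        stats = _block_stats(D, Y, blocks, train_b)
    G = sum(stats[b][0] for b in train_b)
    C = sum(stats[b][1] for b in train_b)
    z = sum(stats[b][2] for b in train_b)
    y = sum(stats[b][3] for b in train_b)
    ntr = sum(stats[b][4] for b in train_b)
    mu = z / ntr
    ymu = y / ntr
    Gc = G - np.outer(z, z) / ntr
    Cc = C - np.outer(z, y) / ntr
    var = np.clip(np.diag(Gc) / ntr, 0.0, None)
    sd_safe = np.where(var > 0, np.sqrt(var), 1.0)
    Gz = Gc / np.outer(sd_safe, sd_safe)
    Cz = Cc / sd_safe[:, None]
    scale = float(np.mean(np.diag(Gz))) or 1.0
    eye = np.eye(Gz.shape[0])

    def prepared(idx: np.ndarray):
        rows = idx[valid[idx]]
        if rows.size < 3:
            return None, None
        return (D[rows] - mu) / sd_safe, Y[rows]

    Zval, Yval = prepared(blocks[vi])
    Ztest, Ytest = prepared(blocks[fold])

    best_lam, best_val, best_W = None, -np.inf, None
    for lam in lambda_grid:
        W = linalg.solve(Gz + lam * scale * eye, Cz, assume_a="pos")
        if Zval is None:
            v, W_keep = 0.0, W
        else:
            v = float(_pearson_cols(Zval @ W + ymu, Yval).mean())
        if v > best_val:
            best_lam, best_val, best_W = lam, v, W
    if Ztest is None:
        return best_lam, best_val, np.zeros(Y.shape[1])
    return best_lam, best_val, _pearson_cols(Ztest @ best_W + ymu, Ytest)


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    fs: float,
    lag_window_ms=DEFAULT_LAG_WINDOW_MS,
    folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    valid: np.ndarray | None = None,
) -> CVResult:
    """10-fold cross-validated prediction accuracy.

    The time axis is split into contiguous blocks; per fold the model is fit
    on ~80% of blocks, lambda is tuned on a fold-specific validation block
    (exhaustive search over ``lambda_grid``), and Pearson r between
    predicted and observed EEG is reported on the held-out test block.
    ``valid`` marks rows that are real data (inserted zero gaps are excluded
    from scoring but retained in training).  Deterministic.
    """
    if not len(tuple(lambda_grid)):
        raise ValueError("empty lambda grid")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must share the time axis")
    min_len = folds * (lag_samples(lag_window_ms, fs).size + int(fs))
    if n < min_len:
        raise ValueError(f"need >= {min_len} samples for {folds}-fold CV")
    if valid is None:
        valid = np.ones(n, dtype=bool)
    D = lag_design_matrix(X, fs, lag_window_ms)
    blocks = _contiguous_blocks(n, folds)
    stats = _block_stats(D, Y, blocks, range(folds))
    per_fold = np.empty((folds, Y.shape[1]))
    best_lams = np.empty(folds)
    for f in range(folds):
        best_lams[f], _, per_fold[f] = _fit_score_fold(
            D, Y, blocks, f, lambda_grid, valid, stats=stats)
    return CVResult(fisher_mean(per_fold, axis=0), per_fold, best_lams, "observed")


def permutation_baseline(
    X: np.ndarray,
    Y: np.ndarray,
    fs: float,
    lag_window_ms=DEFAULT_LAG_WINDOW_MS,
    folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    valid: np.ndarray | None = None,
    n_per_fold: int = 1,
    rng: np.random.Generator | int | None = 0,
    min_shift_s: float = 5.0,
) -> CVResult:
    """Surrogate accuracy with circularly time-shifted predictors.

    For every fold (and each of ``n_per_fold`` repeats) the raw predictors
    are circularly shifted by a uniform random offset between ``min_shift_s``
    and ``duration - min_shift_s`` before the fold is re-fit and re-scored;
    the shift destroys the predictor-EEG alignment while preserving the
    predictor statistics.
    """
    rng = np.random.default_rng(rng)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    min_shift = int(round(min_shift_s * fs))
    if n <= 2 * min_shift:
        raise ValueError("record too short for the minimum time shift")
    if valid is None:
        valid = np.ones(n, dtype=bool)
    blocks = _contiguous_blocks(n, folds)
    per_fold = np.empty((folds, Y.shape[1]))
    best_lams = np.empty(folds)
    for f in range(folds):
        rs, lams = [], []
        for _ in range(n_per_fold):
            shift = int(rng.integers(min_shift, n - min_shift, endpoint=True))
            D = lag_design_matrix(np.roll(X, shift, axis=0), fs, lag_window_ms)
            lam, _, r = _fit_score_fold(D, Y, blocks, f, lambda_grid, valid)
            rs.append(r)
            lams.append(lam)
        per_fold[f] = fisher_mean(np.asarray(rs), axis=0)
        best_lams[f] = lams[-1]
    return CVResult(fisher_mean(per_fold, axis=0), per_fold, best_lams, "baseline")


def best_electrode(accuracies: np.ndarray) -> int:
    """Index of the electrode with highest mean accuracy across a stack of
    CV accuracies (participants/conditions x electrodes)."""
    acc = np.atleast_2d(np.asarray(accuracies, dtype=float))
    return int(np.argmax(acc.mean(axis=0)))
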