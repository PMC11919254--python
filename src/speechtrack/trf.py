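"""Forward (encoding) temporal response function models.

A TRF is a lag-indexed linear kernel mapping the speech onset-envelope to
EEG. Weights are estimated per channel by ridge regression on z-scored
lagged predictor columns,

    (Z'Z + lambda I) w = Z'y,

with the regularization parameter fixed at lambda = 10. Model estimation
follows a snippet scheme: 50 random 25-s snippets per story, each held out
once while all snippets not overlapping it form the training set (training
snippets may overlap one another); prediction accuracy is the Pearson
correlation between predicted and observed EEG on the held-out snippet,
averaged over snippets and channels. TRF weights for component analysis use
the broader analysis lag range (-0.15 to 0.5 s); prediction uses 0 to 0.4 s.

The usage pattern mirrors statsmodels: build a
:class:`TemporalResponseFunction` model from an envelope and an EEG
recording, call ``fit()`` (full data) or ``fit_crossval()`` (snippet
cross-validation), and read estimates off the returned results object.

Implementation note: training Gram matrices are accumulated per snippet as
sums of X'X and X'y (algebraically identical to concatenating snippets);
because every predictor column is a shift of the same envelope, each
snippet's X'X is assembled exactly from prefix sums of lag-difference
products in O(L^2) lookups instead of an O(n L^2) matrix product. The
z-scoring of columns is applied to the accumulated moments afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .envelope import EnvelopeSeries
from .preprocess import FRONTO_CENTRAL, EEGRecording

__all__ = [
    "SnippetScheme",
    "PredictionAccuracy",
    "TRFResults",
    "SnippetCVResults",
    "TemporalResponseFunction",
    "lag_shifts",
    "build_design_matrix",
    "fit_trf_ridge",
    "snippet_crossval",
    "predict_accuracy",
    "crosscorr_tracking",
]

PREDICTION_LAGS = (0.0, 0.4)
ANALYSIS_LAGS = (-0.15, 0.5)


@dataclass
class SnippetScheme:
    """Random-snippet cross-validation layout (50 snippets of 25 s)."""

    n_snippets: int = 50
    duration: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snippets < 2:
            raise ValueError("need at least 2 snippets")
        if self.duration <= 0:
            raise ValueError("snippet duration must be positive")


@dataclass
class PredictionAccuracy:
    """Pearson correlations between predicted and observed EEG.

    ``r_per_snippet`` has one row per held-out snippet (or a single row for
    a plain prediction) and one column per channel; ``r_mean`` averages over
    snippets and channels (NaN-aware: degenerate constant segments are
    excluded).
    """

    r_per_snippet: np.ndarray
    r_mean: float

    def __post_init__(self) -> None:
        self.r_per_snippet = np.atleast_2d(np.asarray(self.r_per_snippet, float))
        finite = self.r_per_snippet[np.isfinite(self.r_per_snippet)]
        if finite.size and (np.any(finite > 1 + 1e-12) or np.any(finite < -1 - 1e-12)):
            raise ValueError("correlations must lie in [-1, 1]")


def lag_shifts(lag_min: float, lag_max: float, rate: float) -> np.ndarray:
    """Integer sample shifts for all lags inside [lag_min, lag_max].

    The grid is every integer shift k with lag_min <= k/rate <= lag_max
    (small float tolerance), ascending.
    """
    if not lag_min < lag_max:
        raise ValueError("need lag_min < lag_max")
    tol = 1e-9
    k_min = int(np.ceil(lag_min * rate - tol))
    k_max = int(np.floor(lag_max * rate + tol))
    return np.arange(k_min, k_max + 1)


def build_design_matrix(
    env: EnvelopeSeries | np.ndarray,
    lag_min: float,
    lag_max: float,
    rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged predictor matrix: column j at row t equals env(t - lag_j).

    Samples outside the story are zero-padded. Returns ``(X, lags)`` with
    ``X`` of shape (n_samples, n_lags) and ``lags`` in seconds.
    """
    if isinstance(env, EnvelopeSeries):
        values, rate = env.values, env.rate
    else:
        if rate is None:
            raise ValueError("rate required when env is a plain array")
        values = np.asarray(env, float)
    ks = lag_shifts(lag_min, lag_max, rate)
    n = values.size
    if n <= ks[-1] - ks[0]:
        raise ValueError("envelope shorter than the lag span")
    K = int(max(abs(ks[0]), abs(ks[-1]), 1))
    padded = np.zeros(n + 2 * K)
    padded[K : K + n] = values
    X = np.empty((n, ks.size))
    for j, k in enumerate(ks):
        X[:, j] = padded[K - k : K - k + n]
    return X, ks / rate


def _zscore_moments(
    G: np.ndarray, b: np.ndarray, csum: np.ndarray, ysum: np.ndarray, nrows: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert raw moments (X'X, X'Y, column sums, response sums) into the
    z-scored, response-centered normal equations."""
    mu = csum / nrows
    var = np.diag(G) / nrows - mu**2
    sd = np.sqrt(np.maximum(var, 0.0))
    sd_safe = np.where(sd > 0, sd, 1.0)
    A = (G - nrows * np.outer(mu, mu)) / np.outer(sd_safe, sd_safe)
    rhs = (b - np.outer(mu, ysum)) / sd_safe[:, None]
    return A, rhs, mu, sd_safe, ysum / nrows


def _ridge_solve(A: np.ndarray, rhs: np.ndarray, lam: float) -> np.ndarray:
    M = A + lam * np.eye(A.shape[0])
    if lam > 0:
        c, low = linalg.cho_factor(M)
        return linalg.cho_solve((c, low), rhs)
    try:
        return linalg.solve(M, rhs, assume_a="pos")
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "design matrix is rank-deficient with lambda=0; use lambda > 0"
        ) from err


@dataclass
class TRFResults:
    """Fitted TRF weights and the metadata needed to predict with them.

    ``weights`` (channels x lags) are on z-scored predictor columns;
    ``kernel`` rescales them to per-unit-envelope amplitude (weights divided
    by the column scales), which is the time course used for component
    analysis and kernel-recovery comparisons.
    """

    weights: np.ndarray
    lags: np.ndarray
    lam: float
    col_means: np.ndarray
    col_scales: np.ndarray
    y_means: np.ndarray
    labels: tuple[str, ...]
    rate: float
    normalization: str = "zscored predictor columns; response in original units"

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, float))
        self.lags = np.asarray(self.lags, float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("TRF weights must be finite")
        steps = np.diff(self.lags)
        if np.any(steps <= 0) or not np.allclose(steps, 1.0 / self.rate):
            raise ValueError("lags must increase uniformly by 1/rate")

    @property
    def kernel(self) -> np.ndarray:
        """Weights in envelope units (channels x lags)."""
        return self.weights / self.col_scales[None, :]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def predict(self, env: EnvelopeSeries) -> np.ndarray:
        """Predicted EEG (channels x samples) for an envelope at the model
        rate, using the stored column standardization."""
        if env.rate != self.rate:
            raise ValueError("envelope rate must match the fitted model rate")
        X, _ = build_design_matrix(env, self.lags[0], self.lags[-1])
        Z = (X - self.col_means) / self.col_scales
        return (Z @ self.weights.T + self.y_means).T

    def plot(self, ax=None, cluster: tuple[str, ...] | None = None):
        """Plot the TRF time course (envelope units) per channel, or the
        mean over ``cluster`` channels if given. Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = self.kernel
        if cluster is not None:
            idx = [self.labels.index(c) for c in cluster if c in self.labels]
            ax.plot(self.lags, k[idx].mean(axis=0), color="k", label="cluster mean")
            ax.legend()
        else:
            for row, lab in zip(k, self.labels):
                ax.plot(self.lags, row, lw=0.8, label=lab)
        ax.axhline(0.0, color="0.7", lw=0.5)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("TRF amplitude (a.u. per unit envelope)")
        return ax

    def summary(self) -> str:
        lines = [
            "Temporal response function (ridge)",
            "=" * 44,
            f"channels:        {self.n_channels}",
            f"lags:            {self.lags[0]:+.4f} .. {self.lags[-1]:+.4f} s "
            f"({self.lags.size} taps @ {self.rate:g} Hz)",
            f"lambda:          {self.lam:g}",
            f"normalization:   {self.normalization}",
        ]
        k = self.kernel.mean(axis=0)
        lines.append(
            f"mean-kernel extrema: max {k.max():+.4g} at "
            f"{self.lags[np.argmax(k)]:+.3f} s, min {k.min():+.4g} at "
            f"{self.lags[np.argmin(k)]:+.3f} s"
        )
        return "\n".join(lines)


@dataclass
class SnippetCVResults:
    """Snippet cross-validation output: the TRF averaged over training fits
    plus held-out prediction accuracy."""

    trf: TRFResults
    accuracy: PredictionAccuracy
    snippet_starts: np.ndarray

    def summary(self) -> str:
        return (
            self.trf.summary()
            + f"\nsnippets:        {self.snippet_starts.size}"
            + f"\nprediction r:    {self.accuracy.r_mean:+.4f} "
            "(mean over snippets and channels)"
        )


class TemporalResponseFunction:
    """Ridge TRF model of an EEG recording given a stimulus envelope.

    Parameters
    ----------
    env : EnvelopeSeries
        Stimulus regressor at the EEG rate (onset envelope by convention,
        computed from the clear speech).
    eeg : EEGRecording
        Response recording, same rate and length as ``env``.
    lags : (float, float)
        Lag range in seconds (default 0 to 0.4 s, the prediction
        convention; use -0.15 to 0.5 s for component analysis).
    lam : float
        Ridge parameter on z-scored predictor columns (default 10).
    """

    def __init__(
        self,
        env: EnvelopeSeries,
        eeg: EEGRecording,
        lags: tuple[float, float] = PREDICTION_LAGS,
        lam: float = 10.0,
    ) -> None:
        if env.rate != eeg.rate:
            raise ValueError("envelope and EEG must share one sampling rate")
        if env.n_samples != eeg.n_samples:
            raise ValueError("envelope and EEG must be aligned (same length)")
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        self.env = env
        self.eeg = eeg
        self.lag_range = (float(lags[0]), float(lags[1]))
        self.lam = float(lam)
        self._ks = lag_shifts(*self.lag_range, env.rate)

    # -- full-data fit ----------------------------------------------------
    def fit(self) -> TRFResults:
        """Single ridge fit on the full recording."""
        X, lags = build_design_matrix(self.env, *self.lag_range)
        Y = self.eeg.data.T  # samples x channels
        n = X.shape[0]
        G = X.T @ X
        b = X.T @ Y
        A, rhs, mu, sd, ym = _zscore_moments(G, b, X.sum(axis=0), Y.sum(axis=0), n)
        w = _ridge_solve(A, rhs, self.lam)
        return TRFResults(
            weights=w.T, lags=lags, lam=self.lam, col_means=mu, col_scales=sd,
            y_means=ym, labels=self.eeg.labels, rate=self.env.rate,
        )

    # -- snippet cross-validation -----------------------------------------
    def _snippet_starts(self, scheme: SnippetScheme, dur: int) -> np.ndarray:
        n = self.env.n_samples
        n_starts = n - dur + 1
        if n_starts < 1:
            raise ValueError("story shorter than the snippet duration")
        if n_starts < scheme.n_snippets:
            raise ValueError(
                "story too short to draw snippet starts without replacement"
            )
        rng = np.random.default_rng(scheme.seed)
        return np.sort(rng.choice(n_starts, size=scheme.n_snippets, replace=False))

    def fit_crossval(self, scheme: SnippetScheme | None = None) -> SnippetCVResults:
        """Snippet-based cross-validation.

        Each snippet is held out once; training moments are the sums over
        all snippets that do not overlap the held-out one. The returned TRF
        is the average of the per-fold training fits (in envelope units);
        accuracy holds the held-out Pearson correlations.
        """
        scheme = scheme or SnippetScheme()
        rate = self.env.rate
        dur = int(round(scheme.duration * rate))
        ks = self._ks
        L = ks.size
        if dur <= ks[-1] - ks[0]:
            raise ValueError("snippet duration shorter than the lag span")
        starts = self._snippet_starts(scheme, dur)
        nsnip = starts.size

        values = self.env.values
        n = values.size
        K = int(max(abs(ks[0]), abs(ks[-1]), 1))
        padded = np.zeros(n + 2 * K)
        padded[K : K + n] = values
        m = padded.size

        # prefix sums of lag-difference products: T[d, u] = sum of
        # padded[v] * padded[v + d] for v < u
        D = int(ks[-1] - ks[0])
        T = np.zeros((D + 1, m + 1))
        for d in range(D + 1):
            prod = padded[: m - d] * padded[d:]
            np.cumsum(prod, out=T[d, 1 : m - d + 1])
            if d:
                T[d, m - d + 1 :] = T[d, m - d]
        cumP = np.concatenate([[0.0], np.cumsum(padded)])

        # per-pair lookup geometry: for columns i, j the product series is at
        # lag difference |k_i - k_j| and the snippet window starts at
        # K + s - max(k_i, k_j)
        d_mat = np.abs(ks[:, None] - ks[None, :])
        base = K - np.maximum(ks[:, None], ks[None, :])

        Y = self.eeg.data  # channels x samples
        C = Y.shape[0]
        Gs = np.empty((nsnip, L, L))
        bs = np.empty((nsnip, L, C))
        csums = np.empty((nsnip, L))
        ysums = np.empty((nsnip, C))
        Xbuf = np.empty((dur, L))
        for f, s in enumerate(starts):
            lo = base + s
            Gs[f] = T[d_mat, lo + dur] - T[d_mat, lo]
            col_lo = K + s - ks
            csums[f] = cumP[col_lo + dur] - cumP[col_lo]
            for j, k in enumerate(ks):
                Xbuf[:, j] = padded[K + s - k : K + s - k + dur]
            Ys = Y[:, s : s + dur].T
            bs[f] = Xbuf.T @ Ys
            ysums[f] = Ys.sum(axis=0)

        nonoverlap = np.abs(starts[:, None] - starts[None, :]) >= dur
        if not np.all(nonoverlap.sum(axis=1) >= 1):
            raise ValueError(
                "every snippet overlaps all others; story too short for the scheme"
            )

        kernels = np.zeros((C, L))
        mus = np.zeros(L)
        sds = np.zeros(L)
        ymeans = np.zeros(C)
        r = np.full((nsnip, C), np.nan)
        flat = Gs.reshape(nsnip, -1)
        for f in range(nsnip):
            sel = nonoverlap[f].astype(float)
            G = (sel @ flat).reshape(L, L)
            b = np.tensordot(sel, bs, axes=(0, 0))
            csum = sel @ csums
            ysum = sel @ ysums
            nrows = int(nonoverlap[f].sum()) * dur
            A, rhs, mu, sd, ym = _zscore_moments(G, b, csum, ysum, nrows)
            w = _ridge_solve(A, rhs, self.lam)  # L x C
            kernels += (w / sd[:, None]).T
            mus += mu
            sds += sd
            ymeans += ym

            # held-out prediction
            s = starts[f]
            for j, k in enumerate(ks):
                Xbuf[:, j] = padded[K + s - k : K + s - k + dur]
            pred = ((Xbuf - mu) / sd) @ w  # dur x C
            obs = Y[:, s : s + dur].T
            r[f] = _pearson_columns(pred, obs)

        sds /= nsnip
        mus /= nsnip
        trf = TRFResults(
            weights=(kernels / nsnip) * sds[None, :],
            lags=ks / rate, lam=self.lam, col_means=mus, col_scales=sds,
            y_means=ymeans / nsnip, labels=self.eeg.labels, rate=rate,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r_mean = float(np.nanmean(r))
        return SnippetCVResults(
            trf=trf, accuracy=PredictionAccuracy(r, r_mean), snippet_starts=starts
        )


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (n x c) arrays; NaN where a
    column is constant."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.clip(r, -1.0, 1.0)


# -- functional wrappers (thin aliases over the model object) --------------

def fit_trf_ridge(
    env: EnvelopeSeries,
    eeg: EEGRecording,
    lam: float = 10.0,
    lags: tuple[float, float] = PREDICTION_LAGS,
) -> TRFResults:
    """Full-data ridge TRF fit; see :class:`TemporalResponseFunction`."""
    return TemporalResponseFunction(env, eeg, lags=lags, lam=lam).fit()


def snippet_crossval(
    env: EnvelopeSeries,
    eeg: EEGRecording,
    scheme: SnippetScheme | None = None,
    lam: float = 10.0,
    lags: tuple[float, float] = PREDICTION_LAGS,
) -> SnippetCVResults:
    """Snippet cross-validation; see
    :meth:`TemporalResponseFunction.fit_crossval`."""
    return TemporalResponseFunction(env, eeg, lags=lags, lam=lam).fit_crossval(scheme)


def predict_accuracy(
    trf: TRFResults,
    env: EnvelopeSeries,
    eeg: EEGRecording,
    cluster: tuple[str, ...] = FRONTO_CENTRAL,
) -> PredictionAccuracy:
    """Pearson correlation between TRF-predicted and observed EEG.

    Computes per-channel correlations and averages them over the
    fronto-central cluster (channels present in the recording). Constant
    predictions or responses yield NaN with a warning.
    """
    pred = trf.predict(env)
    r = _pearson_columns(pred.T, eeg.data.T)
    if np.any(~np.isfinite(r)):
        warnings.warn(
            "constant prediction or EEG channel: correlation undefined (NaN)",
            stacklevel=2,
        )
    idx = [i for i, lab in enumerate(eeg.labels) if lab in cluster]
    if not idx:
        raise ValueError("no cluster channels present in the recording")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_mean = float(np.nanmean(r[idx]))
    return PredictionAccuracy(r[None, :], r_mean)


def crosscorr_tracking(
    env: EnvelopeSeries,
    eeg: EEGRecording,
    lags: tuple[float, float] = ANALYSIS_LAGS,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation (Pearson at each lag) per channel.

    A model-free alternative to the ridge TRF: returns ``(lag_grid,
    corr)`` with ``corr`` of shape (channels, n_lags), where lag k uses the
    fully overlapping segment of env(t - k) and eeg(t).
    """
    if env.rate != eeg.rate:
        raise ValueError("envelope and EEG must share one sampling rate")
    if env.n_samples != eeg.n_samples:
        raise ValueError("envelope and EEG must be aligned (same length)")
    ks = lag_shifts(*lags, env.rate)
    n = env.n_samples
    out = np.full((eeg.n_channels, ks.size), np.nan)
    for j, k in enumerate(ks):
        if k >= 0:
            x = env.values[: n - k] if k else env.values
            yseg = eeg.data[:, k:]
        else:
            x = env.values[-k:]
            yseg = eeg.data[:, : n + k]
        out[:, j] = _pearson_columns(x[:, None], yseg.T)
    return ks / env.rate, out
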