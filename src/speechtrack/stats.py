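"""Condition-level statistics for SNR profiles.

Covers the analysis applied per metric (P1-N1, P2-N1, prediction accuracy,
behavior): a sliding average over neighboring SNR conditions, paired
t-tests of each SNR condition against clear speech with Benjamini-Hochberg
FDR control, and an explorative two-piece ("broken-stick") regression whose
breakpoint minimizes the combined RMSE on the across-participant mean, with
per-participant slopes tested against zero per piece.

The two pieces are independent least-squares lines (no continuity
constraint) and the breakpoint sample belongs to both pieces; among RMSE
ties the highest-SNR candidate wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SNRProfile",
    "TTestResult",
    "PiecewiseFit",
    "PiecewiseRegression",
    "sliding_average",
    "paired_tests_vs_clear",
    "piecewise_fit",
    "slope_ttest",
]


@dataclass
class SNRProfile:
    """Per-participant values on a descending SNR grid.

    ``x`` holds condition SNRs in dB (strictly decreasing); ``y`` is a
    participants x conditions matrix of the metric named by ``metric``.
    """

    x: np.ndarray
    y: np.ndarray
    metric: str = "p1n1"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.atleast_2d(np.asarray(self.y, float))
        if self.y.shape[1] != self.x.size:
            raise ValueError("y columns must align with the SNR grid")
        if np.any(np.diff(self.x) >= 0):
            raise ValueError("SNR grid must be strictly decreasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("profile values must be finite (no missing cells)")

    @property
    def n_participants(self) -> int:
        return self.y.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format tidy table (participant, snr_db, value, metric)."""
        p, c = np.meshgrid(np.arange(self.n_participants), self.x, indexing="ij")
        return pd.DataFrame(
            {
                "participant": p.ravel(),
                "snr_db": c.ravel(),
                "value": self.y.ravel(),
                "metric": self.metric,
            }
        )


@dataclass
class TTestResult:
    """t statistic, degrees of freedom, two-sided p, and Cohen's d (mean
    difference over the SD of differences)."""

    t: float
    dof: int
    p: float
    d: float


def sliding_average(profile: SNRProfile, window: int) -> SNRProfile:
    """Average ``window`` neighboring SNR conditions (moving mean).

    Output has n - window + 1 conditions; the output grid takes the center
    SNR for odd windows and the mean of the window's SNRs for even windows
    (identical for equally spaced grids).
    """
    n = profile.x.size
    if window < 1:
        raise ValueError("window must be at least 1")
    if window > n:
        raise ValueError(f"window {window} exceeds the {n} conditions")
    y = np.lib.stride_tricks.sliding_window_view(profile.y, window, axis=1).mean(-1)
    x = np.lib.stride_tricks.sliding_window_view(profile.x, window).mean(-1)
    return SNRProfile(x, y, metric=profile.metric)


def _paired_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    diff = np.asarray(a, float) - np.asarray(b, float)
    if diff.size < 2:
        raise ValueError("need at least 2 participants")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sp_stats.ttest_rel(a, b)
    return TTestResult(
        t=float(res.statistic), dof=diff.size - 1, p=float(res.pvalue),
        d=float(diff.mean() / sd),
    )


def paired_tests_vs_clear(
    clear: np.ndarray, conditions: SNRProfile, q: float = 0.05
) -> tuple[list[TTestResult], np.ndarray, np.ndarray]:
    """Paired t-test of every SNR condition against the clear condition,
    FDR-corrected (Benjamini-Hochberg step-up) over the condition family.

    Returns ``(tests, significant, p_fdr)`` where ``significant`` flags
    conditions with FDR-adjusted p <= q.
    """
    clear = np.asarray(clear, float)
    if clear.size != conditions.n_participants:
        raise ValueError("clear values must cover the same participants")
    tests = [
        _paired_t(conditions.y[:, j], clear) for j in range(conditions.x.size)
    ]
    pvals = np.array([t.p for t in tests])
    significant, p_fdr, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return tests, significant, p_fdr


def slope_ttest(slopes: np.ndarray) -> TTestResult:
    """One-sample two-sided t-test of per-participant slopes against zero."""
    slopes = np.asarray(slopes, float)
    if slopes.size < 2:
        raise ValueError("need at least 2 participants")
    sd = slopes.std(ddof=1)
    if sd == 0:
        if np.all(slopes == 0):
            # identically-zero slopes: trivially non-significant
            return TTestResult(t=0.0, dof=slopes.size - 1, p=1.0, d=0.0)
        raise ValueError("zero-variance slopes: t undefined")
    res = sp_stats.ttest_1samp(slopes, 0.0)
    return TTestResult(
        t=float(res.statistic), dof=slopes.size - 1, p=float(res.pvalue),
        d=float(slopes.mean() / sd),
    )


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line per row of y; returns (slopes, residual SSE)."""
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ coef
    return coef[0], (resid**2).sum(axis=0)


@dataclass
class PiecewiseFit:
    """Broken-stick result: breakpoint on the condition grid, group and
    per-participant slopes per piece, slope t-tests, and the total RMSE at
    the optimum."""

    breakpoint: float
    slopes_group: tuple[float, float]
    slopes_per_participant: np.ndarray
    t_stats: tuple[TTestResult, TTestResult]
    rmse: float
    metric: str = ""

    def plot(self, profile: "SNRProfile", ax=None):
        """Plot the group-mean profile with the two fitted pieces and the
        breakpoint. Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, g = profile.x, profile.y.mean(axis=0)
        ax.plot(x, g, "o", color="0.3", ms=4, label="group mean")
        i = int(np.argmin(np.abs(x - self.breakpoint)))
        for sl, seg in zip(self.slopes_group, (slice(0, i + 1), slice(i, x.size))):
            xx = x[seg]
            coef = np.polyfit(xx, g[seg], 1)
            ax.plot(xx, np.polyval(coef, xx), lw=1.5)
        ax.axvline(self.breakpoint, color="r", ls="--", lw=1,
                   label=f"breakpoint {self.breakpoint:+.1f} dB")
        ax.invert_xaxis()  # descending SNR, clear -> noisy left to right
        ax.set_xlabel("SNR (dB)")
        ax.set_ylabel(self.metric or "metric")
        ax.legend()
        return ax

    def summary(self) -> str:
        t1, t2 = self.t_stats
        return "\n".join(
            [
                f"Broken-stick regression ({self.metric or 'metric'})",
                "=" * 44,
                f"breakpoint:   {self.breakpoint:+.2f} dB SNR "
                f"(group RMSE {self.rmse:.4g})",
                f"piece 1 (high SNR): slope {self.slopes_group[0]:+.4g}/dB, "
                f"t({t1.dof}) = {t1.t:.3f}, p = {t1.p:.3g}, d = {t1.d:.3f}",
                f"piece 2 (low SNR):  slope {self.slopes_group[1]:+.4g}/dB, "
                f"t({t2.dof}) = {t2.t:.3f}, p = {t2.p:.3g}, d = {t2.d:.3f}",
            ]
        )


class PiecewiseRegression:
    """Two-piece linear model of a condition profile with a free breakpoint.

    The breakpoint is chosen by grid search over interior grid values: at
    each candidate, independent least-squares lines are fitted on the
    across-participant mean over [x_max .. bp] and [bp .. x_min] (the
    breakpoint sample belongs to both pieces, matching how the piece ranges
    are reported), and the candidate minimizing the combined RMSE wins
    (ties: highest SNR). Per-participant slopes are then fitted on each
    piece's range and tested against zero.
    """

    def __init__(self, profile: SNRProfile, shared_breakpoint: bool = True):
        if profile.x.size < 5:
            raise ValueError("need at least 5 conditions for a broken stick")
        if profile.n_participants < 2:
            raise ValueError("need at least 2 participants")
        self.profile = profile
        self.shared_breakpoint = shared_breakpoint

    def fit(self) -> PiecewiseFit:
        x, y = self.profile.x, self.profile.y
        g = y.mean(axis=0)
        n = x.size
        best: tuple[float, int] | None = None
        off = 0 if self.shared_breakpoint else 1
        # scale-aware tolerance so numerically tied candidates resolve to
        # the first (highest-SNR) one deterministically
        tie_tol = 1e-9 * (float(np.abs(g).mean()) + 1e-30)
        for i in range(1, n - 1):
            hi = slice(0, i + 1)
            lo = slice(i + off, n)
            if hi.stop - hi.start < 2 or lo.stop - lo.start < 2:
                continue
            _, sse1 = _line_fit(x[hi], g[None, hi])
            _, sse2 = _line_fit(x[lo], g[None, lo])
            npts = (hi.stop - hi.start) + (lo.stop - lo.start)
            rmse = float(np.sqrt((sse1[0] + sse2[0]) / npts))
            if best is None or rmse < best[0] - tie_tol:
                best = (rmse, i)
        if best is None:
            raise ValueError("no valid breakpoint candidate (pieces too short)")
        rmse, i = best
        hi = slice(0, i + 1)
        lo = slice(i + off, n)
        s1_group, _ = _line_fit(x[hi], g[None, hi])
        s2_group, _ = _line_fit(x[lo], g[None, lo])
        s1, _ = _line_fit(x[hi], y[:, hi])
        s2, _ = _line_fit(x[lo], y[:, lo])
        return PiecewiseFit(
            breakpoint=float(x[i]),
            slopes_group=(float(s1_group[0]), float(s2_group[0])),
            slopes_per_participant=np.column_stack([s1, s2]),
            t_stats=(slope_ttest(s1), slope_ttest(s2)),
            rmse=rmse,
            metric=self.profile.metric,
        )


def piecewise_fit(profile: SNRProfile, shared_breakpoint: bool = True) -> PiecewiseFit:
    """Broken-stick fit of a profile; see :class:`PiecewiseRegression`."""
    return PiecewiseRegression(profile, shared_breakpoint=shared_breakpoint).fit()
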