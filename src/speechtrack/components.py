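"""TRF component quantification: P1, N1, P2 and their differences.

The analysis-lag TRF is baseline-corrected (mean over -0.15 to 0 s removed
per channel) and averaged over the fronto-central electrode cluster (F3,
Fz, F4, C3, Cz, C4). Component latencies are found on the across-
participant mean time course (P1 and P2 as window maxima, N1 as a window
minimum); per-participant amplitudes are means over a 0.02-s window
centered on each group latency. Analyses use the P1-minus-N1 and
P2-minus-N1 differences, which are invariant to additive offsets of the
TRF — raw component amplitudes are biased by the overall positive shift of
clear-speech TRFs.

Latency search windows default to canonical auditory-response morphology
(P1 0.02-0.09 s, N1 0.06-0.16 s, P2 0.14-0.30 s) and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FRONTO_CENTRAL
from .trf import TRFResults

__all__ = [
    "DEFAULT_SEARCH_WINDOWS",
    "BASELINE_WINDOW",
    "ComponentSummary",
    "baseline_and_cluster",
    "find_component_latencies",
    "component_amplitudes",
    "components_table",
]

DEFAULT_SEARCH_WINDOWS = {
    "P1": (0.02, 0.09),
    "N1": (0.06, 0.16),
    "P2": (0.14, 0.30),
}
BASELINE_WINDOW = (-0.15, 0.0)
AMPLITUDE_WINDOW = 0.02


@dataclass
class ComponentSummary:
    """Component latencies (s), windowed amplitudes (a.u.), and the
    offset-invariant P1-N1 / P2-N1 differences."""

    latencies: dict[str, float]
    amplitudes: dict[str, float]
    p1n1: float
    p2n1: float


def baseline_and_cluster(
    trf: TRFResults,
    cluster: tuple[str, ...] = FRONTO_CENTRAL,
    baseline: tuple[float, float] = BASELINE_WINDOW,
) -> np.ndarray:
    """Baseline-corrected cluster-mean TRF time course.

    Per channel the mean over the baseline lag window is subtracted, then
    the six cluster channels are averaged. Requires the analysis lag range
    (must cover the baseline window) and all cluster channels.
    """
    lags = trf.lags
    # the first grid lag may sit up to one sample inside the window start
    step = 1.0 / trf.rate
    if lags[0] > baseline[0] + step + 1e-9 or lags[-1] < baseline[1] - 1e-9:
        raise ValueError(
            f"lag range [{lags[0]:.3f}, {lags[-1]:.3f}] s does not cover the "
            f"baseline window {baseline}"
        )
    missing = [c for c in cluster if c not in trf.labels]
    if missing:
        raise ValueError(f"cluster channel(s) missing from TRF: {missing}")
    tc = trf.kernel
    in_base = (lags >= baseline[0] - 1e-12) & (lags <= baseline[1] + 1e-12)
    tc = tc - tc[:, in_base].mean(axis=1, keepdims=True)
    idx = [trf.labels.index(c) for c in cluster]
    return tc[idx].mean(axis=0)


def _window_extremum(
    tc: np.ndarray, lags: np.ndarray, window: tuple[float, float], mode: str,
    name: str,
) -> float:
    sel = np.flatnonzero((lags >= window[0] - 1e-12) & (lags <= window[1] + 1e-12))
    if sel.size == 0:
        raise ValueError(f"search window {window} outside the lag range")
    seg = tc[sel]
    j = int(np.argmax(seg) if mode == "max" else np.argmin(seg))
    if j in (0, seg.size - 1):
        warnings.warn(
            f"{name} extremum lies on its search-window edge "
            f"({window[0]:.3f}-{window[1]:.3f} s); the window may be "
            "mis-specified for this morphology",
            stacklevel=3,
        )
    return float(lags[sel[j]])


def find_component_latencies(
    group_mean_trf: np.ndarray,
    lags: np.ndarray,
    search_windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """P1/N1/P2 latencies from a group-mean cluster time course.

    P1 and P2 are window maxima, N1 a window minimum; the P1 < N1 < P2
    ordering is enforced. Latencies are estimated once per condition from
    the across-participant mean, never per participant.
    """
    windows = search_windows or DEFAULT_SEARCH_WINDOWS
    tc = np.asarray(group_mean_trf, float)
    lags = np.asarray(lags, float)
    step = float(np.mean(np.diff(lags)))
    # sequential search keeps P1 < N1 < P2 by construction: each window is
    # clipped to start strictly after the previous component
    p1 = _window_extremum(tc, lags, windows["P1"], "max", "P1")
    w_n1 = (max(windows["N1"][0], p1 + step / 2), windows["N1"][1])
    if w_n1[0] > w_n1[1]:
        raise ValueError("N1 window lies entirely before the P1 latency")
    n1 = _window_extremum(tc, lags, w_n1, "min", "N1")
    w_p2 = (max(windows["P2"][0], n1 + step / 2), windows["P2"][1])
    if w_p2[0] > w_p2[1]:
        raise ValueError("P2 window lies entirely before the N1 latency")
    p2 = _window_extremum(tc, lags, w_p2, "max", "P2")
    return {"P1": p1, "N1": n1, "P2": p2}


def component_amplitudes(
    participant_trf: np.ndarray,
    lags: np.ndarray,
    latencies: dict[str, float],
    window: float = AMPLITUDE_WINDOW,
) -> ComponentSummary:
    """Windowed component amplitudes for one participant's time course.

    Each amplitude is the mean over a ``window``-second window centered on
    the group latency; a window extending past the lag range is an error
    (never silently truncated).
    """
    tc = np.asarray(participant_trf, float)
    lags = np.asarray(lags, float)
    half = window / 2.0
    amps: dict[str, float] = {}
    for name, lat in latencies.items():
        lo, hi = lat - half, lat + half
        if lo < lags[0] - 1e-12 or hi > lags[-1] + 1e-12:
            raise ValueError(
                f"{name} amplitude window [{lo:.3f}, {hi:.3f}] s exceeds the "
                f"lag range [{lags[0]:.3f}, {lags[-1]:.3f}] s"
            )
        sel = (lags >= lo - 1e-12) & (lags <= hi + 1e-12)
        amps[name] = float(tc[sel].mean())
    return ComponentSummary(
        latencies=dict(latencies),
        amplitudes=amps,
        p1n1=amps["P1"] - amps["N1"],
        p2n1=amps["P2"] - amps["N1"],
    )


def components_table(
    summaries: dict[tuple[str, str], ComponentSummary]
) -> pd.DataFrame:
    """Tidy table of component measures.

    ``summaries`` maps (participant, condition) to a
    :class:`ComponentSummary`; the result has one row per pair with
    latencies and the P1-N1 / P2-N1 differences, ready for CSV export.
    """
    rows = []
    for (participant, condition), s in summaries.items():
        rows.append(
            {
                "participant": participant,
                "condition": condition,
                "p1_latency": s.latencies["P1"],
                "n1_latency": s.latencies["N1"],
                "p2_latency": s.latencies["P2"],
                "p1n1": s.p1n1,
                "p2n1": s.p2n1,
            }
        )
    return pd.DataFrame(rows)
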