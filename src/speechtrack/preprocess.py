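"""EEG conditioning chain for envelope-tracking analysis.

Takes raw multichannel recordings (16 scalp channels + 2 mastoids at
1024 Hz) to analysis-ready data: 60 Hz elliptic notch, linked-mastoid
re-referencing, 0.7 Hz high-pass (2449-tap Hann FIR) and 22 Hz low-pass
(211-tap Kaiser FIR), downsampling to 512 Hz, an optional pluggable
component-removal hook, zeroing of segments whose amplitude range exceeds
80 uV within 0.2 s in any channel, and a final 10 Hz low-pass (251-tap
Kaiser FIR). All FIR filters are odd-length linear-phase and applied with
exact group-delay compensation; the notch is applied forward-backward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = [
    "SCALP_LABELS",
    "MASTOID_LABELS",
    "FRONTO_CENTRAL",
    "EEGRecording",
    "ArtifactParams",
    "notch_60hz",
    "rereference_mastoids",
    "band_limit",
    "artifact_zero",
    "artifact_zero_bruteforce",
    "downsample_512",
    "lowpass_10hz",
    "downsample_and_smooth",
    "preprocess_chain",
]

#: 10-20 labels of the 16 scalp electrodes used throughout.
SCALP_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "C3", "Cz", "C4", "P7", "P3", "Pz", "P4", "P8", "Oz",
)
MASTOID_LABELS = ("M1", "M2")
#: Fronto-central cluster over which TRFs and accuracies are averaged.
FRONTO_CENTRAL = ("F3", "Fz", "F4", "C3", "Cz", "C4")


@dataclass
class EEGRecording:
    """Channels x samples EEG matrix in microvolts.

    ``reference`` is ``"raw"`` before and ``"linked_mastoids"`` after
    mastoid re-referencing; ``artifact_mask`` marks samples zeroed by the
    artifact rule.
    """

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    reference: str = "raw"
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.size != self.data.shape[1]:
                raise ValueError("artifact mask length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def _replace(self, **kw) -> "EEGRecording":
        out = dict(
            data=self.data,
            rate=self.rate,
            labels=self.labels,
            reference=self.reference,
            artifact_mask=self.artifact_mask.copy(),
        )
        out.update(kw)
        return EEGRecording(**out)


@dataclass
class ArtifactParams:
    """Threshold rule for artifact zeroing: any channel whose amplitude
    range exceeds ``range_threshold`` uV within a ``window``-second sliding
    window flags the whole window."""

    range_threshold: float = 80.0
    window: float = 0.2

    def __post_init__(self) -> None:
        if self.range_threshold <= 0 or self.window <= 0:
            raise ValueError("threshold and window must be positive")


def notch_60hz(rec: EEGRecording) -> EEGRecording:
    """Suppress the 60 Hz line frequency (elliptic band-stop, stopband
    59.5-60.5 Hz, >=80 dB suppression, zero-phase)."""
    if rec.rate <= 121:
        raise ValueError("sampling rate too low for a 60 Hz notch")
    n, wn = signal.ellipord(
        wp=[58.0, 62.0], ws=[59.5, 60.5], gpass=0.4, gstop=80.0, fs=rec.rate
    )
    sos = signal.ellip(n, 0.4, 80.0, wn, btype="bandstop", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec._replace(data=filtered)


def rereference_mastoids(
    rec: EEGRecording, mastoids: Sequence[str] = MASTOID_LABELS
) -> EEGRecording:
    """Subtract the mean of the two mastoids from every scalp channel.

    The mastoid channels are dropped from the output and the reference state
    set to ``"linked_mastoids"``; re-referencing twice is an error.
    """
    if rec.reference != "raw":
        raise ValueError("recording is already re-referenced")
    missing = [m for m in mastoids if m not in rec.labels]
    if missing:
        raise ValueError(f"mastoid channel(s) missing: {missing}")
    m_mean = np.mean([rec.channel(m) for m in mastoids], axis=0)
    keep = [i for i, lab in enumerate(rec.labels) if lab not in mastoids]
    data = rec.data[keep] - m_mean
    labels = tuple(rec.labels[i] for i in keep)
    return EEGRecording(
        data, rec.rate, labels, reference="linked_mastoids",
        artifact_mask=rec.artifact_mask.copy(),
    )


def _fir_same(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # odd-length linear-phase FIR; mode="same" centers the output, which is
    # exact group-delay compensation
    return signal.fftconvolve(data, taps[None, :], mode="same", axes=1)


# Kaiser beta for >= 60 dB sidelobe attenuation at the stated tap counts
_KAISER_BETA = signal.kaiser_beta(60.0)


def band_limit(
    rec: EEGRecording, hp_hz: float = 0.7, lp_hz: float = 22.0
) -> EEGRecording:
    """0.7 Hz high-pass (2449-tap Hann FIR) then 22 Hz low-pass (211-tap
    Kaiser FIR). Tap counts are defined at 1024 Hz and rescaled
    proportionally (with a warning) at other rates."""
    n_hp, n_lp = 2449, 211
    if rec.rate != 1024:
        scale = rec.rate / 1024.0
        n_hp = int(round(n_hp * scale)) | 1
        n_lp = int(round(n_lp * scale)) | 1
        warnings.warn(
            f"band_limit tap counts rescaled for rate {rec.rate} Hz "
            f"(HP {n_hp}, LP {n_lp})",
            stacklevel=2,
        )
    hp = signal.firwin(n_hp, hp_hz, window="hann", pass_zero=False, fs=rec.rate)
    lp = signal.firwin(n_lp, lp_hz, window=("kaiser", _KAISER_BETA), fs=rec.rate)
    data = _fir_same(_fir_same(rec.data, hp), lp)
    return rec._replace(data=data)


def _window_flags(data: np.ndarray, w: int, threshold: float) -> np.ndarray:
    """Boolean flag per window start: True where max-min > threshold in any
    channel over data[:, s:s+w]."""
    n = data.shape[1]
    n_starts = n - w + 1
    # maximum_filter1d: output[i] = max over x[i - w//2 : i - w//2 + w],
    # so the window starting at s sits at index s + w//2
    hi = maximum_filter1d(data, size=w, axis=1, mode="nearest")
    lo = minimum_filter1d(data, size=w, axis=1, mode="nearest")
    rng = (hi - lo)[:, w // 2 : w // 2 + n_starts]
    return np.any(rng > threshold, axis=0)


def artifact_zero(
    rec: EEGRecording, params: ArtifactParams | None = None
) -> EEGRecording:
    """Zero every sliding window whose amplitude range exceeds the threshold
    (strict >) in any channel; flagged windows are unioned and zeroed in all
    channels, and the artifact mask marks the zeroed samples."""
    params = params or ArtifactParams()
    w = int(round(params.window * rec.rate))
    if w < 2:
        raise ValueError("window too short: need window*rate >= 2 samples")
    n = rec.n_samples
    if w > n:
        return rec._replace()
    flags = _window_flags(rec.data, w, params.range_threshold)
    # union of flagged windows via a difference array over coverage counts
    cover = np.zeros(n + 1, dtype=np.int64)
    starts = np.flatnonzero(flags)
    np.add.at(cover, starts, 1)
    np.add.at(cover, starts + w, -1)
    mask = np.cumsum(cover[:-1]) > 0
    data = rec.data.copy()
    data[:, mask] = 0.0
    return rec._replace(data=data, artifact_mask=rec.artifact_mask | mask)


def artifact_zero_bruteforce(
    rec: EEGRecording, params: ArtifactParams | None = None
) -> EEGRecording:
    """O(n*w) reference implementation of :func:`artifact_zero` that
    enumerates every sliding window explicitly. Used for verification."""
    params = params or ArtifactParams()
    w = int(round(params.window * rec.rate))
    if w < 2:
        raise ValueError("window too short: need window*rate >= 2 samples")
    n = rec.n_samples
    mask = np.zeros(n, dtype=bool)
    for s in range(n - w + 1):
        seg = rec.data[:, s : s + w]
        if np.any(seg.max(axis=1) - seg.min(axis=1) > params.range_threshold):
            mask[s : s + w] = True
    data = rec.data.copy()
    data[:, mask] = 0.0
    return rec._replace(data=data, artifact_mask=rec.artifact_mask | mask)


def downsample_512(rec: EEGRecording, target_rate: float = 512.0) -> EEGRecording:
    """Polyphase anti-aliased downsampling to the analysis rate."""
    if rec.rate == target_rate:
        return rec._replace()
    from fractions import Fraction

    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_out = data.shape[1]
    idx = np.minimum(
        (np.arange(n_out) * frac.denominator / frac.numerator).astype(int),
        rec.n_samples - 1,
    )
    return EEGRecording(
        data, target_rate, rec.labels, rec.reference,
        artifact_mask=rec.artifact_mask[idx],
    )


def lowpass_10hz(rec: EEGRecording, cutoff_hz: float = 10.0) -> EEGRecording:
    """Final 10 Hz low-pass (251-tap Kaiser FIR at 512 Hz), delay-compensated."""
    n_taps = 251
    if rec.rate != 512:
        n_taps = int(round(n_taps * rec.rate / 512.0)) | 1
    lp = signal.firwin(n_taps, cutoff_hz, window=("kaiser", _KAISER_BETA), fs=rec.rate)
    return rec._replace(data=_fir_same(rec.data, lp))


def downsample_and_smooth(rec: EEGRecording) -> EEGRecording:
    """Downsample to 512 Hz and apply the 10 Hz low-pass in one step."""
    return lowpass_10hz(downsample_512(rec))


def preprocess_chain(
    rec: EEGRecording,
    artifact_params: ArtifactParams | None = None,
    ica_hook: Callable[[EEGRecording], EEGRecording] | None = None,
) -> EEGRecording:
    """Full conditioning chain in its fixed order.

    notch -> mastoid re-reference -> band-limit -> downsample to 512 Hz ->
    component-removal hook (identity by default) -> artifact zeroing ->
    10 Hz low-pass. Story segmentation happens upstream of this call; each
    epoch is conditioned independently.
    """
    out = notch_60hz(rec)
    out = rereference_mastoids(out)
    out = band_limit(out)
    out = downsample_512(out)
    if ica_hook is not None:
        out = ica_hook(out)
    out = artifact_zero(out, artifact_params)
    return lowpass_10hz(out)
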