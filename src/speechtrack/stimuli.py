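"""Speech-plus-masker stimulus construction.

Builds the acoustic conditions of a speech-in-noise tracking experiment:
mixing a speech story with a masker at a prescribed signal-to-noise ratio
(SNR), the two RMS-normalization schemes used to equate presentation level,
and the stationary maskers themselves (12-talker babble, speech-matched
noise, white and pink noise).

SNR is defined on broadband RMS over the full story duration: mixing at
``snr_db`` scales the masker so that

    20 * log10(rms(speech) / rms(scaled_masker)) = snr_db

The two normalization schemes differ in what is held constant across SNR
conditions: ``mixture_rms`` rescales the finished mixture to a reference RMS
(so the speech level inside the mixture falls as SNR falls), while
``speech_rms`` leaves the mixture alone (speech fixed upstream, so mixture
level rises as SNR falls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = [
    "REFERENCE_RMS",
    "MixtureSpec",
    "ConditionGrid",
    "mix_at_snr",
    "normalize_mixture",
    "spectrally_matched_noise",
    "synth_noise",
    "make_babble",
]

#: Package-level reference RMS all stimuli are finally scaled to; a stand-in
#: for a fixed presentation level (absolute SPL is out of scope).
REFERENCE_RMS = 0.05


@dataclass
class MixtureSpec:
    """How a speech+masker mixture is levelled.

    normalization ``"mixture_rms"``: the mixture is rescaled to
    ``target_rms`` (speech level in the mixture decreases as SNR decreases).
    ``"speech_rms"``: the mixture is left unchanged; the speech was fixed at
    ``target_rms`` upstream (mixture RMS grows as SNR decreases).
    """

    snr_db: float
    normalization: str = "mixture_rms"
    target_rms: float = REFERENCE_RMS

    def __post_init__(self) -> None:
        if self.normalization not in ("mixture_rms", "speech_rms"):
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                "expected 'mixture_rms' or 'speech_rms'"
            )
        if not self.target_rms > 0:
            raise ValueError("target_rms must be positive")


@dataclass
class ConditionGrid:
    """Ordered (descending) grid of SNR conditions, optionally with a
    no-masker 'clear' condition."""

    snr_levels_db: np.ndarray
    includes_clear: bool = True

    def __post_init__(self) -> None:
        self.snr_levels_db = np.asarray(self.snr_levels_db, dtype=float)
        if self.snr_levels_db.ndim != 1 or self.snr_levels_db.size < 1:
            raise ValueError("snr_levels_db must be a non-empty 1-D array")
        if np.any(np.diff(self.snr_levels_db) >= 0):
            raise ValueError("SNR levels must be strictly decreasing")

    @classmethod
    def from_range(
        cls,
        start_db: float = 30.0,
        step_db: float = 1.6,
        n_levels: int = 21,
        includes_clear: bool = True,
    ) -> "ConditionGrid":
        """Equally spaced grid from ``start_db`` downwards in steps of
        ``step_db`` (default: +30 to -2 dB in 21 steps of 1.6 dB)."""
        levels = start_db - step_db * np.arange(n_levels)
        return cls(levels, includes_clear=includes_clear)

    @property
    def n_levels(self) -> int:
        return self.snr_levels_db.size


def _check_rms(wave: Waveform, name: str) -> float:
    r = wave.rms()
    if r == 0.0:
        raise ValueError(f"{name} has zero RMS; cannot set an SNR")
    return r


def mix_at_snr(
    speech: Waveform,
    masker: Waveform,
    snr_db: float,
    seed: int = 0,
) -> Waveform:
    """Add a masker to speech at a broadband RMS SNR (dB).

    The masker is scaled so that ``20*log10(rms(speech)/rms(scaled)) ==
    snr_db`` and added sample-wise. A masker longer than the speech is
    cropped from a seeded random start offset (avoids audible loop seams and
    is reproducible); a shorter masker is an error.
    """
    if speech.rate != masker.rate:
        raise ValueError(
            f"rate mismatch: speech {speech.rate} Hz vs masker {masker.rate} Hz"
        )
    if masker.n_samples < speech.n_samples:
        raise ValueError("masker must be at least as long as the speech")
    s_rms = _check_rms(speech, "speech")

    n = speech.n_samples
    if masker.n_samples > n:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, masker.n_samples - n + 1))
        masker_seg = masker.samples[start : start + n]
    else:
        masker_seg = masker.samples
    m_rms = float(np.sqrt(np.mean(masker_seg**2)))
    if m_rms == 0.0:
        raise ValueError("masker has zero RMS; cannot set an SNR")

    scale = s_rms / (m_rms * 10.0 ** (snr_db / 20.0))
    return Waveform(speech.samples + scale * masker_seg, speech.rate)


def normalize_mixture(
    mix: Waveform, spec: MixtureSpec, speech_rms: float | None = None
) -> Waveform:
    """Apply one of the two level-normalization schemes to a mixture.

    ``mixture_rms`` rescales the whole mixture to ``spec.target_rms``;
    ``speech_rms`` returns the mixture unchanged (the speech was levelled
    before mixing). ``speech_rms`` is accepted for interface symmetry and
    unused in the identity branch.
    """
    if spec.normalization == "speech_rms":
        return mix.copy()
    r = mix.rms()
    if r == 0.0:
        raise ValueError("zero-RMS mixture cannot be normalized to a target RMS")
    return Waveform(mix.samples * (spec.target_rms / r), mix.rate)


def spectrally_matched_noise(speech: Waveform, seed: int) -> Waveform:
    """Stationary noise with the long-term magnitude spectrum of the speech.

    The FFT magnitude of the speech is kept bin-wise and the phases are
    redrawn uniformly on (-pi, pi]; conjugate symmetry is enforced by
    synthesizing on the one-sided (rfft) spectrum with the DC and Nyquist
    bins kept real, so the output is exactly real-valued and has the same
    length and rate as the input.
    """
    if speech.n_samples < 2:
        raise ValueError("speech must have at least 2 samples")
    n = speech.n_samples
    mag = np.abs(np.fft.rfft(speech.samples))
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, size=mag.size)
    phases[0] = 0.0
    if n % 2 == 0:  # real Nyquist bin
        phases[-1] = 0.0
    spectrum = mag * np.exp(1j * phases)
    noise = np.fft.irfft(spectrum, n=n)
    return Waveform(noise, speech.rate)


def synth_noise(kind: str, n: int, rate: float, seed: int) -> Waveform:
    """Synthesize zero-mean white or pink noise of unit RMS.

    Pink noise (power spectral density proportional to 1/f) is built in the
    frequency domain with amplitude 1/sqrt(f) and seeded random phases, which
    gives the exact -1 log-log PSD slope in expectation.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    if kind == "white":
        x = rng.standard_normal(n)
    elif kind == "pink":
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        amp = np.zeros_like(freqs)
        amp[1:] = 1.0 / np.sqrt(freqs[1:])
        phases = rng.uniform(-np.pi, np.pi, size=freqs.size)
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = 0.0
        x = np.fft.irfft(amp * np.exp(1j * phases), n=n)
    else:
        raise ValueError(f"unknown noise kind {kind!r}; expected 'white' or 'pink'")
    x = x - x.mean()
    x /= np.sqrt(np.mean(x**2))
    return Waveform(x, rate)


def make_babble(
    talkers: list[Waveform],
    n_required: int = 12,
    seed: int = 0,
    n_samples: int | None = None,
) -> Waveform:
    """Multi-talker babble: RMS-equalize and sum concurrent speech streams.

    Streams are each scaled to unit RMS, summed sample-wise, and the sum is
    RMS-normalized to 1. With twelve independent streams the pre-
    normalization RMS is ~sqrt(12). Streams longer than the requested output
    are cropped from a seeded random offset.
    """
    if len(talkers) < n_required:
        raise ValueError(
            f"need at least {n_required} talker streams, got {len(talkers)}"
        )
    rates = {t.rate for t in talkers}
    if len(rates) > 1:
        raise ValueError("all talker streams must share one sampling rate")
    rate = rates.pop()
    streams = talkers[:n_required]
    if n_samples is None:
        n_samples = min(t.n_samples for t in streams)
    rng = np.random.default_rng(seed)
    total = np.zeros(n_samples)
    for t in streams:
        if t.n_samples < n_samples:
            raise ValueError("every talker stream must cover the requested output")
        start = 0
        if t.n_samples > n_samples:
            start = int(rng.integers(0, t.n_samples - n_samples + 1))
        seg = t.samples[start : start + n_samples]
        total += seg / _check_rms(Waveform(seg, rate), "talker stream")
    total /= np.sqrt(np.mean(total**2))
    return Waveform(total, rate)
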