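"""Mono audio container used by all acoustic processing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Waveform"]


@dataclass
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued amplitude sequence (arbitrary units).
    rate : float
        Sampling rate in Hz. Must be positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires a 1-D (mono) sample array")
        if self.samples.size < 1:
            raise ValueError("Waveform requires at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.rate)
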