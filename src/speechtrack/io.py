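"""File formats: WAV audio, HDF5 containers, optional EDF/BDF reading.

WAV covers RIFF PCM (16/24/32-bit) and IEEE float, mono only; integer PCM
is scaled to [-1, 1) on read. The package-internal container is HDF5:
envelopes as dataset ``values`` with attrs ``rate``/``kind``, EEG as
datasets ``data``/``labels``/``artifact_mask`` with attrs
``rate``/``reference``, TRFs as ``weights``/``lags`` plus fit metadata.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .envelope import EnvelopeSeries
from .preprocess import EEGRecording
from .trf import TRFResults
from .waveform import Waveform

__all__ = [
    "read_wav",
    "write_wav",
    "read_envelope",
    "write_envelope",
    "read_eeg",
    "write_eeg",
    "read_trf",
    "write_trf",
    "read_edf",
]

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31,
              np.dtype("uint8"): 2**7}


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file; integer PCM is scaled to [-1, 1)."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: multichannel audio not supported (mono required)")
    if data.dtype in _PCM_SCALE:
        if data.dtype == np.dtype("uint8"):
            data = (data.astype(float) - 128.0) / 128.0
        else:
            data = data.astype(float) / _PCM_SCALE[data.dtype]
    else:
        data = data.astype(float)
    return Waveform(data, float(rate))


def write_wav(path: str | Path, wave: Waveform, dtype: str = "float32") -> None:
    """Write a mono WAV file (IEEE float by default, or 16-bit PCM)."""
    if dtype == "float32":
        wavfile.write(str(path), int(wave.rate), wave.samples.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(wave.samples, -1.0, 1.0 - 2.0**-15)
        wavfile.write(
            str(path), int(wave.rate), np.round(clipped * 2**15).astype(np.int16)
        )
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")


def write_envelope(path: str | Path, env: EnvelopeSeries) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=env.values)
        d.attrs["rate"] = env.rate
        d.attrs["kind"] = env.kind


def read_envelope(path: str | Path) -> EnvelopeSeries:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return EnvelopeSeries(d[()], float(d.attrs["rate"]), str(d.attrs["kind"]))


def write_eeg(path: str | Path, rec: EEGRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset(
            "labels", data=np.array(rec.labels, dtype=h5py.string_dtype())
        )
        f.create_dataset("artifact_mask", data=rec.artifact_mask)
        f.attrs["rate"] = rec.rate
        f.attrs["reference"] = rec.reference


def read_eeg(path: str | Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = tuple(s.decode() for s in f["labels"][()])
        mask = f["artifact_mask"][()]
        if mask.size != data.shape[1]:
            raise ValueError(f"{path}: artifact mask does not match sample count")
        return EEGRecording(
            data, float(f.attrs["rate"]), labels,
            reference=str(f.attrs["reference"]), artifact_mask=mask,
        )


def write_trf(path: str | Path, trf: TRFResults) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=trf.weights)
        f.create_dataset("lags", data=trf.lags)
        f.create_dataset("col_means", data=trf.col_means)
        f.create_dataset("col_scales", data=trf.col_scales)
        f.create_dataset("y_means", data=trf.y_means)
        f.create_dataset(
            "labels", data=np.array(trf.labels, dtype=h5py.string_dtype())
        )
        f.attrs["lambda"] = trf.lam
        f.attrs["rate"] = trf.rate
        f.attrs["normalization"] = trf.normalization


def read_trf(path: str | Path) -> TRFResults:
    with h5py.File(path, "r") as f:
        return TRFResults(
            weights=f["weights"][()],
            lags=f["lags"][()],
            lam=float(f.attrs["lambda"]),
            col_means=f["col_means"][()],
            col_scales=f["col_scales"][()],
            y_means=f["y_means"][()],
            labels=tuple(s.decode() for s in f["labels"][()]),
            rate=float(f.attrs["rate"]),
            normalization=str(f.attrs["normalization"]),
        )


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/BDF recording via MNE (optional dependency) into the
    package container, data in microvolts, reference state ``raw``."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF/BDF requires the 'mne' package") from err
    path = str(path)
    reader = mne.io.read_raw_bdf if path.lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))
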