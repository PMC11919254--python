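"""Synthetic experiments with known ground truth.

Every pipeline stage can be verified without human EEG by generating the
data from a known forward model:

* speech-like onset envelopes — Poisson syllable-rate onset events
  convolved with a positive onset pulse;
* linear-mode EEG — a known TRF kernel convolved with the envelope, scaled
  by a fronto-centrally peaked channel topography, plus 1/f sensor noise at
  a stated response SNR;
* stochastic-resonance (SR) mode — a population of threshold (rectified-
  linear) units driven by the speech envelope plus an acoustic-masker
  envelope and independent internal noise. When the speech drive alone is
  subthreshold, a moderate masker drive pushes the population through its
  threshold and the envelope-locked output grows; too much masker drive
  floods the output with masker fluctuations. The encoder demonstrates the
  proposed mechanism; its parameters are package choices, not fitted
  values.

All generators are seeded and a dataset is reproducible bit-for-bit from
its manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import signal

from .envelope import EnvelopeSeries
from .preprocess import SCALP_LABELS, EEGRecording
from .stimuli import ConditionGrid
from .waveform import Waveform

__all__ = [
    "KernelSpec",
    "SREncoderParams",
    "speechlike_onset_events",
    "gen_speechlike_envelope",
    "gen_linear_eeg",
    "sr_population_response",
    "envelope_locked_power",
    "sr_masker_sweep",
    "gen_sr_eeg",
    "masker_envelope_from_noise",
    "masker_envelope_from_waveform",
    "inject_artifacts",
    "gen_experiment",
    "ExperimentDataset",
]

#: Relative channel gains: evoked activity peaks over the fronto-central
#: cluster, as expected for auditory-cortex sources under a linked-mastoid
#: reference.
CHANNEL_TOPOGRAPHY = {
    "Fp1": 0.6, "Fp2": 0.6, "F7": 0.55, "F3": 1.0, "Fz": 1.0, "F4": 1.0,
    "F8": 0.55, "C3": 1.0, "Cz": 1.0, "C4": 1.0, "P7": 0.45, "P3": 0.5,
    "Pz": 0.55, "P4": 0.5, "P8": 0.45, "Oz": 0.3,
}


@dataclass
class KernelSpec:
    """Ground-truth TRF kernel: a sum of Gaussian deflections.

    Default deflections mimic the P1 (+, 0.06 s), N1 (-, 0.11 s) and P2
    (+, 0.20 s) morphology of auditory TRFs.
    """

    deflections: tuple[tuple[float, float, float], ...] = (
        (0.06, 1.0, 0.02),
        (0.11, -1.3, 0.03),
        (0.20, 0.8, 0.05),
    )
    rate: float = 512.0

    def __post_init__(self) -> None:
        lats = [d[0] for d in self.deflections]
        if any(np.diff(lats) <= 0):
            raise ValueError("deflection latencies must increase")
        if any(d[2] <= 0 for d in self.deflections):
            raise ValueError("deflection widths must be positive")

    def sample(self, lag_min: float = -0.15, lag_max: float = 0.5) -> tuple[
        np.ndarray, np.ndarray
    ]:
        """Kernel values on the integer lag grid; returns (lags_s, values)."""
        from .trf import lag_shifts

        ks = lag_shifts(lag_min, lag_max, self.rate)
        lags = ks / self.rate
        vals = np.zeros_like(lags)
        for lat, amp, width in self.deflections:
            vals += amp * np.exp(-0.5 * ((lags - lat) / width) ** 2)
        return lags, vals


@dataclass
class SREncoderParams:
    """Threshold-population encoder parameters (drive units).

    Defaults put the speech drive *below* threshold for an envelope
    normalized to unit maximum (gain * max(env) = 0.6 < threshold = 1), the
    regime in which added masker drive can enhance envelope-locked output.
    """

    n_units: int = 100
    threshold: float = 1.0
    internal_noise_sd: float = 0.05
    gain: float = 0.6
    masker_gain: float = 0.0
    seed: int = 0
    heaviside: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("need at least one unit")
        if self.internal_noise_sd < 0:
            raise ValueError("internal noise SD must be non-negative")


def speechlike_onset_events(
    duration: float, syllable_rate: float = 4.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson onset events underlying a speech-like envelope.

    Returns event times (s, uniform over the story) and gamma-distributed
    event strengths (mean 1); the event count is Poisson with mean
    ``duration * syllable_rate``.
    """
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(duration * syllable_rate)
    times = rng.uniform(0, duration, size=n_events)
    amps = rng.gamma(shape=2.0, scale=0.5, size=n_events)
    return times, amps


def gen_speechlike_envelope(
    duration: float,
    rate: float = 512.0,
    syllable_rate: float = 4.0,
    seed: int = 0,
) -> EnvelopeSeries:
    """Speech-like onset envelope: Poisson onset events at the syllabic
    rate, with gamma-distributed strengths, convolved with a positive
    alpha-function onset pulse (~20 ms rise). Normalized to unit maximum.

    Durations below 25 s are rejected because the snippet cross-validation
    scheme holds out 25-s snippets.
    """
    if duration < 25.0:
        raise ValueError(
            "duration must be >= 25 s so that 25-s snippets can be extracted"
        )
    if not (1.0 < syllable_rate < 10.0):
        raise ValueError("syllable_rate must lie in (1, 10) Hz")
    n = int(round(duration * rate))
    times, amps = speechlike_onset_events(duration, syllable_rate, seed)
    train = np.zeros(n)
    idx = np.minimum((times * rate).astype(int), n - 1)
    np.add.at(train, idx, amps)
    tau = 0.02
    t = np.arange(0, 0.15, 1.0 / rate)
    pulse = (t / tau) * np.exp(1.0 - t / tau)
    env = signal.fftconvolve(train, pulse)[:n]
    env = np.maximum(env, 0.0)
    peak = env.max()
    if peak > 0:
        env /= peak
    return EnvelopeSeries(env, rate, kind="onset")


def _convolve_kernel(env: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """EEG-style response: sum_j kernel(lag_j) * env(t - lag_j), honoring
    negative lags."""
    from .trf import lag_shifts

    ks = lag_shifts(-0.15, 0.5, kernel.rate)
    _, kern = kernel.sample(-0.15, 0.5)
    full = signal.fftconvolve(env, kern)  # full[i] = sum_j kern[j] env[i-j]
    n = env.size
    out = np.zeros(n)
    t = np.arange(n)
    src = t - ks[0]
    ok = (src >= 0) & (src < full.size)
    out[t[ok]] = full[src[ok]]
    return out


def _pink_noise_matrix(
    n_channels: int, n: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        phases = rng.uniform(-np.pi, np.pi, size=freqs.size)
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = 0.0
        x = np.fft.irfft(amp * np.exp(1j * phases), n=n)
        x -= x.mean()
        out[c] = x / np.sqrt(np.mean(x**2))
    return out


def gen_linear_eeg(
    env: EnvelopeSeries,
    kernel: KernelSpec | None = None,
    response_snr_db: float = -10.0,
    n_channels: int = 16,
    seed: int = 0,
) -> tuple[EEGRecording, dict]:
    """Linear forward-model EEG: kernel-convolved envelope scaled by the
    channel topography plus 1/f sensor noise.

    ``response_snr_db`` is 10*log10(signal power / noise power) for a
    unit-topography channel; ``np.inf`` disables the noise. Returns the
    recording and a ground-truth dict (kernel lags/values, noise scale).
    """
    kernel = kernel or KernelSpec(rate=env.rate)
    if kernel.rate != env.rate:
        raise ValueError("kernel rate must match the envelope rate")
    labels = SCALP_LABELS[:n_channels]
    weights = np.array([CHANNEL_TOPOGRAPHY[lab] for lab in labels])
    evoked = _convolve_kernel(env.values, kernel)
    sig_rms = float(np.sqrt(np.mean(evoked**2)))
    rng = np.random.default_rng(seed)
    data = weights[:, None] * evoked[None, :]
    noise_sd = 0.0
    if np.isfinite(response_snr_db):
        # a silent kernel still gets sensor noise (unit RMS reference)
        noise_sd = (sig_rms or 1.0) * 10.0 ** (-response_snr_db / 20.0)
        data = data + noise_sd * _pink_noise_matrix(
            len(labels), env.n_samples, env.rate, rng
        )
    rec = EEGRecording(data, env.rate, labels, reference="linked_mastoids")
    lags, kern = kernel.sample(-0.15, 0.5)
    truth = {
        "kernel_lags": lags,
        "kernel": kern,
        "channel_weights": weights,
        "noise_sd": noise_sd,
    }
    return rec, truth


def sr_population_response(
    clear_env: EnvelopeSeries,
    masker_env: EnvelopeSeries | None,
    params: SREncoderParams,
    seed: int | None = None,
) -> np.ndarray:
    """Mean output of the threshold population.

    Each unit i receives drive ``gain*clear + masker_gain*masker + noise_i``
    with i.i.d. Gaussian internal noise and emits
    ``max(drive - threshold, 0)`` (or a 0/1 Heaviside output if configured);
    the population mean over units is returned.
    """
    if masker_env is not None:
        if masker_env.rate != clear_env.rate:
            raise ValueError("clear and masker envelopes must share one rate")
        if masker_env.n_samples != clear_env.n_samples:
            raise ValueError("clear and masker envelopes must be aligned")
    drive = params.gain * clear_env.values
    if masker_env is not None and params.masker_gain != 0.0:
        drive = drive + params.masker_gain * masker_env.values
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = drive.size
    if params.internal_noise_sd == 0.0:
        d = drive - params.threshold
        return (d > 0).astype(float) if params.heaviside else np.maximum(d, 0.0)
    acc = np.zeros(n)
    # accumulate units in blocks to bound memory
    block = max(1, min(params.n_units, int(2e7 // max(n, 1)) or 1))
    done = 0
    while done < params.n_units:
        b = min(block, params.n_units - done)
        d = drive[None, :] + params.internal_noise_sd * rng.standard_normal((b, n))
        d -= params.threshold
        out = (d > 0).astype(float) if params.heaviside else np.maximum(d, 0.0)
        acc += out.sum(axis=0)
        done += b
    return acc / params.n_units


def envelope_locked_power(pop: np.ndarray, env: EnvelopeSeries) -> float:
    """Fraction of output power locked to the envelope: the squared Pearson
    correlation between the population output and the clear envelope.
    Returns 0 for a constant (e.g. fully subthreshold, silent) output."""
    pop = np.asarray(pop, float)
    x = env.values - env.values.mean()
    y = pop - pop.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float(((x * y).sum() / denom) ** 2)


def sr_masker_sweep(
    clear_env: EnvelopeSeries,
    masker_env: EnvelopeSeries,
    params: SREncoderParams,
    masker_gains: np.ndarray,
    n_seeds: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Envelope-locked power across a masker-drive sweep.

    Returns an (n_seeds, n_gains) array; each seed redraws the internal
    noise of the population. The canonical stochastic-resonance signature
    is an interior maximum over the sweep when the speech drive is
    subthreshold, and a maximum at zero masker when it is suprathreshold.
    """
    from dataclasses import replace

    masker_gains = np.asarray(masker_gains, float)
    ss = np.random.SeedSequence(seed)
    out = np.empty((n_seeds, masker_gains.size))
    for i, child in enumerate(ss.spawn(n_seeds)):
        unit_seed = int(child.generate_state(1)[0] % (2**31))
        for j, mg in enumerate(masker_gains):
            p = replace(params, masker_gain=float(mg))
            pop = sr_population_response(clear_env, masker_env, p, seed=unit_seed)
            out[i, j] = envelope_locked_power(pop, clear_env)
    return out


def gen_sr_eeg(
    clear_env: EnvelopeSeries,
    masker_env: EnvelopeSeries | None,
    params: SREncoderParams,
    kernel: KernelSpec | None = None,
    sensor_noise_snr_db: float = 10.0,
    seed: int = 0,
) -> tuple[EEGRecording, dict]:
    """EEG from the SR encoder: the population mean is convolved with the
    TRF kernel, scaled by the channel topography, and 1/f sensor noise is
    added.

    The sensor-noise level is anchored to the power of the *fully
    suprathreshold* reference response (kernel convolved with gain*env), so
    it is constant across masker conditions of one experiment rather than
    tracking the condition-dependent evoked power.
    """
    kernel = kernel or KernelSpec(rate=clear_env.rate)
    rng = np.random.default_rng(seed)
    unit_seed = int(rng.integers(2**31))
    pop = sr_population_response(clear_env, masker_env, params, seed=unit_seed)
    evoked = _convolve_kernel(pop, kernel)
    labels = SCALP_LABELS
    weights = np.array([CHANNEL_TOPOGRAPHY[lab] for lab in labels])
    data = weights[:, None] * evoked[None, :]
    ref = _convolve_kernel(params.gain * clear_env.values, kernel)
    ref_rms = float(np.sqrt(np.mean(ref**2)))
    noise_sd = 0.0
    if np.isfinite(sensor_noise_snr_db) and ref_rms > 0:
        noise_sd = ref_rms * 10.0 ** (-sensor_noise_snr_db / 20.0)
        data = data + noise_sd * _pink_noise_matrix(
            len(labels), clear_env.n_samples, clear_env.rate, rng
        )
    rec = EEGRecording(data, clear_env.rate, labels, reference="linked_mastoids")
    lags, kern = kernel.sample(-0.15, 0.5)
    truth = {
        "kernel_lags": lags,
        "kernel": kern,
        "population": pop,
        "noise_sd": noise_sd,
    }
    return rec, truth


def masker_envelope_from_noise(
    duration: float,
    rate: float = 512.0,
    kind: str = "pink",
    seed: int = 0,
) -> EnvelopeSeries:
    """Fast masker envelope: Hilbert magnitude of synthesized noise,
    40 Hz low-passed and normalized to unit mean.

    A stationary-noise envelope (Rayleigh-like fluctuations around a steady
    mean), appropriate for the SR encoder's masker drive without running the
    full cochleogram chain.
    """
    from .stimuli import synth_noise

    audio_rate = 4 * rate
    n = int(round(duration * audio_rate))
    noise = synth_noise(kind, n, audio_rate, seed)
    env = np.abs(signal.hilbert(noise.samples))
    sos = signal.butter(4, 40.0, btype="low", fs=audio_rate, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = np.maximum(signal.resample_poly(env, 1, 4), 0.0)
    env = env[: int(round(duration * rate))]
    m = env.mean()
    if m > 0:
        env /= m
    return EnvelopeSeries(env, rate, kind="amplitude")


def masker_envelope_from_waveform(
    masker: Waveform, eeg_rate: float = 512.0, params=None
) -> EnvelopeSeries:
    """Masker envelope through the full auditory-periphery chain
    (cochleogram + compression + 40 Hz low-pass), normalized to unit mean.
    Lets babble and speech-matched noise differ in envelope statistics."""
    from .envelope import amplitude_envelope

    env = amplitude_envelope(masker, params, eeg_rate)
    m = env.values.mean()
    vals = env.values / m if m > 0 else env.values
    return EnvelopeSeries(vals, eeg_rate, kind="amplitude")


def inject_artifacts(
    rec: EEGRecording,
    n_events: int = 3,
    amplitude: float = 100.0,
    duration: float = 0.1,
    seed: int = 0,
) -> EEGRecording:
    """Add rectangular voltage excursions (default 100 uV, 0.1 s) at seeded
    random positions, for exercising the artifact-zeroing stage."""
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    w = int(round(duration * rec.rate))
    for _ in range(n_events):
        ch = int(rng.integers(rec.n_channels))
        s = int(rng.integers(0, max(rec.n_samples - w, 1)))
        data[ch, s : s + w] += amplitude
    return EEGRecording(
        data, rec.rate, rec.labels, rec.reference, rec.artifact_mask.copy()
    )


def _mixture_gains(snr_db: float) -> tuple[float, float]:
    """Speech and masker amplitude scales under mixture-RMS normalization.

    With unit-RMS speech and masker, mixing at ``snr_db`` and renormalizing
    the mixture RMS gives speech scale 1/sqrt(1 + 10^(-snr/10)) and masker
    scale speech_scale * 10^(-snr/20): the speech level falls and the
    masker drive rises as SNR falls.
    """
    a = 1.0 / np.sqrt(1.0 + 10.0 ** (-snr_db / 10.0))
    return float(a), float(a * 10.0 ** (-snr_db / 20.0))


@dataclass
class ExperimentDataset:
    """A complete synthetic experiment.

    ``recordings`` and ``envelopes`` are keyed by (participant, condition);
    the regressor stored per recording is always the *clear-speech* onset
    envelope, also for masked conditions. ``manifest`` (seeds + parameters)
    suffices to regenerate the dataset bit-identically.
    """

    conditions: tuple[str, ...]
    recordings: dict
    envelopes: dict
    manifest: dict
    truth: dict

    @property
    def n_participants(self) -> int:
        return self.manifest["n_participants"]


#: Drive units of masker envelope per unit of (normalized) masker amplitude
#: scale; places the threshold crossing of the default encoder mid-grid
#: (around +10 dB SNR).
MASKER_DRIVE_SCALE = 2.6


def gen_experiment(
    n_participants: int,
    grid: ConditionGrid,
    mode: str = "linear",
    seed: int = 0,
    story_duration: float = 60.0,
    rate: float = 512.0,
    response_snr_db: float = -10.0,
    sensor_noise_snr_db: float = 10.0,
    kernel: KernelSpec | None = None,
    sr_params: SREncoderParams | None = None,
    inject_artifact_events: int = 0,
) -> ExperimentDataset:
    """Generate a full synthetic experiment (participants x conditions).

    ``linear`` mode produces condition-independent linear-model EEG (a null
    world in which no condition differences exist); ``sr`` mode maps each
    SNR to speech/masker drive gains under mixture-RMS normalization and
    passes the drives through the threshold population, so decreasing SNR
    increases the masker drive while slightly attenuating the speech drive.
    Each participant x condition cell gets its own story (envelope) and
    noise, with deterministic per-cell seeds derived from ``seed``.
    """
    if mode not in ("linear", "sr"):
        raise ValueError("mode must be 'linear' or 'sr'")
    kernel = kernel or KernelSpec(rate=rate)
    sr_params = sr_params or SREncoderParams()
    conditions = (["clear"] if grid.includes_clear else []) + [
        f"snr{v:+.1f}" for v in grid.snr_levels_db
    ]
    snr_of = dict(zip(conditions[-grid.n_levels :], grid.snr_levels_db))
    recordings: dict = {}
    envelopes: dict = {}
    truth: dict = {"kernel": kernel, "gains": {}}
    for p in range(n_participants):
        for c, cond in enumerate(conditions):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(p, c))
            s_env, s_noise, s_masker, s_art = (
                int(x % (2**31)) for x in ss.generate_state(4)
            )
            env = gen_speechlike_envelope(story_duration, rate, seed=s_env)
            if mode == "linear":
                rec, _ = gen_linear_eeg(
                    env, kernel, response_snr_db, n_channels=16, seed=s_noise
                )
            else:
                if cond == "clear":
                    a, mg = 1.0, 0.0
                    masker = None
                else:
                    a, b = _mixture_gains(snr_of[cond])
                    mg = MASKER_DRIVE_SCALE * b
                    masker = masker_envelope_from_noise(
                        story_duration, rate, seed=s_masker
                    )
                from dataclasses import replace

                p_cond = replace(
                    sr_params, gain=sr_params.gain * a, masker_gain=mg
                )
                truth["gains"][cond] = (p_cond.gain, mg)
                rec, _ = gen_sr_eeg(
                    env, masker, p_cond, kernel, sensor_noise_snr_db, seed=s_noise
                )
            if inject_artifact_events:
                rec = inject_artifacts(rec, inject_artifact_events, seed=s_art)
            recordings[(p, cond)] = rec
            envelopes[(p, cond)] = env
    manifest = {
        "mode": mode,
        "seed": seed,
        "n_participants": n_participants,
        "conditions": list(conditions),
        "story_duration": story_duration,
        "rate": rate,
        "response_snr_db": response_snr_db,
        "sensor_noise_snr_db": sensor_noise_snr_db,
        "kernel": asdict(kernel),
        "sr_params": asdict(sr_params),
        "snr_levels_db": [float(v) for v in grid.snr_levels_db],
        "includes_clear": grid.includes_clear,
        "inject_artifact_events": inject_artifact_events,
    }
    return ExperimentDataset(
        conditions=tuple(conditions),
        recordings=recordings,
        envelopes=envelopes,
        manifest=manifest,
        truth=truth,
    )
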