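# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Acoustic stimuli

SNR is defined on broadband RMS over the full story duration: mixing at
`snr_db` scales the masker so that `20·log10(rms(speech)/rms(masker)) =
snr_db` exactly. No level-dependent or speech-active-segment weighting is
applied; whole-story RMS is the simplest consistent definition and is used
everywhere. A masker longer than the speech is cropped from a seeded random
start offset (reproducible, no loop seams); shorter maskers are an error.

Two normalization schemes are supported because they disagree about what
"same loudness" means across SNR conditions: `mixture_rms` rescales the
finished mixture to a reference RMS (speech level inside the mixture falls
as SNR falls), `speech_rms` keeps the speech fixed (mixture level rises as
SNR falls). The package reference RMS (0.05 a.u.) stands in for a fixed
presentation level; absolute SPL calibration is out of scope.

Speech-matched noise keeps the FFT magnitude of the speech bin-wise and
redraws phases uniformly on (−π, π], synthesized on the one-sided spectrum
with real DC/Nyquist bins so the output is exactly real. Pink noise is
synthesized in the frequency domain with amplitude ∝ 1/√f, which gives the
−1 log-log PSD slope by construction. Babble sums RMS-equalized talker
streams and renormalizes; twelve independent streams sum to ≈√12 RMS before
normalization.

## Envelope front end

The auditory periphery is deliberately simple: 30 gammatone filters
(4th-order IIR, `scipy.signal.gammatone`) with centers equally spaced on
the ERB-number scale `ERBn(f) = 21.4·log10(0.00437·f + 1)` between 20 Hz
and 10 kHz (both configurable; the filterbank realization sits behind
`CochleagramParams` and can be swapped). Sub-band envelopes are Hilbert
magnitudes compressed pointwise by 0.6. The band average is low-passed at
40 Hz (4th-order Butterworth, zero-phase by default — the phase handling is
a package choice exposed in the parameters), differentiated (first
difference × rate, computed *before* resampling), half-wave rectified, and
polyphase-resampled to the EEG rate (512 Hz). Resampling can introduce
ringing of order 1e−6; the output is re-clipped at zero so the onset
envelope is non-negative everywhere.

Envelopes are always computed from the clear speech, also for masked
conditions — the regressor asks how well the brain tracks the *speech*,
not the mixture.

## EEG conditioning

Fixed order: 60 Hz elliptic notch (minimal-order band-stop, stopband
59.5–60.5 Hz, ≥80 dB, 0.4 dB passband ripple, forward–backward) →
linked-mastoid re-reference (mean of M1/M2 subtracted from the 16 scalp
channels; re-referencing twice raises) → 0.7 Hz high-pass (2449-tap Hann
FIR) and 22 Hz low-pass (211-tap Kaiser FIR) → polyphase downsampling to
512 Hz → optional component-removal hook (identity by default) → artifact
zeroing → 10 Hz low-pass (251-tap Kaiser FIR). FIR tap counts are defined
at 1024 Hz and rescaled proportionally (with a warning) at other rates;
Kaiser β is chosen for 60 dB sidelobe attenuation. All FIR filters are
odd-length linear-phase and applied with centered convolution, i.e. exact
group-delay compensation.

Artifact rule: every 0.2-s sliding window in which any channel's amplitude
range exceeds 80 µV (strict >) is zeroed in *all* channels; overlapping
flagged windows are unioned, and the zeroed samples are recorded in a mask.
The production implementation uses running max/min filters plus a coverage
difference-array (O(n)); a brute-force O(n·w) reference implementation is
kept in the package and the two are required to agree bit-exactly.
Cross-channel zeroing is the conservative reading of "any channel";
per-channel zeroing would be a trivial variant but is not implemented.

## TRF estimation

Predictors are lagged copies of the envelope; the lag grid contains every
integer sample shift k with `lag_min ≤ k/rate ≤ lag_max` (205 columns for
0–0.4 s at 512 Hz, 333 for −0.15–0.5 s). Out-of-story samples are
zero-padded. Columns are z-scored and the response centered, and ridge
weights solve `(Z'Z + λI)w = Z'y` per channel with λ = 10. The paper-level
convention under which λ is meaningful is not uniquely determined by the
method description; the z-scored-column convention is recorded in the
results object so fits remain comparable. `TRFResults.kernel` rescales the
weights by the column scales back to per-unit-envelope amplitude; that time
course is what component analysis and kernel-recovery comparisons use.

Snippet cross-validation draws 50 starts uniformly without replacement,
holds each snippet out once, and trains on all snippets that do not overlap
it (training snippets may overlap one another). Training moments are
accumulated as sums of per-snippet X'X and X'y — algebraically identical to
concatenating the training rows. Because every column is a shift of one
envelope, each snippet's X'X is assembled exactly from prefix sums of
lag-difference products in O(L²) lookups rather than an O(n·L²) product;
a test requires exact agreement with explicit concatenation. The reported
TRF is the average of the per-fold kernels; prediction accuracy averages
held-out Pearson correlations over folds and channels (NaN for degenerate
constant segments, excluded from means with a warning).

Edge taps of the analysis-lag TRF carry elevated estimation noise (the
usual boundary artifact of barely-regularized lagged regressions); all
component windows are interior, so this does not propagate into P1−N1 or
P2−N1.

A model-free cross-correlation variant (`crosscorr_tracking`, Pearson at
each lag over the fully-overlapping segment) is provided as a check on the
ridge pipeline.

## Components

Latency search windows default to P1 0.02–0.09 s, N1 0.06–0.16 s, P2
0.14–0.30 s — canonical auditory morphology, configurable, and not claimed
to be the original analysis values. The P1 < N1 < P2 ordering is enforced
by sequential constrained search (each window is clipped to begin after the
previous component), so noise-only inputs yield ordered (if meaningless)
latencies plus an edge warning instead of a hard failure mid-analysis.
Latencies are group-level only; amplitudes are per-participant 0.02-s
windowed means, and windows that would leave the lag range raise instead of
silently truncating.

## Statistics

The sliding average over SNR neighbors (3 for the fine 21-level grid, 4
for coarser designs) mirrors the averaging of the clear-condition stories;
on the +30…−2 dB grid with window 3 the centers run +28.4…−0.4 dB. Paired
t-tests against clear speech are corrected with Benjamini-Hochberg FDR
(step-up, flags at adjusted p ≤ q; Benjamini-Yekutieli would be a one-line
variant but BH is the default). The broken stick fits two *independent*
least-squares lines — per-piece slope tests imply no continuity constraint
— with the breakpoint sample shared by both pieces, chosen by minimum
combined RMSE on the group mean over interior grid candidates; numerically
tied candidates resolve to the highest-SNR one via a scale-aware tolerance
(1e−9 of the mean absolute profile value). Per-participant slopes on each
piece's range feed one-sample t-tests; identically-zero slopes return
t = 0, p = 1 (trivially non-significant) while zero variance around a
nonzero mean raises. rmANOVA-style factorial tests are intentionally not
implemented; profiles export as tidy long-format tables for external
statistics software.

## Synthetic data

The generator defines the conditions under which the pipeline is verified:

- **Envelopes**: Poisson onset events at 4 Hz (syllabic rate) with
  gamma-distributed strengths (mean 1), convolved with a 20-ms-rise alpha
  pulse, normalized to unit maximum. Stories must be ≥ 25 s so the snippet
  scheme applies.
- **Linear mode**: EEG = known kernel (Gaussian deflections +1.0 at 60 ms,
  −1.3 at 110 ms, +0.8 at 200 ms) ⊛ envelope, scaled by a fronto-centrally
  peaked channel topography, plus 1/f (pink) sensor noise. `response_snr_db`
  is signal-to-noise power for a unit-topography channel; −10 dB is the
  default heavy-noise condition. Synthetic recordings model
  already-re-referenced EEG; analyses apply the conditioning chain's final
  10 Hz low-pass before fitting, exactly as real preprocessing restricts
  TRF estimation to the low-frequency band (without it, broadband noise
  makes the barely-regularized estimate much noisier). Under the default
  conditions (12 stories × 2 min) the recovered-kernel correlation with the
  truth is typically 0.93–0.98.
- **SR mode**: a population of 100 rectified-linear threshold units
  (threshold 1.0, internal noise SD 0.05, speech gain 0.6 — subthreshold
  for a unit-max envelope). Rectified-linear output is the default for a
  smooth masker sweep; a Heaviside variant is available. The masker
  envelope comes from stationary noise (Hilbert magnitude, 40 Hz LP, unit
  mean); the full cochleogram route is available so babble and
  speech-matched noise can differ in envelope statistics. Experiment
  generation maps SNR to drive gains under mixture-RMS normalization
  (speech scale `1/√(1+10^(−snr/10))`, masker drive `2.6 ×` the masker
  amplitude scale, placing the threshold crossing of the default encoder
  near +10 dB SNR). The encoder is a demonstration of the proposed
  mechanism, not a fitted model: none of its parameters are estimated from
  data, and no quantitative empirical claim rests on it.

Every cell (participant × condition) derives its seeds deterministically
from the experiment seed, so a dataset regenerates bit-identically from its
manifest.

What passing tests show — and don't. The linear-mode recovery results show
the estimator chain is correct and well-calibrated *under the generator's
assumptions*: a single linear kernel, stationary pink noise, topography
known to peak fronto-centrally, no eye/muscle artifacts unless injected,
no inter-participant kernel variability. Real EEG violates all of these to
some degree; passing recovery therefore validates the code, not the
neuroscience. The SR signature (interior maximum of envelope-locked power
over masker level for subthreshold drive; maximum at zero masker for
suprathreshold drive) is a property of the encoder, offered as an existence
proof of the mechanism, not evidence that human auditory cortex implements
it.

## Sizes used by the shipped checks

The test-suite and acceptance-script simulations use desk-scale sizes
chosen as the package's own defaults: 12 stories × 2 min for kernel
recovery, 22 simulated participants × 1 story for prediction accuracy, 200
breakpoint-recovery and 5000 slope-calibration simulations, 20-seed masker
sweeps on 30-s envelopes, and an SR-mode experiment of 10 participants ×
(clear + 11 SNRs) × 40-s stories. The broken-stick recovery adds cell noise
with SD 0.25 × the piece-1 rise on the raw 21-level grid and applies the
3-neighbor sliding average before fitting, matching the analysis order used
on real profiles.

## Known limitations

- ICA-based artifact removal is an interface hook only (identity default).
- No per-participant latency estimation, no topographic statistics beyond
  the fixed cluster, no λ search (fixed at 10 by design), no banded or
  multi-feature TRFs.
- The EDF/BDF reader requires `mne` and is read-only; the package container
  is HDF5.
- PCM WAV quantization is documented but no dithering is applied on write.
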