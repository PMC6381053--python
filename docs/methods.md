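# Methods

`ecogmap` implements the computational core of a real-time
electrocorticographic (ECoG) functional mapping system: a block-wise
streaming pipeline that turns raw intracranial recordings into per-channel
high-gamma band power, and a trial-locked statistical map of task-related
activation with false-discovery-rate control. Everything is exercised on
synthetic sessions with known ground truth, so every stage is testable
without patient data.

## Signal model and preprocessing

The unit of streaming is the *sample block* (default 20 ms): acquisition
systems deliver `channels x block_samples` arrays plus a packed per-sample
state vector carrying integer markers such as `StimulusCode` (zero between
trials, the stimulus identifier while a stimulus is shown). The
preprocessing chain is:

1. **Common average reference (CAR).** At each sample, the mean over the
   included channels is subtracted from each included channel. The
   inclusion list defaults to all channels and can exclude bad contacts.
2. **IIR Butterworth cascade** at the native rate (default 1 kHz):
   4th-order low-pass at 110 Hz, 2nd-order high-pass at 70 Hz, and a
   4th-order notch at the mains frequency, realized as a Butterworth
   band-stop with a −3 dB band of 58–62 Hz (the mains line gives only
   order and center; a ±2 Hz band is a conventional choice and is
   config-exposed). All sections are designed by bilinear transform with
   frequency pre-warping, so the realized −3 dB points sit on the printed
   cutoffs; designs are emitted as second-order sections and verified
   stable (all poles strictly inside the unit circle).
3. **Decimation to 500 Hz** by integer-factor sample picking with a phase
   counter. No extra anti-alias filter is inserted: the mandated 110 Hz
   low-pass already suppresses content above the 250 Hz post-decimation
   Nyquist.

Filter memory and decimation phase persist across blocks, so block-wise
processing is numerically identical to one offline call — the streaming
tests assert this to 1e-8 relative and it holds to rounding noise. The
passband that survives the cascade is roughly 70–110 Hz, which is what
makes the downstream band integral a *high-gamma* power estimate. Note
that a 2nd-order high-pass leaves ≈ −15 dB at 30 Hz; strong low-frequency
rhythms are attenuated, not removed.

## Burg autoregressive band power

On each sliding window (default 256 ms, sliding by 20 ms, right-aligned so
the estimate at time t uses samples (t − window, t] and is causal) an
AR(p) model is fit by the Burg lattice recursion: each stage's reflection
coefficient minimizes the summed forward + backward prediction error, and
coefficients update by the Levinson recursion. Reflection magnitudes are
< 1 by construction, so the model is always stable. With
A(z) = 1 + Σ a_k z^(−k) and residual variance σ², the one-sided PSD is

    P(f) = 2 σ² / ( fs · |A(e^(−2πif/fs))|² )

Band power integrates P over 70–110 Hz (trapezoid on a 2 Hz grid) and is
natural-log transformed by default — power is strongly right-skewed and
the log makes the downstream t-statistics far better behaved; the
transform is a config flag for sensitivity analysis. Model order defaults
to 16 at 500 Hz: enough to resolve a single high-gamma peak in a 128–256
ms window without overfitting it; order, grid, and band are config-exposed
rather than asserted as any production system's exact values. The Burg
kernel is vectorized across windows (each lattice stage is a handful of
elementwise array operations), which is what keeps desk-scale Monte-Carlo
runs (hundreds of full sessions) in minutes.

## Trial-locked mapping

Trial onsets are the 0 → non-zero transitions of `StimulusCode` sampled at
the feature rate. Each trial contributes a fixed window of feature bins
(default −1000 … +2000 ms, inclusive grid, bin spacing = the feature
slide, 151 bins). Per channel, a **baseline distribution** pools every bin
whose center lies in −1000 … −200 ms before onset, across all trials
(41 bins × trials), with mean μ_b and sd σ_b (ddof = 1). Each
time-channel bin's across-trials sample is compared with the baseline pool
by a two-tailed two-sample t-test; the Welch (unequal-variance) form is
the default because the two samples differ hugely in size, with the pooled
form available as a flag. The resulting p-values are thresholded jointly
over all testable time-channel bins of the map by the Benjamini-Hochberg
step-up rule at q = 0.05 (the whole raster is one family; per-channel
correction is deliberately not used). Display values are baseline
z-scores, (bin mean − μ_b)/σ_b; non-significant bins are masked, never
deleted; channels with a numerically constant baseline are flagged
untestable and excluded from the family. Degenerate bins report t = 0,
p = 1.

Maps update after every accepted trial by recomputation over all trials so
far — trial counts are small, so no streaming approximation of the
t-statistic is used, and incremental ≡ batch holds exactly. A **live
mode** z-scores each feature step against an exponentially weighted
running baseline (time constant τ = 30 s; update weight
max(1/n, 1 − e^(−Δt/τ)), so the τ → ∞ limit degrades gracefully to
cumulative fixed-baseline z-scoring); its first τ seconds are flagged as
warm-up.

### Known limitation: anti-conservatism under overlapping bins

The pooled baseline treats its 41 bins per trial as independent draws, but
with a 256 ms window sliding by 20 ms, neighbouring bins share ~92% of
their samples. The Welch denominator therefore underestimates the variance
of the baseline mean: if ρ_d is the correlation between baseline bins d
slides apart, the true Var(pooled mean) is larger than the iid value by
the factor Σ_d ρ_d (≈ 9–10 here), inflating the null t-statistic's scale
by sqrt((1/n_t + Σρ/n_b) / (1/n_t + 1/n_b)) for n_t trials and an n_b-value
pool. The realized false-discovery proportion of the thresholded map on
synthetic sessions therefore runs above the nominal q — the acceptance
run measures this directly — and the effect vanishes only when bins do
not overlap (slide ≥ window, where Σρ → 1). Users who need strict FDR
control should treat the q = 0.05 mask as a display threshold, lower q,
or use non-overlapping statistics bins; the window/slide and q are all
config-exposed. This is a property of the pooled-baseline procedure
itself, not of its implementation here.

A second, related caveat: the common average reference mixes −1/N of every
channel into every other channel, so a genuine high-gamma burst on a few
channels leaves a faint negative ghost on the rest. For truth-scored
synthetic evaluation this package therefore scores the CAR-less pipeline
(the generator's channel-level truth then matches what the pipeline sees);
CAR remains the default for ordinary use, where it removes common-mode
and line contamination.

## Synthetic sessions

The generator emulates the *statistical* structure the mapping stage
consumes, not neural waveform morphology (no spikes, no evoked
potentials, no BCI2000 file emission):

- per-channel 1/f^α background noise (α = 1), synthesized by shaping
  white-noise FFT magnitudes by f^(−α/2) and rescaled to an exact RMS
  (default 15 µV);
- one shared common-mode waveform (same synthesis, default 10 µV RMS)
  added to every channel — removable exactly by CAR;
- a mains sinusoid (60 Hz, 5 µV) identical on all channels;
- a `StimulusCode` state channel that is zero between trials and holds the
  trial's code for the stimulus duration;
- on the modulated channels, the channel's own 70–110 Hz band-limited
  component is amplitude-scaled by `mod_gain` during a burst at a fixed
  latency after each onset (default 0.2–0.8 s, gain 3), with 10 ms
  raised-cosine ramps inside the burst interval so injected energy never
  leaks outside it. Because the scaling is multiplicative on the in-band
  amplitude, in-band power on the plateau is exactly `mod_gain²` ×
  baseline, giving a closed-form oracle for every downstream stage.

The default fixture is 16 channels at 1 kHz, 30 trials of 2 s with 2 s
inter-stimulus intervals (a ~2-minute session) — small enough that
hundreds of full-pipeline replicates run on one CPU in minutes, large
enough that per-bin tests at 30 trials have realistic power. Ground truth
is defined at the feature-bin level: a bin is truly modulated iff its
causal window support (t − window, t] overlaps a burst on a modulated
channel. What passing tests show about real data is deliberately limited:
real ECoG has non-Gaussian transients, non-stationary baselines and
behaviourally jittered responses, none of which the generator produces.

## Replay and streaming

Sessions are stored in a single-file container (JSON header + float32
signal + uint16 state) and replayed over TCP in the documented binary
protocol (`docs/wire_format.md`): handshake, then one signal/state packet
per block, with a strict-FIFO command broker multiplexing any number of
clients. The raw tap streams the unprocessed signal (the client runs the
full chain); the feature tap runs the chain server-side and streams the
band-power series. The pacing multiplier affects wall-clock delivery only;
tests assert records are identical at any speed, and that streamed mapping
equals the offline pipeline on the same file (same masks, |Δz| ≤ 1e-6 —
transport floats are the container's float32, so no extra quantization is
introduced).

## Numerical and edge-case policy

- Constant analysis windows raise a degenerate-input error in the
  single-window Burg fit; in batch they yield zero coefficients and are
  flagged by the zero-variance guard downstream.
- Band power is floored at the smallest positive double before the log.
- Trials whose analysis window leaves the recording are dropped with a
  logged warning, never padded; zero usable trials is an error.
- p-values are clipped to (1e-300, 1]; BH uses a stable sort, so ties
  reject deterministically.
- The .eds container stores float32 samples; all computation is float64.
- Every randomized component takes an explicit integer seed; identical
  configs are bit-identical.
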