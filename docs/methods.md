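# Methods

## Signal model

Voiced speech is modeled as a harmonic process: every spectral component is
an integer multiple of a slowly varying fundamental f0(t). The pipeline's
object of interest is the lower-sideband cubic distortion product that a
pair of harmonic elicitors (harmonic numbers n < m) evokes in the cochlea.
Because both elicitors are derived from one analytic representation
A(t)·e^{iΦ(t)} of the fundamental waveform by phase multiplication, the
expected emission waveform is itself the (2n−m)-th harmonic waveform and is
known sample-for-sample — up to a gain, a delay of a few milliseconds, and
a constant phase rotation. Detection is therefore a matched-template
problem, and the complex cross-correlation envelope removes the unknown
phase.

## Fundamental-frequency tracking

`estimate_f0` is a YIN-style estimator: per frame (2048 samples, hop 512 at
44.1 kHz — standard speech-analysis framing) it computes the difference
function over a 1024-sample integration window via FFT correlation,
normalizes it cumulatively, takes the first dip below an absolute threshold
(0.15), refines it to the local minimum and by parabolic interpolation, and
declares the frame voiced when the dip depth is below 0.35 and the frame is
not silent relative to the loudest frame (2%). All parameters are exposed.
The estimator is intentionally minimal: it targets clean, strongly periodic
sources (synthetic voices, TTS audiobooks), not adverse acoustic
conditions. f0 statistics use the population SD over voiced frames, a
convention fixed for determinism.

## Fundamental waveform

The fundamental waveform is obtained with a Butterworth bandpass
(maximally flat, to avoid passband ripple feeding into the instantaneous
phase) with corners at mean f0 ± 0.5 SD, applied forward and backward
(`sosfiltfilt`) for exact zero phase. "Sixth-order" is read as the order of
the one-pass filter (six poles; the cascade then has twelve); the
alternative reading is available via `order_convention="combined"`, where
the nearest realizable symmetric bandpass is used. A degenerate band
(sd_f0 = 0, e.g. pure-tone test sources) is widened to a configurable
minimum half-bandwidth of 5 Hz with a warning. Z-scoring spans the whole
trial, voiced and unvoiced samples alike.

## Harmonic synthesis

The analytic signal is computed by `scipy.signal.hilbert` after tapering
the first and last 50 ms with a raised cosine: finite-length end
transients otherwise corrupt A(t) and Φ(t). The phase is unwrapped once
before multiplication, since wrapped phase times k is discontinuous at wrap
points. No per-harmonic amplitude shaping is applied: every harmonic
carries the fundamental's envelope A(t), which also guarantees that
voiceless stretches stay silent in all harmonics and in the expected
emission waveform. Channel assembly sums lower harmonics into W1 and
higher harmonics into W2 (played through separate speakers in a real
setup), zero-pads unequal pairs at the tail, and applies a single scalar to
all waveforms so the combined-channel RMS maps to the target level under
the calibration anchor *digital RMS 2.0e-3 ↔ 37 dB SPL*. The anchor is a
configuration constant, not hardware control: only the relative contract
matters at desk scale.

## Synthetic data

`synth_voiced_source` emulates a narrated voice: a harmonic stack
(fundamental plus 9 overtones, 1/k amplitude tilt, aliased terms dropped)
whose f0 follows a Gaussian random walk smoothed over 1 s and affinely
rescaled to the target mean/SD (female 195 ± 40 Hz, male 90 ± 20 Hz), with
silent gaps of ~0.5 s totalling 20% of the duration (voiced_fraction 0.8)
and 20 ms on/off ramps. Everything is reproducible from one seed.

What it does **not** emulate: formant structure and spectral tilt beyond
1/k, jitter/shimmer, consonant noise, reverberation, or any cochlear
mechanics — `simulate_recording` embeds the expected emission waveform
directly (scaled, delayed, phase-rotated), plus elicitor leak-through and
white or pink noise. Passing tests therefore demonstrate that the
*measurement pipeline* recovers known embedded quantities under realistic
noise and leak conditions; they say nothing about the physiology of
emission generation. The in-band SNR convention used throughout defines
noise by its RMS within the band holding the central 90% of the DP
waveform's power.

## Detection

The complex cross-correlation is computed at one-sample lag resolution
(0.023 ms; delays are reported without sub-sample interpolation, ties break
to the smallest lag) over ±750 ms. Both signals are de-meaned; per lag the
correlation is divided by the template's L2 norm over the overlap
("matched" mode, the default), so the envelope stays in recording-amplitude
units and is **linear in emission gain** — an embedded emission of gain g
peaks at ≈ g·template_norm, which the gain-recovery tests exploit. A
"pearson" mode additionally divides by the recording's overlap norm,
yielding a bounded correlation coefficient; it is scale-invariant and hence
cannot express gain linearity, but is the right scale-free criterion for
the stimulus-lock test in hardware-delay estimation (default lock threshold:
coefficient 0.1 over ±50 ms). The template's analytic representation is
computed once per call; the recording itself is never transformed.

Noise statistics come from the envelope at lags [−750, −70] and
[+70, +750] ms, far from plausible emission delays: per-trial peaks
(searched in [−2, +4] ms, i.e. 1 ± 3 ms) are significant above the linear
interpolation 97th percentile; grand-average peaks (pointwise mean of
envelopes, noise re-estimated on the averaged envelope) must exceed the
noise maximum. For recordings too short to host ±750 ms lags, both the lag
range and the noise windows shrink proportionally with a warning — the full
windows are used whenever trial length permits.

Trial-level significance at the 97th percentile has a non-trivial null
exceedance by construction (the search window holds roughly one to two
independent envelope samples given the template bandwidth); the null
calibration suite measures it at ≈ 8% over 200 seeded noise trials, well
below the 20% bound the pipeline is tested against. A peak elsewhere
between the noise windows that exceeds both the threshold and the in-window
maximum is reported as "out-of-window energy" in the peak diagnostics
rather than as a detection.

## Group statistics

Per participant and (stimulus × condition) cell, amplitudes are read at
the grand-average peak delay for *all* trials, delays averaged over
significant trials only. Contrast tests are selected by a Shapiro–Wilk
check at α = 0.05 on paired differences (paired design) or on both groups
(unpaired): parametric t-tests when normality is not rejected, Wilcoxon
signed-rank / Mann–Whitney U otherwise; the policy can be forced either
way. Identical paired differences trigger a degenerate-test warning and
the nonparametric fallback. All contrasts computed in one call form a
single Benjamini–Hochberg FDR family. Amplitude effects are reported as
ratios of group means together with 20·log10(ratio) dB, unrounded. MAD
based outlier exclusion (|x − median| > 3·MAD) is available but off by
default and always returns the excluded values explicitly.

## Problem sizes and numerical choices

Desk-scale runs use trials of 2–4 s and single-pair stimulus sets for
Monte-Carlo suites (null calibration with 200 trials, SNR sweeps with
common random numbers across levels so rates are comparable), 3 s trials
for 38-participant × 20-replicate cohort simulations, and 20–60 s sources
for f0-statistics and autocorrelation checks; per-participant gains
scatter log-normally (SD 0.1) around the condition means. Emission delays
are realized at integer samples; waveforms are float64 throughout; all
randomness flows through `numpy.random.default_rng` seeds.

## Known limitations

- The f0 tracker is not a full probabilistic-YIN implementation (no HMM
  smoothing over candidate trajectories); octave errors are possible on
  weak-fundamental material.
- The "combined" filter-order reading is approximated by the nearest
  realizable even-order symmetric bandpass.
- The simulator's emission model is phenomenological: gain, delay and
  phase are free parameters per condition, with no mechanistic link to
  attention or efferent physiology.
- Pure-tone DPOAE measurement is supported only as waveform construction
  (`pure_tone_pair`); no swept or multi-level paradigms.
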