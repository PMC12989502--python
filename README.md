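# speechdpoae

Tools for eliciting and detecting **speech-like distortion-product
otoacoustic emissions (DPOAEs)** — cochlear emissions evoked by a pair of
harmonic elicitor waveforms derived from running speech rather than by two
pure tones. The package is aimed at auditory neuroscientists who want to
design such stimuli, simulate ear-canal recordings with known embedded
emissions, and run the full detection and group-statistics pipeline at desk
scale.

## The method

A voiced speech signal has a slowly varying fundamental frequency f0(t).
From the speech waveform the pipeline extracts the *fundamental waveform*
w0(t) — a zero-phase sixth-order Butterworth bandpass around the mean f0
(± 0.5 SD), z-scored — and forms its analytic representation via the
Hilbert transform,

    W0(t) = w0(t) + i·H[w0(t)] = A(t)·e^{iΦ(t)}.

Harmonic elicitors are built by phase multiplication,

    w_k(t) = Re[A(t)·e^{i·k·Φ(t)}],

so a pair (w_n, w_m) with n < m has instantaneous frequencies n·f0(t) and
m·f0(t). The cochlear nonlinearity responds with the lower-sideband cubic
distortion product at (2n−m)·f0(t) — exactly the harmonic waveform
w_{2n−m}(t), which is known in advance and serves as a matched template.

Detection computes the **complex cross-correlation** of the ear-canal
recording with w_{2n−m}: the real/imaginary parts correlate the recording
with the real/imaginary parts of the template's analytic representation,
and the envelope (modulus) is invariant to any constant phase offset of the
emission. A per-trial peak (searched at lags of 1 ± 3 ms) is significant if
it exceeds the 97th percentile of the envelope at far lags (±70–750 ms);
grand-average peaks must exceed the far-lag maximum. Per-participant
amplitudes (envelope at the grand-average peak delay) are contrasted across
attentional conditions with paired t / Wilcoxon tests and
Benjamini–Hochberg FDR control, reported as ratios and in dB
(20·log10 ratio).

The default stimulus roster pairs resolved and unresolved harmonics of a
female-like (f0 ≈ 195 ± 40 Hz) and a male-like (f0 ≈ 90 ± 20 Hz) voice:

| stimulus | n | m | 2n−m | m/n |
|----------|---|---|------|-----|
| F_res    | 7 | 9 | 5    | 1.29 |
| F_unres  | 15| 18| 12   | 1.2  |
| M_res    | 6 | 8 | 4    | 1.33 |
| M_unres  | 15| 18| 12   | 1.2  |

## Worked example

```python
import numpy as np
import speechdpoae as sd

# a 20 s female-like voiced source with known f0 statistics
src = sd.synth_voiced_source(
    sd.VoicedSourceSpec(duration=20, mean_f0=195, sd_f0=40, seed=7))
track = sd.estimate_f0(src, fmin=100, fmax=350)
stats = sd.f0_stats(track)
print(f"f0 = {stats.mean_f0:.1f} ± {stats.sd_f0:.1f} Hz")

w0 = sd.extract_fundamental(src, stats)
pair = sd.make_pair(w0, sd.HarmonicPairSpec(7, 9, "female", "resolved"))
stim = sd.assemble_set([pair])      # level-calibrated stimulus set
w_dp = stim.pairs[0].w_dp           # expected emission waveform (template)

# embed an emission (gain 1e-3, delay 2 ms, arbitrary phase) at 20 dB
# in-band SNR behind a strong elicitor leak and a 3.2 ms hardware delay
em = sd.EmissionSpec(0, gain=1e-3, delay_ms=2.0, phase_rotation=np.pi/3)
noise = sd.white_noise_rms_for_inband_snr(w_dp, stim.fs, 20.0, gain=1e-3)
rec = sd.simulate_recording(stim, [em], noise_rms=noise, leak_gain=1.0,
                            hardware_delay_ms=3.2, seed=1)

hw = sd.estimate_hardware_delay(rec, stim)
cg = sd.complex_xcorr(sd.correct_delay(rec, hw), w_dp)
peak = sd.detect_trial_peak(cg, sd.noise_floor(cg))
print(f"hardware delay {hw:.2f} ms; emission at {peak.delay_ms:.2f} ms, "
      f"significant={peak.significant}, gain {peak.amplitude/cg.template_norm:.2e}")
```

Output:

```
f0 = 194.1 ± 41.3 Hz
hardware delay 3.20 ms; emission at 2.02 ms, significant=True, gain 9.96e-04
```


The tracker recovers the programmed f0 statistics; the hardware delay, the
emission delay and the linear emission gain are all recovered from the
noisy recording.

A CLI wraps the same pipeline (`speechdpoae synthesize | simulate | detect
| analyze | report`); configuration lives in a YAML `RunConfig` whose
defaults are the published measurement constants.

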