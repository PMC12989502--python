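"""Synthetic voiced sources and simulated ear-canal recordings.

The generator provides a fully controlled stand-in for the two experimental
ingredients no repository can ship: a voiced speech source with a slowly
wandering fundamental frequency (female-like 195 ± 40 Hz or male-like
90 ± 20 Hz), and the microphone signal recorded in the ear canal. A
simulated recording is the sum of (i) scaled, delayed, phase-rotated copies
of the expected distortion-product waveforms, (ii) elicitor leak-through
(the stimulus is physically present in the canal, typically far above the
emission), and (iii) broadband white or pink noise. Every embedded emission
is recorded in a ground-truth sidecar so that detection can be validated
against known delays, gains and phases.

No cochlear mechanics are modeled; the simulator embeds the expected
emission waveform directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import hilbert

from .audio import DEFAULT_FS, rms, read_wav, write_wav
from .fundamental import SourceSignal
from .synthesis import StimulusSet, normalize_rms


@dataclass
class VoicedSourceSpec:
    """Parameters of a synthetic voiced source.

    Defaults model the female narrator condition: mean f0 195 Hz with 40 Hz
    SD wandering on a ~1 s timescale, ten-component harmonic stack with a
    1/k spectral tilt, and 80% voiced time (the remainder is silence, as in
    read speech with natural pauses).
    """

    duration: float = 120.0
    mean_f0: float = 195.0
    sd_f0: float = 40.0
    f0_wander_timescale: float = 1.0
    n_source_harmonics: int = 9
    voiced_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.voiced_fraction <= 1):
            raise ValueError("voiced_fraction must be in (0, 1]")
        if self.mean_f0 - 3 * self.sd_f0 <= 0:
            raise ValueError("mean_f0 - 3*sd_f0 must stay positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _f0_trajectory(spec: VoicedSourceSpec, n_samples: int, fs: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth random f0 wander with exact target mean and SD.

    A Gaussian random walk at a 100 Hz control rate is smoothed by a moving
    average of one wander timescale, affinely rescaled to the requested
    mean/SD, clipped to stay positive, and interpolated to sample rate.
    """
    ctrl_rate = 100.0
    n_ctrl = max(int(np.ceil(spec.duration * ctrl_rate)) + 1, 8)
    walk = np.cumsum(rng.standard_normal(n_ctrl))
    win = max(int(round(spec.f0_wander_timescale * ctrl_rate)), 1)
    kernel = np.ones(win) / win
    smooth = np.convolve(np.pad(walk, (win // 2, win - 1 - win // 2), mode="edge"),
                         kernel, mode="valid")
    sd = np.std(smooth)
    z = (smooth - np.mean(smooth)) / sd if sd > 0 else np.zeros_like(smooth)
    f0_ctrl = np.clip(spec.mean_f0 + spec.sd_f0 * z, 1.0, None)
    t_ctrl = np.arange(n_ctrl) / ctrl_rate
    t = np.arange(n_samples) / fs
    return np.interp(t, t_ctrl, f0_ctrl)


def _voicing_envelope(spec: VoicedSourceSpec, n_samples: int, fs: int,
                      rng: np.random.Generator) -> np.ndarray:
    """0/1 voicing envelope with smooth 20 ms ramps around silent gaps."""
    env = np.ones(n_samples)
    gap_total = (1.0 - spec.voiced_fraction) * spec.duration
    if gap_total <= 0:
        return env
    mean_gap = 0.5
    n_gaps = max(1, int(round(gap_total / mean_gap)))
    gap_len = gap_total / n_gaps
    centers = np.sort(rng.uniform(0.05 * spec.duration, 0.95 * spec.duration, n_gaps))
    for c in centers:
        lo = max(0, int(round((c - gap_len / 2) * fs)))
        hi = min(n_samples, int(round((c + gap_len / 2) * fs)))
        env[lo:hi] = 0.0
    ramp_n = max(int(round(0.02 * fs)), 1)
    kernel = np.hanning(2 * ramp_n + 1)
    kernel /= kernel.sum()
    return np.convolve(np.pad(env, (ramp_n, ramp_n), mode="edge"), kernel, mode="valid")


def synth_voiced_source(spec: VoicedSourceSpec, fs: int = DEFAULT_FS,
                        target_rms: float = 2.0e-3, label: str = "synthetic") -> SourceSignal:
    """Generate a voiced source signal; bit-reproducible from the seed.

    The waveform is a harmonic stack (fundamental plus ``n_source_harmonics``
    overtones with 1/k amplitudes, aliased components dropped) following the
    random f0 trajectory, gated by the voicing envelope and normalized to
    the digital-waveform RMS convention of 2.0e-3.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * fs))
    f0 = _f0_trajectory(spec, n, fs, rng)
    phase = 2 * np.pi * np.cumsum(f0) / fs
    x = np.zeros(n)
    f0_max = float(f0.max())
    for k in range(1, spec.n_source_harmonics + 2):
        if k * f0_max > 0.45 * fs:
            break
        x += np.sin(k * phase) / k
    x *= _voicing_envelope(spec, n, fs, rng)
    x = normalize_rms(x, target_rms)
    return SourceSignal(samples=x, fs=fs, label=label)


FEMALE_SOURCE = VoicedSourceSpec(mean_f0=195.0, sd_f0=40.0)
MALE_SOURCE = VoicedSourceSpec(mean_f0=90.0, sd_f0=20.0)


@dataclass
class EmissionSpec:
    """One distortion-product emission embedded in a simulated recording.

    ``pair_index`` names the StimulusPair (by position in the stimulus set)
    whose expected DP waveform is embedded; the waveform is scaled by
    ``gain``, shifted by ``delay_ms`` and rotated by ``phase_rotation``
    radians in the analytic domain — the constant phase offset real
    emissions carry relative to the constructed waveform.
    """

    pair_index: int
    gain: float
    delay_ms: float = 1.0
    phase_rotation: float = 0.0

    def __post_init__(self):
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if abs(self.delay_ms) > 50:
            raise ValueError("emission delay must be within ±50 ms")


@dataclass
class EarCanalRecording:
    """Microphone-channel samples with trial metadata.

    ``truth`` carries the embedded emission specs (simulated data only).
    """

    samples: np.ndarray
    fs: int
    trial_id: str = ""
    condition_label: str = ""
    participant_id: str = ""
    truth: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording samples must be finite")


def _shift(x: np.ndarray, n: int) -> np.ndarray:
    """Shift right by n samples (left for negative n), zero-filled."""
    out = np.zeros_like(x)
    if n >= 0:
        if n < x.size:
            out[n:] = x[: x.size - n]
    else:
        if -n < x.size:
            out[: x.size + n] = x[-n:]
    return out


def _colored_noise(n: int, color: str, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if color == "white":
        return white
    if color == "pink":
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        shaping = np.ones_like(freqs)
        nonzero = freqs > 0
        shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
        shaping[0] = 0.0
        return np.fft.irfft(spec * shaping, n)
    raise ValueError("noise_color must be 'white' or 'pink'")


def spectral_band(w: np.ndarray, fs: int, coverage: float = 0.9) -> tuple:
    """Frequency band holding the central ``coverage`` of a waveform's power."""
    spec = np.abs(np.fft.rfft(np.asarray(w, dtype=float))) ** 2
    freqs = np.fft.rfftfreq(len(w), 1 / fs)
    cum = np.cumsum(spec)
    cum /= cum[-1]
    tail = (1 - coverage) / 2
    lo = freqs[np.searchsorted(cum, tail)]
    hi = freqs[np.searchsorted(cum, 1 - tail)]
    return float(lo), float(hi)


def white_noise_rms_for_inband_snr(w_dp: np.ndarray, fs: int, snr_db: float,
                                   gain: float = 1.0) -> float:
    """Total white-noise RMS giving a target SNR within the DP waveform's band.

    White noise of total RMS sigma carries in-band RMS
    sigma·sqrt(bandwidth / Nyquist); the SNR is defined as the embedded
    emission RMS (gain·RMS(w_dp)) over that in-band noise RMS.
    """
    lo, hi = spectral_band(w_dp, fs)
    bw_frac = max(hi - lo, 1.0) / (fs / 2)
    return gain * rms(w_dp) * 10.0 ** (-snr_db / 20.0) / np.sqrt(bw_frac)


def simulate_recording(
    stimuli: StimulusSet,
    emissions: list,
    noise_rms: float,
    noise_color: str = "white",
    leak_gain: float = 0.0,
    seed: int = 0,
    hardware_delay_ms: float = 0.0,
    trial_id: str = "",
    condition_label: str = "",
    participant_id: str = "",
) -> EarCanalRecording:
    """Simulate one ear-canal recording for a stimulus set.

    recording = Σ_j gain_j · rotate(shift(w_dp_j, hw_delay + delay_j), φ_j)
                + leak_gain · shift(W1 + W2, hw_delay) + noise.

    The hardware delay shifts everything the probe picks up (leak-through
    and emissions alike); each emission is additionally delayed by its own
    physiological delay. The truth field retains the emission specs.
    """
    fs = stimuli.fs
    n = len(stimuli.W1)
    rng = np.random.default_rng(seed)
    n_hw = int(round(hardware_delay_ms * fs / 1000.0))
    out = np.zeros(n)
    for em in emissions:
        if not (0 <= em.pair_index < len(stimuli.pairs)):
            raise ValueError(f"emission references pair {em.pair_index} outside the set")
        pair = stimuli.pairs[em.pair_index]
        if pair.fs != fs:
            raise ValueError("sampling-rate mismatch between emission pair and set")
        z = hilbert(pair.w_dp)
        wave = np.real(z * np.exp(1j * em.phase_rotation))
        n_shift = n_hw + int(round(em.delay_ms * fs / 1000.0))
        out += em.gain * _shift(wave, n_shift)
    if leak_gain:
        out += leak_gain * _shift(stimuli.W1 + stimuli.W2, n_hw)
    if noise_rms > 0:
        noise = _colored_noise(n, noise_color, rng)
        out += noise * (noise_rms / rms(noise))
    return EarCanalRecording(
        samples=out,
        fs=fs,
        trial_id=trial_id,
        condition_label=condition_label,
        participant_id=participant_id,
        truth=list(emissions),
    )


def write_recording(rec: EarCanalRecording, wav_path, sidecar_path=None) -> None:
    """Write a recording as WAV plus a JSON truth sidecar."""
    write_wav(wav_path, rec.samples, rec.fs)
    if sidecar_path is not None:
        payload = {
            "trial_id": rec.trial_id,
            "condition_label": rec.condition_label,
            "participant_id": rec.participant_id,
            "fs": rec.fs,
            "truth": [asdict(e) for e in rec.truth],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_recording(wav_path, sidecar_path=None) -> EarCanalRecording:
    """Read a recording written by :func:`write_recording`."""
    samples, fs = read_wav(wav_path)
    meta = {}
    truth = []
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        truth = [EmissionSpec(**e) for e in meta.get("truth", [])]
    return EarCanalRecording(
        samples=samples,
        fs=int(meta.get("fs", fs)),
        trial_id=meta.get("trial_id", ""),
        condition_label=meta.get("condition_label", ""),
        participant_id=meta.get("participant_id", ""),
        truth=truth,
    )
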