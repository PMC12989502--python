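"""Fundamental-frequency tracking and extraction of the fundamental waveform.

Voiced speech is quasi-periodic: its spectrum consists of harmonics of a
slowly varying fundamental frequency f0(t). This module estimates f0(t) with
a YIN-style difference-function tracker with explicit per-frame voicing
decisions, summarizes the voiced-frame statistics (mean and SD of f0), and
isolates the *fundamental waveform* w0(t) — the source bandpass-filtered to
a narrow band around the mean f0 with a zero-phase (forward-backward) IIR
filter and normalized by z-scoring. w0(t) follows the instantaneous
frequency of the voice during voiced stretches and decays to zero during
pauses and voiceless segments; it is the seed from which all harmonic
elicitor waveforms are built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import FilterDesignError, UnvoicedInputError


@dataclass
class SourceSignal:
    """A voiced source waveform (e.g., synthesized speech).

    samples are dimensionless digital full-scale amplitudes; ``label`` is a
    free-text identifier such as "female" or "male".
    """

    samples: np.ndarray
    fs: int
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("SourceSignal requires a mono (1-D) waveform")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("source samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class F0Track:
    """Frame-wise fundamental-frequency estimates with a voicing mask.

    ``f0`` is NaN on unvoiced frames; ``times`` (s) are strictly increasing
    frame centers.
    """

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (len(self.times) == len(self.f0) == len(self.voiced)):
            raise ValueError("times, f0 and voiced must be equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(~(self.f0[self.voiced] > 0)):
            raise ValueError("voiced frames must carry positive f0")

    def to_table(self) -> "np.ndarray":
        """Tabular (time, f0, voiced) view for text export."""
        return np.column_stack([self.times, self.f0, self.voiced.astype(float)])


@dataclass
class F0Stats:
    """Mean and standard deviation of f0 over voiced frames."""

    mean_f0: float
    sd_f0: float

    def __post_init__(self):
        if not self.mean_f0 > 0:
            raise ValueError("mean f0 must be positive")
        if self.sd_f0 < 0:
            raise ValueError("f0 SD cannot be negative")


@dataclass
class FundamentalWaveform:
    """The z-scored fundamental waveform w0(t)."""

    samples: np.ndarray
    fs: int
    source_label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


def _difference_function(frames: np.ndarray, window: int, tau_max: int) -> np.ndarray:
    """YIN difference function d(tau) for a batch of frames.

    d(tau) = sum_{j<window} (x_j - x_{j+tau})^2, computed via FFT
    cross-correlation; frames must be at least window + tau_max long.
    """
    n_frames, frame_len = frames.shape
    nfft = 1 << int(np.ceil(np.log2(frame_len + window)))
    spec_full = np.fft.rfft(frames, nfft)
    spec_head = np.fft.rfft(frames[:, :window], nfft)
    cross = np.fft.irfft(spec_full * np.conj(spec_head), nfft)[:, : tau_max + 1]
    sq = np.cumsum(np.square(frames), axis=1)
    sq = np.concatenate([np.zeros((n_frames, 1)), sq], axis=1)
    head_energy = sq[:, window][:, None]
    taus = np.arange(tau_max + 1)
    lag_energy = sq[:, taus + window] - sq[:, taus]
    return head_energy + lag_energy - 2.0 * cross


def _cmndf(d: np.ndarray) -> np.ndarray:
    """Cumulative-mean-normalized difference function; d'(0) = 1."""
    taus = np.arange(1, d.shape[1])
    running = np.cumsum(d[:, 1:], axis=1)
    out = np.ones_like(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[:, 1:] = np.where(running > 0, d[:, 1:] * taus / running, 1.0)
    return out


def estimate_f0(
    source: SourceSignal,
    fmin: float = 65.0,
    fmax: float = 400.0,
    frame_length: int = 2048,
    hop_length: int = 512,
    threshold: float = 0.15,
    voicing_threshold: float = 0.35,
    silence_rel: float = 0.02,
) -> F0Track:
    """Track f0(t) with a YIN-style estimator and explicit voicing decisions.

    Per frame, the cumulative-mean-normalized difference function is
    searched over periods in [fs/fmax, fs/fmin]; the first dip below
    ``threshold`` (refined to its local minimum and by parabolic
    interpolation) gives the period. A frame is voiced when that dip is
    deeper than ``voicing_threshold`` and the frame is not silent relative
    to the loudest frame (``silence_rel``).

    Raises UnvoicedInputError when no frame is voiced.
    """
    if fmin >= fmax:
        raise ValueError("invalid range: fmin must be below fmax")
    if fmin <= 40.0:
        raise ValueError("fmin must be above 40 Hz")
    x = source.samples
    fs = source.fs
    if x.size < fs:
        raise ValueError("source must be at least 1 s long for f0 statistics")
    window = frame_length // 2
    tau_min = max(2, int(fs / fmax))
    tau_max = int(np.ceil(fs / fmin))
    if tau_max > frame_length - window:
        raise ValueError(
            f"fmin={fmin} Hz needs a period of {tau_max} samples, exceeding "
            f"the {frame_length - window}-sample search span of "
            f"frame_length={frame_length}; increase frame_length or fmin"
        )

    starts = np.arange(0, x.size - frame_length + 1, hop_length)
    frames = np.lib.stride_tricks.sliding_window_view(x, frame_length)[starts]
    frame_rms = np.sqrt(np.mean(np.square(frames[:, :window]), axis=1))
    silence_floor = silence_rel * max(frame_rms.max(), np.finfo(float).tiny)

    f0 = np.full(starts.size, np.nan)
    voiced = np.zeros(starts.size, dtype=bool)
    chunk = 2048
    for lo in range(0, starts.size, chunk):
        hi = min(lo + chunk, starts.size)
        d = _difference_function(frames[lo:hi], window, tau_max)
        dprime = _cmndf(d)
        for i in range(hi - lo):
            seg = dprime[i, tau_min : tau_max + 1]
            below = np.flatnonzero(seg < threshold)
            if below.size:
                t = int(below[0])
                while t + 1 < seg.size and seg[t + 1] < seg[t]:
                    t += 1
            else:
                t = int(np.argmin(seg))
            depth = seg[t]
            if depth >= voicing_threshold or frame_rms[lo + i] < silence_floor:
                continue
            tau = tau_min + t
            # parabolic interpolation of the dip for sub-sample period
            if 0 < tau < tau_max:
                a, b, c = dprime[i, tau - 1], dprime[i, tau], dprime[i, tau + 1]
                denom = a - 2 * b + c
                if denom > 0:
                    tau = tau + 0.5 * (a - c) / denom
            f0[lo + i] = fs / tau
            voiced[lo + i] = True

    if not voiced.any():
        raise UnvoicedInputError("unvoiced input: no voiced frames found")
    times = (starts + frame_length / 2) / fs
    return F0Track(times=times, f0=f0, voiced=voiced)


def f0_stats(track: F0Track) -> F0Stats:
    """Mean and population SD of f0 over voiced frames only."""
    vals = track.f0[track.voiced]
    if vals.size == 0:
        raise UnvoicedInputError("unvoiced input: no voiced frames in track")
    return F0Stats(mean_f0=float(np.mean(vals)), sd_f0=float(np.std(vals)))


def extract_fundamental(
    source: SourceSignal,
    stats: F0Stats,
    order: int = 6,
    order_convention: str = "one_pass",
    min_half_bandwidth: float = 5.0,
    zscore: bool = True,
) -> FundamentalWaveform:
    """Isolate the fundamental waveform w0(t).

    The source is bandpass-filtered with a zero-phase (forward-backward)
    Butterworth filter whose passband is mean_f0 ± 0.5·sd_f0 and z-scored.
    ``order`` counts the poles of the one-pass bandpass when
    ``order_convention`` is "one_pass" (the default; the forward-backward
    cascade then has twice that order); with "combined" the cascade itself
    is kept at approximately ``order`` poles.

    A degenerate band (sd_f0 = 0, e.g. a pure-tone source) is widened to
    ± ``min_half_bandwidth`` Hz with a warning.
    """
    half_bw = 0.5 * stats.sd_f0
    if half_bw < min_half_bandwidth:
        warnings.warn(
            f"f0 band ±{half_bw:.2f} Hz is narrower than the minimum "
            f"half-bandwidth; widening to ±{min_half_bandwidth:.1f} Hz",
            stacklevel=2,
        )
        half_bw = min_half_bandwidth
    lo = stats.mean_f0 - half_bw
    hi = stats.mean_f0 + half_bw
    if lo <= 0:
        raise ValueError("lower corner frequency must be positive")
    if hi >= source.fs / 2:
        raise FilterDesignError("upper corner frequency exceeds Nyquist")
    if order_convention == "one_pass":
        design_n = max(1, order // 2)
    elif order_convention == "combined":
        design_n = max(1, order // 4)
    else:
        raise ValueError("order_convention must be 'one_pass' or 'combined'")
    try:
        sos = butter(design_n, [lo, hi], btype="bandpass", fs=source.fs, output="sos")
    except ValueError as exc:  # pragma: no cover - scipy validates corners
        raise FilterDesignError(str(exc)) from exc
    y = sosfiltfilt(sos, source.samples)
    if zscore:
        sd = np.std(y)
        if sd == 0:
            raise FilterDesignError("filtered output is identically zero")
        y = (y - np.mean(y)) / sd
    return FundamentalWaveform(samples=y, fs=source.fs, source_label=source.label)


def track_to_text(track: F0Track, path) -> None:
    """Write an F0Track as a three-column (time, f0, voiced) text table."""
    np.savetxt(
        path,
        track.to_table(),
        header="time_s\tf0_hz\tvoiced",
        fmt=["%.6f", "%.4f", "%d"],
        delimiter="\t",
        comments="",
    )
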