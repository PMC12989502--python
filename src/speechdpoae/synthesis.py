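"""Harmonic elicitor and distortion-product waveform construction.

Two elicitor tones with instantaneous frequencies n·f0(t) and m·f0(t)
(n < m) drive the cochlear nonlinearity to produce the lower-sideband cubic
distortion product at (2n−m)·f0(t). All three waveforms are built from one
analytic representation of the fundamental waveform,

    W0(t) = w0(t) + i·H[w0(t)] = A(t)·exp(iΦ(t)),

by multiplying the instantaneous phase Φ(t) by the harmonic number and
keeping the amplitude envelope A(t):  w_k(t) = Re[A(t)·exp(i·k·Φ(t))].
The envelope — and hence the silence pattern of the voice — is therefore
identical across all harmonics of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .audio import rms
from .errors import DegenerateAmplitudeError
from .fundamental import FundamentalWaveform

#: digital-RMS -> dB SPL calibration anchor: a waveform of RMS 2.0e-3
#: corresponds to 37 dB SPL at the default presentation level.
SPL_REFERENCE_RMS = 2.0e-3
SPL_REFERENCE_DB = 37.0


@dataclass
class AnalyticWaveform:
    """Amplitude/phase decomposition of a real waveform.

    ``phase`` is unwrapped so that multiplying it by a harmonic number does
    not introduce wrap-point discontinuities. ``real`` retains the (edge
    tapered) real waveform the decomposition was computed from;
    Re[A·exp(iΦ)] reconstructs it to numerical precision.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    fs: int
    real: np.ndarray = field(repr=False, default=None)

    @property
    def imag(self) -> np.ndarray:
        return self.amplitude * np.sin(self.phase)

    def reconstruct(self) -> np.ndarray:
        return self.amplitude * np.cos(self.phase)


def _edge_taper(n: int, fs: int, taper_s: float) -> np.ndarray:
    """Raised-cosine on/off ramps over the first and last ``taper_s`` seconds."""
    ramp_n = min(int(round(taper_s * fs)), n // 2)
    env = np.ones(n)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = ramp
        env[-ramp_n:] = ramp[::-1]
    return env


def analytic(w: FundamentalWaveform, edge_taper_s: float = 0.05) -> AnalyticWaveform:
    """Analytic representation (Hilbert transform) of the fundamental waveform.

    End transients of the discrete Hilbert transform corrupt amplitude and
    phase near the edges, so the first and last ``edge_taper_s`` seconds are
    tapered with a raised cosine before analysis.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size < 2:
        raise ValueError("waveform must contain at least two samples")
    if not np.any(x):
        raise DegenerateAmplitudeError("degenerate amplitude: all-zero waveform")
    x = x * _edge_taper(x.size, w.fs, edge_taper_s)
    z = hilbert(x)
    return AnalyticWaveform(
        amplitude=np.abs(z),
        phase=np.unwrap(np.angle(z)),
        fs=w.fs,
        real=x,
    )


def harmonic_waveform(aw: AnalyticWaveform, k: int) -> np.ndarray:
    """k-th harmonic waveform Re[A(t)·exp(i·k·Φ(t))].

    k = 1 reproduces the analyzed waveform; the amplitude envelope is A(t)
    for every k, so voiceless stretches stay silent in all harmonics.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("invalid harmonic number: k must be a positive integer")
    return aw.amplitude * np.cos(k * aw.phase)


def instantaneous_frequency(x: np.ndarray, fs: int) -> np.ndarray:
    """Instantaneous frequency (Hz) of a real waveform via its analytic phase."""
    phase = np.unwrap(np.angle(hilbert(np.asarray(x, dtype=float))))
    return np.gradient(phase) * fs / (2 * np.pi)


@dataclass
class HarmonicPairSpec:
    """Harmonic numbers (n, m) of an elicitor pair.

    The lower-sideband cubic distortion product sits at harmonic 2n−m;
    distortion generation is strongest near frequency ratios m/n ≈ 1.2.
    """

    n: int
    m: int
    voice_label: str = ""
    resolvability: str = "resolved"

    def __post_init__(self):
        if not (1 <= self.n < self.m):
            raise ValueError("harmonic numbers must satisfy 1 <= n < m")
        if 2 * self.n - self.m < 1:
            raise ValueError("distortion-product index 2n-m must be >= 1")
        if self.resolvability not in ("resolved", "unresolved"):
            raise ValueError("resolvability must be 'resolved' or 'unresolved'")

    def dp_index(self) -> int:
        return 2 * self.n - self.m

    def ratio(self) -> float:
        return self.m / self.n

    @property
    def label(self) -> str:
        return f"{self.voice_label}_{self.resolvability}" if self.voice_label else f"pair_{self.n}_{self.m}"


@dataclass
class StimulusPair:
    """Elicitor waveforms w_n, w_m and the expected emission waveform w_dp."""

    spec: HarmonicPairSpec
    w_n: np.ndarray
    w_m: np.ndarray
    w_dp: np.ndarray
    fs: int

    def __post_init__(self):
        if not (len(self.w_n) == len(self.w_m) == len(self.w_dp)):
            raise ValueError("pair waveforms must be equally long")


def make_pair(w0: FundamentalWaveform, spec: HarmonicPairSpec,
              edge_taper_s: float = 0.05) -> StimulusPair:
    """Build elicitors and expected DP waveform from one analytic decomposition."""
    aw = analytic(w0, edge_taper_s=edge_taper_s)
    return StimulusPair(
        spec=spec,
        w_n=harmonic_waveform(aw, spec.n),
        w_m=harmonic_waveform(aw, spec.m),
        w_dp=harmonic_waveform(aw, spec.dp_index()),
        fs=w0.fs,
    )


def normalize_rms(w: np.ndarray, target_rms: float) -> np.ndarray:
    """Scale a waveform to an exact RMS amplitude."""
    r = rms(w)
    if r == 0:
        raise DegenerateAmplitudeError("degenerate amplitude: silent waveform")
    return np.asarray(w, dtype=float) * (target_rms / r)


def level_to_rms(level_db: float, reference_rms: float = SPL_REFERENCE_RMS,
                 reference_db: float = SPL_REFERENCE_DB) -> float:
    """Digital RMS corresponding to a sound pressure level under the calibration anchor."""
    return reference_rms * 10.0 ** ((level_db - reference_db) / 20.0)


@dataclass
class StimulusSet:
    """A roster of stimulus pairs with the two summed presentation channels.

    W1 sums all lower-harmonic waveforms w_n, W2 all higher-harmonic
    waveforms w_m; the two channels are played through separate speakers so
    that hardware distortion cannot mimic the emission. ``level_target`` is
    the calibration metadata (dB SPL) the joint channel RMS was mapped to.
    """

    pairs: list
    W1: np.ndarray
    W2: np.ndarray
    fs: int
    level_target: float
    metadata: dict = field(default_factory=dict)


def assemble_set(
    pairs: list,
    level_target: float = SPL_REFERENCE_DB,
    reference_rms: float = SPL_REFERENCE_RMS,
    reference_db: float = SPL_REFERENCE_DB,
) -> StimulusSet:
    """Sum pairs into the two presentation channels and calibrate the level.

    Pairs of unequal length are zero-padded at the tail (recorded in
    metadata). A single scalar maps the combined-channel RMS to
    ``level_target`` under the digital-RMS/SPL anchor; the scalar is applied
    to the member pairs as well so the channel sums remain exact.
    """
    if not pairs:
        raise ValueError("assemble_set requires at least one pair")
    fs = pairs[0].fs
    if any(p.fs != fs for p in pairs):
        raise ValueError("mixed sampling rates in stimulus set")
    n_max = max(len(p.w_n) for p in pairs)
    padded = []
    pad_counts = []
    for p in pairs:
        pad = n_max - len(p.w_n)
        pad_counts.append(pad)
        if pad:
            p = StimulusPair(
                spec=p.spec,
                w_n=np.pad(p.w_n, (0, pad)),
                w_m=np.pad(p.w_m, (0, pad)),
                w_dp=np.pad(p.w_dp, (0, pad)),
                fs=p.fs,
            )
        padded.append(p)
    W1 = np.sum([p.w_n for p in padded], axis=0)
    W2 = np.sum([p.w_m for p in padded], axis=0)
    combined_rms = rms(W1 + W2)
    if combined_rms == 0:
        raise DegenerateAmplitudeError("degenerate amplitude: silent stimulus set")
    scale = level_to_rms(level_target, reference_rms, reference_db) / combined_rms
    calibrated = [
        StimulusPair(spec=p.spec, w_n=p.w_n * scale, w_m=p.w_m * scale,
                     w_dp=p.w_dp * scale, fs=p.fs)
        for p in padded
    ]
    W1 = np.sum([p.w_n for p in calibrated], axis=0)
    W2 = np.sum([p.w_m for p in calibrated], axis=0)
    return StimulusSet(
        pairs=calibrated,
        W1=W1,
        W2=W2,
        fs=fs,
        level_target=level_target,
        metadata={"pad_samples": pad_counts, "calibration_scale": scale},
    )


@dataclass
class PureToneSpec:
    """Primary frequencies for a classic two-tone distortion product."""

    f1: float
    f2: float

    def __post_init__(self):
        ratio = self.f2 / self.f1
        if not (1.1 <= ratio <= 1.3):
            raise ValueError("f2/f1 must lie within [1.1, 1.3]")
        if 2 * self.f1 - self.f2 <= 0:
            raise ValueError("distortion frequency 2*f1-f2 must be positive")

    @property
    def dp_frequency(self) -> float:
        return 2 * self.f1 - self.f2


@dataclass
class PureTonePair:
    """Constant-frequency analogue of a StimulusPair (w_dp at 2·f1−f2)."""

    spec: PureToneSpec
    w_n: np.ndarray
    w_m: np.ndarray
    w_dp: np.ndarray
    fs: int


def pure_tone_pair(spec: PureToneSpec, duration: float, fs: int,
                   amplitude: float = 1.0) -> PureTonePair:
    """Sinusoidal primaries f1, f2 and the expected 2·f1−f2 distortion tone."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    return PureTonePair(
        spec=spec,
        w_n=amplitude * np.sin(2 * np.pi * spec.f1 * t),
        w_m=amplitude * np.sin(2 * np.pi * spec.f2 * t),
        w_dp=amplitude * np.sin(2 * np.pi * spec.dp_frequency * t),
        fs=fs,
    )
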