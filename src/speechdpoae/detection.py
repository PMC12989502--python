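"""Detection of speech-like distortion-product emissions in recordings.

The emission is buried far below the elicitors and the microphone noise, but
its waveform is known in advance: the (2n−m)-th harmonic waveform
constructed alongside the stimulus. Detection is therefore template
matching by *complex* cross-correlation — the recording is correlated with
both the real and the imaginary part of the analytic representation of the
expected DP waveform, and the modulus (envelope) of the resulting complex
correlation is phase-blind: a constant phase offset between the true
emission and the constructed template rotates the complex correlation but
leaves its envelope unchanged.

Significance is assessed against the envelope's own noise floor, taken at
lags far from any plausible emission delay ([−750, −70] and [+70, +750] ms):
per-trial peaks (searched within 1 ± 3 ms) must exceed the 97th percentile
of the noise values; grand-average peaks must exceed their maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, hilbert

from .audio import rms
from .errors import DegenerateAmplitudeError, NoStimulusLockError
from .simulate import EarCanalRecording

#: lag windows (ms) over which the noise floor is estimated
NOISE_WINDOWS_MS = ((-750.0, -70.0), (70.0, 750.0))
#: per-trial peak search window (ms): expected delay 1 ms ± 3 ms SD
PEAK_WINDOW_MS = (-2.0, 4.0)
#: default lag coverage (ms)
LAG_RANGE_MS = (-750.0, 750.0)
NOISE_PERCENTILE = 97.0


@dataclass
class ComplexCorrelogram:
    """Complex lagged correlation of a recording against a DP template.

    ``values[k]`` is the correlation at lag ``lags_ms[k]``; its real part
    correlates the recording with the real component of the template's
    analytic representation, the imaginary part with the imaginary
    component. ``template_norm`` is the L2 norm of the (real) template, so
    that in "matched" normalization an embedded emission of linear gain g
    produces an envelope peak of about g·template_norm.
    """

    lags_ms: np.ndarray
    values: np.ndarray
    fs: int
    dp_index: int = 0
    trial_id: str = ""
    condition_label: str = ""
    participant_id: str = ""
    stimulus_label: str = ""
    template_norm: float = 1.0
    mode: str = "matched"

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def max_lag_ms(self) -> float:
        return float(min(-self.lags_ms[0], self.lags_ms[-1]))


@dataclass
class NoiseStats:
    """Noise-floor statistics of a correlogram envelope."""

    noise_max: float
    noise_p97: float
    window_definition: tuple = NOISE_WINDOWS_MS


@dataclass
class DPOAEPeak:
    """A detected (or absent) emission peak."""

    delay_ms: float
    amplitude: float
    significant: bool
    criterion: str  # "trial_p97" or "grand_average_max"
    search_window: tuple
    diagnostics: str = ""


def _lagged_correlation(rec: np.ndarray, template: np.ndarray,
                        lag_lo: int, lag_hi: int) -> np.ndarray:
    """c(l) = sum_t rec[t + l] * template[t] for l in [lag_lo, lag_hi]."""
    full = fftconvolve(rec, template[::-1])
    center = len(template) - 1
    return full[center + lag_lo: center + lag_hi + 1]


def _overlap_sums(sq_cumsum: np.ndarray, lags: np.ndarray, n: int, side: str) -> np.ndarray:
    """Sum of squares over the lag-dependent overlap of one signal.

    For lag l >= 0 the template overlap is [0, n-l) and the recording
    overlap is [l, n); for l < 0 they swap.
    """
    out = np.empty(lags.size)
    pos = lags >= 0
    if side == "template":
        out[pos] = sq_cumsum[n - lags[pos]]
        out[~pos] = sq_cumsum[n] - sq_cumsum[-lags[~pos]]
    else:
        out[pos] = sq_cumsum[n] - sq_cumsum[lags[pos]]
        out[~pos] = sq_cumsum[n + lags[~pos]]
    return out


def complex_xcorr(
    rec: EarCanalRecording,
    w_dp: np.ndarray,
    lag_range_ms: tuple = LAG_RANGE_MS,
    mode: str = "matched",
    dp_index: int = 0,
    stimulus_label: str = "",
) -> ComplexCorrelogram:
    """Complex cross-correlation of a recording with a DP waveform.

    Both signals are de-meaned. Per lag, the correlation against the real
    and imaginary template components is divided by the template's L2 norm
    over the overlap ("matched" mode: the envelope stays in recording
    amplitude units and is linear in emission gain), or additionally by the
    recording's overlap norm ("pearson" mode: a dimensionless correlation
    coefficient). The lag grid is one sample.

    If the recording is too short for the requested lag range, the range is
    shrunk to 45% of the recording length with a warning.
    """
    w_dp = np.asarray(w_dp, dtype=float)
    if rms(w_dp) == 0:
        raise DegenerateAmplitudeError("degenerate amplitude: silent DP waveform")
    if mode not in ("matched", "pearson"):
        raise ValueError("mode must be 'matched' or 'pearson'")
    fs = rec.fs
    r = rec.samples - np.mean(rec.samples)
    n = min(len(r), len(w_dp))
    r = r[:n]
    z = hilbert(w_dp[:n])
    u = np.real(z) - np.mean(np.real(z))
    v = np.imag(z) - np.mean(np.imag(z))

    lag_lo = int(np.floor(lag_range_ms[0] * fs / 1000.0))
    lag_hi = int(np.ceil(lag_range_ms[1] * fs / 1000.0))
    limit = int(0.45 * n)
    if lag_hi > limit or -lag_lo > limit:
        warnings.warn(
            f"recording of {n / fs:.2f} s is too short for lags "
            f"{lag_range_ms} ms; shrinking lag coverage proportionally",
            stacklevel=2,
        )
        lag_lo, lag_hi = -limit, limit
    lags = np.arange(lag_lo, lag_hi + 1)

    c_real = _lagged_correlation(r, u, lag_lo, lag_hi)
    c_imag = _lagged_correlation(r, v, lag_lo, lag_hi)

    # joint template power over the overlap (u and v carry equal power up
    # to edge effects; a common normalizer keeps the envelope phase-blind)
    t_sq = np.concatenate([[0.0], np.cumsum(0.5 * (u * u + v * v))])
    t_norm = np.sqrt(np.maximum(_overlap_sums(t_sq, lags, n, "template"), np.finfo(float).tiny))
    denom = t_norm
    if mode == "pearson":
        r_sq = np.concatenate([[0.0], np.cumsum(r * r)])
        r_norm = np.sqrt(np.maximum(_overlap_sums(r_sq, lags, n, "recording"),
                                    np.finfo(float).tiny))
        denom = t_norm * r_norm
    values = (c_real + 1j * c_imag) / denom
    return ComplexCorrelogram(
        lags_ms=lags * 1000.0 / fs,
        values=values,
        fs=fs,
        dp_index=dp_index,
        trial_id=rec.trial_id,
        condition_label=rec.condition_label,
        participant_id=rec.participant_id,
        stimulus_label=stimulus_label,
        template_norm=float(np.linalg.norm(u)),
        mode=mode,
    )


def _scaled_windows(cg_max_lag: float, windows) -> tuple:
    """Shrink noise windows proportionally when lag coverage is reduced."""
    outer = max(abs(b) for w in windows for b in w)
    if cg_max_lag >= outer:
        return tuple(tuple(w) for w in windows)
    factor = cg_max_lag / outer
    warnings.warn(
        f"lag coverage ±{cg_max_lag:.0f} ms below ±{outer:.0f} ms; "
        "scaling noise windows proportionally",
        stacklevel=3,
    )
    return tuple((w[0] * factor, w[1] * factor) for w in windows)


def noise_floor(cg: ComplexCorrelogram, windows=NOISE_WINDOWS_MS,
                percentile: float = NOISE_PERCENTILE) -> NoiseStats:
    """Envelope noise statistics over the far-lag windows.

    Returns the maximum and the (linear-interpolation) 97th percentile of
    the envelope restricted to the two windows.
    """
    windows = _scaled_windows(cg.max_lag_ms, tuple(tuple(w) for w in windows))
    env = cg.envelope
    mask = np.zeros(env.size, dtype=bool)
    for lo, hi in windows:
        mask |= (cg.lags_ms >= lo) & (cg.lags_ms <= hi)
    if not mask.any():
        raise ValueError("insufficient lag coverage for the noise windows")
    vals = env[mask]
    return NoiseStats(
        noise_max=float(vals.max()),
        noise_p97=float(np.percentile(vals, percentile)),
        window_definition=windows,
    )


def detect_trial_peak(cg: ComplexCorrelogram, ns: NoiseStats,
                      window_ms: tuple = PEAK_WINDOW_MS) -> DPOAEPeak:
    """Largest envelope value within the expected-delay window of one trial.

    Significant iff the peak exceeds the 97th percentile of the noise. Ties
    resolve to the smallest lag. Energy exceeding the threshold between the
    noise windows but outside the search window is flagged in diagnostics.
    """
    mask = (cg.lags_ms >= window_ms[0]) & (cg.lags_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("search window outside lag coverage")
    env = cg.envelope
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(env[idx])]
    amp = float(env[best])
    noise_lo = min(abs(b) for w in ns.window_definition for b in w)
    near = (np.abs(cg.lags_ms) < noise_lo) & ~mask
    diagnostics = ""
    if near.any() and env[near].max() > ns.noise_p97 and env[near].max() > amp:
        diagnostics = "out-of-window energy"
    return DPOAEPeak(
        delay_ms=float(cg.lags_ms[best]),
        amplitude=amp,
        significant=bool(amp > ns.noise_p97),
        criterion="trial_p97",
        search_window=tuple(window_ms),
        diagnostics=diagnostics,
    )


def grand_average(cgs: list, window_ms: tuple = PEAK_WINDOW_MS,
                  noise_windows=NOISE_WINDOWS_MS):
    """Average correlogram envelopes and test the peak against the noise max.

    Returns (lags_ms, averaged_envelope, DPOAEPeak, NoiseStats). The peak is
    significant iff it exceeds the maximum of the averaged envelope over the
    noise windows.
    """
    if not cgs:
        raise ValueError("grand_average requires at least one correlogram")
    lags = cgs[0].lags_ms
    for cg in cgs[1:]:
        if cg.lags_ms.size != lags.size or not np.allclose(cg.lags_ms, lags):
            raise ValueError("mismatched lag grids in grand average")
    avg = np.mean([cg.envelope for cg in cgs], axis=0)
    ref = ComplexCorrelogram(lags_ms=lags, values=avg.astype(complex), fs=cgs[0].fs)
    ns = noise_floor(ref, windows=noise_windows)
    mask = (lags >= window_ms[0]) & (lags <= window_ms[1])
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(avg[idx])]
    peak = DPOAEPeak(
        delay_ms=float(lags[best]),
        amplitude=float(avg[best]),
        significant=bool(avg[best] > ns.noise_max),
        criterion="grand_average_max",
        search_window=tuple(window_ms),
    )
    return lags, avg, peak, ns


def grand_averages(cgs: list, keys: list, **kwargs) -> dict:
    """Grand averages per group; ``keys`` aligns one hashable key per correlogram."""
    if len(cgs) != len(keys):
        raise ValueError("one group key per correlogram required")
    groups = {}
    for cg, key in zip(cgs, keys):
        groups.setdefault(key, []).append(cg)
    return {key: grand_average(members, **kwargs) for key, members in groups.items()}


def detection_rate(peaks: list, group_keys: list) -> pd.Series:
    """Percentage of significant per-trial peaks per group."""
    if not peaks:
        raise ValueError("detection_rate requires at least one peak")
    if len(peaks) != len(group_keys):
        raise ValueError("one group key per peak required")
    df = pd.DataFrame({
        "group": group_keys,
        "significant": [p.significant for p in peaks],
    })
    return df.groupby("group")["significant"].mean() * 100.0


def amplitude_at(cg: ComplexCorrelogram, delay_ms: float) -> float:
    """Envelope value at the lag sample nearest to ``delay_ms``."""
    idx = int(np.argmin(np.abs(cg.lags_ms - delay_ms)))
    return float(cg.envelope[idx])


def estimate_hardware_delay(rec: EarCanalRecording, stimuli,
                            search_ms: float = 50.0,
                            min_lock: float = 0.1) -> float:
    """Hardware delay (ms) from the stimulus leak-through in the recording.

    Cross-correlates the combined stimulus channels W1 + W2 with the
    recording (Pearson-normalized, so the lock criterion is a correlation
    coefficient) and returns the lag of the envelope maximum. Raises
    NoStimulusLockError if the maximum coefficient stays below ``min_lock``.
    """
    stim = stimuli.W1 + stimuli.W2
    cg = complex_xcorr(rec, stim, lag_range_ms=(-search_ms, search_ms), mode="pearson")
    env = cg.envelope
    best = int(np.argmax(env))
    if env[best] < min_lock:
        raise NoStimulusLockError(
            f"no stimulus lock: peak correlation {env[best]:.3f} < {min_lock}"
        )
    return float(cg.lags_ms[best])


def correct_delay(rec: EarCanalRecording, delay_ms: float) -> EarCanalRecording:
    """Shift a recording earlier by ``delay_ms`` (undo the hardware delay)."""
    n = int(round(delay_ms * rec.fs / 1000.0))
    out = np.zeros_like(rec.samples)
    if n >= 0:
        if n < rec.samples.size:
            out[: rec.samples.size - n] = rec.samples[n:]
    else:
        if -n < rec.samples.size:
            out[-n:] = rec.samples[: rec.samples.size + n]
    return EarCanalRecording(
        samples=out,
        fs=rec.fs,
        trial_id=rec.trial_id,
        condition_label=rec.condition_label,
        participant_id=rec.participant_id,
        truth=rec.truth,
    )
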