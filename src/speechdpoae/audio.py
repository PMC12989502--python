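"""Mono WAV input/output and basic amplitude utilities.

All waveforms in this package are 1-D float64 arrays in digital full scale
(values nominally within [-1, 1]); sampling rates are in Hz.
"""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_FS = 44_100


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a waveform."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(np.square(x))))


def read_wav(path, target_fs: int | None = None, resample: bool = True):
    """Read a mono WAV file as (samples, fs) with float64 samples.

    Integer PCM is rescaled to [-1, 1]. Multi-channel files are averaged to
    mono. If ``target_fs`` is given and differs from the file rate, the
    signal is resampled (polyphase) unless ``resample`` is False, in which
    case a ValueError is raised.
    """
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if target_fs is not None and fs != target_fs:
        if not resample:
            raise ValueError(
                f"sampling rate {fs} Hz does not match required {target_fs} Hz "
                "and resampling is disabled"
            )
        g = np.gcd(int(target_fs), int(fs))
        data = resample_poly(data, int(target_fs) // g, int(fs) // g)
        fs = int(target_fs)
    return data, int(fs)


def write_wav(path, samples: np.ndarray, fs: int) -> None:
    """Write a mono float32 WAV file."""
    wavfile.write(path, int(fs), np.asarray(samples, dtype=np.float32))
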