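"""Shared fixtures: small seeded synthetic sources and stimulus sets.

Desk-scale trials are a few seconds long; the lag and noise windows scale
with the trial as needed, so every fixture here is generated at test time.
"""

import numpy as np
import pytest

from speechdpoae import (
    HarmonicPairSpec, VoicedSourceSpec, assemble_set, estimate_f0,
    extract_fundamental, f0_stats, make_pair, synth_voiced_source,
)

FS = 44_100


def build_stimulus(duration: float, seed: int = 7, n: int = 7, m: int = 9):
    """Female-like source -> fundamental -> single (n, m) stimulus set."""
    spec = VoicedSourceSpec(duration=duration, mean_f0=195.0, sd_f0=40.0, seed=seed)
    source = synth_voiced_source(spec)
    track = estimate_f0(source, fmin=100.0, fmax=350.0)
    w0 = extract_fundamental(source, f0_stats(track))
    pair = make_pair(w0, HarmonicPairSpec(n, m, "female", "resolved"))
    return source, w0, assemble_set([pair])


@pytest.fixture(scope="session")
def female_source():
    spec = VoicedSourceSpec(duration=20.0, mean_f0=195.0, sd_f0=40.0, seed=7)
    return synth_voiced_source(spec)


@pytest.fixture(scope="session")
def female_track(female_source):
    return estimate_f0(female_source, fmin=100.0, fmax=350.0)


@pytest.fixture(scope="session")
def female_w0(female_source, female_track):
    return extract_fundamental(female_source, f0_stats(female_track))


@pytest.fixture(scope="session")
def fres_pair(female_w0):
    return make_pair(female_w0, HarmonicPairSpec(7, 9, "female", "resolved"))


@pytest.fixture(scope="session")
def small_stimulus():
    """4 s single-pair stimulus set for simulation/detection tests."""
    return build_stimulus(4.0)[2]


@pytest.fixture(scope="session")
def tiny_stimulus():
    """2 s single-pair stimulus set for Monte-Carlo suites."""
    return build_stimulus(2.0)[2]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
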