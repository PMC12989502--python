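"""Run configuration: every tunable constant of the pipeline in one place.

Defaults reproduce the published measurement conditions: the four-pair
harmonic roster, 44.1 kHz sampling, the 2.0e-3 digital-RMS source
convention mapped to 37 dB SPL, the ±70–750 ms noise windows with the 97th
percentile criterion, and the 1 ± 3 ms ([−2, +4] ms) peak-delay window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .synthesis import HarmonicPairSpec


def default_roster() -> list:
    """The four-pair stimulus roster (female/male × resolved/unresolved)."""
    return [
        {"n": 7, "m": 9, "voice": "female", "resolvability": "resolved"},
        {"n": 15, "m": 18, "voice": "female", "resolvability": "unresolved"},
        {"n": 6, "m": 8, "voice": "male", "resolvability": "resolved"},
        {"n": 15, "m": 18, "voice": "male", "resolvability": "unresolved"},
    ]


@dataclass
class RunConfig:
    fs: int = 44_100
    roster: list = field(default_factory=default_roster)

    # f0 tracking
    f0_fmin: float = 65.0
    f0_fmax: float = 400.0
    frame_length: int = 2048
    hop_length: int = 512

    # fundamental-waveform filter
    filter_order: int = 6
    order_convention: str = "one_pass"  # or "combined"
    min_half_bandwidth_hz: float = 5.0

    # levels
    source_rms: float = 2.0e-3
    level_target_db: float = 37.0
    spl_reference_rms: float = 2.0e-3
    spl_reference_db: float = 37.0

    # detection
    lag_range_ms: list = field(default_factory=lambda: [-750.0, 750.0])
    noise_windows_ms: list = field(
        default_factory=lambda: [[-750.0, -70.0], [70.0, 750.0]])
    noise_percentile: float = 97.0
    peak_window_ms: list = field(default_factory=lambda: [-2.0, 4.0])
    xcorr_mode: str = "matched"
    hardware_delay_search_ms: float = 50.0
    min_stimulus_lock: float = 0.1

    # trials
    trial_duration_s: float = 120.0
    resample_inputs: bool = True

    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        for entry in self.roster:
            HarmonicPairSpec(
                n=int(entry["n"]), m=int(entry["m"]),
                voice_label=entry.get("voice", ""),
                resolvability=entry.get("resolvability", "resolved"),
            )

    def pair_specs(self) -> list:
        return [
            HarmonicPairSpec(
                n=int(e["n"]), m=int(e["m"]),
                voice_label=e.get("voice", ""),
                resolvability=e.get("resolvability", "resolved"),
            )
            for e in self.roster
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
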