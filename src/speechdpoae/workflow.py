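"""End-to-end runs: synthesize stimuli, simulate a cohort, detect, contrast.

These functions tie the stages together behind a RunConfig so that a single
seeded call reproduces a complete desk-scale experiment: voiced sources →
fundamental waveforms → harmonic stimulus set → simulated ear-canal trials
per participant and attentional condition → complex cross-correlation
detection → grand averages → per-participant summaries → FDR-corrected
condition contrasts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import write_wav, rms
from .config import RunConfig
from .detection import (
    complex_xcorr, correct_delay, detect_trial_peak, estimate_hardware_delay,
    grand_averages, noise_floor,
)
from .errors import NoStimulusLockError
from .fundamental import SourceSignal, estimate_f0, extract_fundamental, f0_stats
from .simulate import (
    EmissionSpec, VoicedSourceSpec, simulate_recording, synth_voiced_source,
    white_noise_rms_for_inband_snr,
)
from .stats import TrialResult, compare_conditions, summarize_participants
from .synthesis import StimulusSet, assemble_set, make_pair

log = logging.getLogger("speechdpoae")

#: f0 search ranges per voice label (Hz)
VOICE_F0_RANGES = {"female": (100.0, 350.0), "male": (55.0, 180.0)}

DEFAULT_SOURCE_SPECS = {
    "female": dict(mean_f0=195.0, sd_f0=40.0),
    "male": dict(mean_f0=90.0, sd_f0=20.0),
}


def build_stimulus_set(config: RunConfig, sources: dict) -> StimulusSet:
    """Full stimulus set for the configured roster from per-voice sources."""
    fundamentals = {}
    for voice, source in sources.items():
        fmin, fmax = VOICE_F0_RANGES.get(voice, (config.f0_fmin, config.f0_fmax))
        t0 = time.perf_counter()
        track = estimate_f0(source, fmin=fmin, fmax=fmax,
                            frame_length=config.frame_length,
                            hop_length=config.hop_length)
        stats = f0_stats(track)
        fundamentals[voice] = extract_fundamental(
            source, stats, order=config.filter_order,
            order_convention=config.order_convention,
            min_half_bandwidth=config.min_half_bandwidth_hz)
        log.info("voice %s: f0 %.1f ± %.1f Hz (%.2f s)", voice,
                 stats.mean_f0, stats.sd_f0, time.perf_counter() - t0)
    pairs = []
    for spec in config.pair_specs():
        if spec.voice_label not in fundamentals:
            raise ValueError(f"no source provided for voice '{spec.voice_label}'")
        pairs.append(make_pair(fundamentals[spec.voice_label], spec))
    return assemble_set(pairs, level_target=config.level_target_db,
                        reference_rms=config.spl_reference_rms,
                        reference_db=config.spl_reference_db)


def synthesize_sources(config: RunConfig, duration: float | None = None) -> dict:
    """Synthetic female/male voiced sources under the default f0 statistics."""
    duration = duration or config.trial_duration_s
    sources = {}
    for i, (voice, params) in enumerate(DEFAULT_SOURCE_SPECS.items()):
        spec = VoicedSourceSpec(duration=duration, seed=config.seed + i, **params)
        sources[voice] = synth_voiced_source(spec, fs=config.fs,
                                             target_rms=config.source_rms,
                                             label=voice)
    return sources


def run_synthesize(config: RunConfig, sources: dict | None = None,
                   out_dir=None) -> StimulusSet:
    """Build the stimulus set and write channel WAVs plus a text manifest."""
    if sources is None:
        sources = synthesize_sources(config)
    stimuli = build_stimulus_set(config, sources)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_wav(out / "W1.wav", stimuli.W1, stimuli.fs)
    write_wav(out / "W2.wav", stimuli.W2, stimuli.fs)
    manifest = {
        "fs": stimuli.fs,
        "level_target_db": stimuli.level_target,
        "seed": config.seed,
        "pairs": [],
    }
    for pair in stimuli.pairs:
        name = f"w_dp_{pair.spec.label}.wav"
        write_wav(out / name, pair.w_dp, pair.fs)
        manifest["pairs"].append({
            "label": pair.spec.label,
            "n": pair.spec.n, "m": pair.spec.m,
            "dp_index": pair.spec.dp_index(),
            "ratio": round(pair.spec.ratio(), 4),
            "rms_w_n": rms(pair.w_n), "rms_w_m": rms(pair.w_m),
            "rms_w_dp": rms(pair.w_dp),
            "file": name,
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return stimuli


@dataclass
class CohortPlan:
    """Design of a simulated cohort experiment.

    ``condition_gains`` maps condition label → {stimulus label → mean gain};
    per-participant gains scatter around those means on a log scale with
    spread ``participant_sd_log`` (multiplicative individual differences).
    ``snr_db`` sets the in-band emission-to-noise ratio at unit mean gain.
    """

    n_participants: int = 38
    trials_per_condition: int = 1
    condition_gains: dict = field(default_factory=lambda: {
        "Att. F": {"female_resolved": 0.8},
        "Att. M": {"female_resolved": 1.0},
    })
    base_gain: float = 1.0
    participant_sd_log: float = 0.1
    emission_delay_ms: float = 1.0
    snr_db: float = 20.0
    leak_gain: float = 0.0
    hardware_delay_ms: float = 0.0
    seed: int = 0


def simulate_cohort(stimuli: StimulusSet, plan: CohortPlan, config: RunConfig):
    """Simulated trials for every participant × condition of the plan.

    Yields (recording, stimulus labels measured in it). Noise RMS is set so
    that a unit-gain emission of the first planned stimulus has the plan's
    in-band SNR.
    """
    rng = np.random.default_rng(plan.seed)
    labels = {p.spec.label: i for i, p in enumerate(stimuli.pairs)}
    first_label = next(iter(next(iter(plan.condition_gains.values())).keys()))
    ref_pair = stimuli.pairs[labels[first_label]]
    noise_rms = white_noise_rms_for_inband_snr(
        ref_pair.w_dp, stimuli.fs, plan.snr_db, gain=plan.base_gain)
    recordings = []
    for p in range(plan.n_participants):
        participant_gain = plan.base_gain * float(
            np.exp(rng.normal(0.0, plan.participant_sd_log)))
        for condition, gains in plan.condition_gains.items():
            for t in range(plan.trials_per_condition):
                emissions = [
                    EmissionSpec(
                        pair_index=labels[stim_label],
                        gain=participant_gain * g,
                        delay_ms=plan.emission_delay_ms,
                        phase_rotation=float(rng.uniform(0, 2 * np.pi)),
                    )
                    for stim_label, g in gains.items()
                ]
                rec = simulate_recording(
                    stimuli, emissions, noise_rms=noise_rms,
                    leak_gain=plan.leak_gain,
                    hardware_delay_ms=plan.hardware_delay_ms,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    trial_id=f"p{p:02d}_{condition}_{t}",
                    condition_label=condition,
                    participant_id=f"p{p:02d}",
                )
                recordings.append((rec, list(gains.keys())))
    return recordings


def detect_trials(recordings, stimuli: StimulusSet, config: RunConfig,
                  correct_hardware_delay: bool = False):
    """Per-trial detection over simulated or ingested recordings.

    Returns a list of TrialResult plus a tidy per-trial DataFrame. Failed
    trials (no stimulus lock) are logged and skipped, never silently
    dropped.
    """
    labels = {p.spec.label: i for i, p in enumerate(stimuli.pairs)}
    trials, rows = [], []
    for rec, stim_labels in recordings:
        if correct_hardware_delay:
            try:
                delay = estimate_hardware_delay(
                    rec, stimuli, search_ms=config.hardware_delay_search_ms,
                    min_lock=config.min_stimulus_lock)
            except NoStimulusLockError as exc:
                log.warning("trial %s skipped: %s", rec.trial_id, exc)
                continue
            rec = correct_delay(rec, delay)
        for stim_label in stim_labels:
            pair = stimuli.pairs[labels[stim_label]]
            cg = complex_xcorr(rec, pair.w_dp,
                               lag_range_ms=tuple(config.lag_range_ms),
                               mode=config.xcorr_mode,
                               dp_index=pair.spec.dp_index(),
                               stimulus_label=stim_label)
            ns = noise_floor(cg, windows=tuple(map(tuple, config.noise_windows_ms)),
                             percentile=config.noise_percentile)
            peak = detect_trial_peak(cg, ns, window_ms=tuple(config.peak_window_ms))
            trials.append(TrialResult(
                participant_id=rec.participant_id,
                stimulus_label=stim_label,
                condition_label=rec.condition_label,
                correlogram=cg,
                peak=peak,
            ))
            rows.append({
                "trial_id": rec.trial_id,
                "participant_id": rec.participant_id,
                "stimulus": stim_label,
                "condition": rec.condition_label,
                "delay_ms": peak.delay_ms,
                "amplitude": peak.amplitude,
                "significant": peak.significant,
                "noise_max": ns.noise_max,
                "noise_p97": ns.noise_p97,
            })
    return trials, pd.DataFrame(rows)


def run_experiment(config: RunConfig, plan: CohortPlan | None = None,
                   stimuli: StimulusSet | None = None, out_dir=None) -> dict:
    """Simulate → detect → summarize → contrast; returns all result tables."""
    plan = plan or CohortPlan(seed=config.seed)
    if stimuli is None:
        sources = synthesize_sources(config)
        stimuli = build_stimulus_set(config, sources)
    recordings = simulate_cohort(stimuli, plan, config)
    trials, trial_df = detect_trials(
        recordings, stimuli, config,
        correct_hardware_delay=plan.leak_gain > 0)
    ga = grand_averages(
        [t.correlogram for t in trials],
        [t.stimulus_label for t in trials],
        window_ms=tuple(config.peak_window_ms),
        noise_windows=tuple(map(tuple, config.noise_windows_ms)))
    grand_delays = {label: peak.delay_ms for label, (_, _, peak, _) in ga.items()}
    summaries = summarize_participants(trials, grand_delays)
    contrast_df = compare_conditions(summaries, design="paired")
    results = {
        "trials": trial_df,
        "summaries": summaries,
        "contrasts": contrast_df,
        "grand_delays": grand_delays,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trial_df.to_csv(out / "trials.tsv", sep="\t", index=False)
        summaries.to_csv(out / "participants.tsv", sep="\t", index=False)
        contrast_df.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        with open(out / "grand_delays.json", "w") as fh:
            json.dump(grand_delays, fh, indent=1)
    return results
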