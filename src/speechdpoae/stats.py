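"""Per-participant aggregation and condition contrasts.

Trial-level emission measures are reduced to one value per participant and
cell (stimulus type × attentional condition): the envelope amplitude read
at the grand-average peak delay is averaged over *all* trials of the cell,
whereas peak delays are averaged over significant trials only. Condition
contrasts then use paired t-tests (competing-speaker design) or their
unpaired analogues, falling back to rank tests when a normality check
fails, with Benjamini–Hochberg FDR control across the contrast family.
Amplitude effects are additionally reported as ratios of group means and in
decibels, 20·log10(ratio).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .detection import ComplexCorrelogram, DPOAEPeak, amplitude_at


@dataclass
class TrialResult:
    """One trial's correlogram and per-trial peak, with its design labels."""

    participant_id: str
    stimulus_label: str
    condition_label: str
    correlogram: ComplexCorrelogram
    peak: DPOAEPeak


@dataclass
class ContrastResult:
    """One condition contrast for one stimulus type."""

    stimulus_label: str
    condition_a: str
    condition_b: str
    test_used: str  # paired_t | wilcoxon | unpaired_t | mann_whitney
    statistic: float
    p_raw: float
    p_fdr: float = float("nan")
    amplitude_ratio: float = float("nan")
    ratio_db: float = float("nan")
    n: int = 0
    note: str = ""


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values for one contrast family."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def amplitude_ratio_db(a: float, b: float):
    """Amplitude ratio a/b and its decibel value 20·log10(a/b)."""
    if b <= 0:
        raise ValueError("undefined ratio: denominator must be positive")
    ratio = a / b
    return ratio, 20.0 * np.log10(ratio)


def summarize_participants(trials: list, grand_peak_delays: dict) -> pd.DataFrame:
    """Per-participant cell means.

    ``grand_peak_delays`` maps a stimulus label (or a
    (stimulus, condition) tuple) to the grand-average peak delay in ms; the
    amplitude of every trial — significant or not — is the envelope read at
    that fixed delay. Mean delays are taken over significant trials only
    (NaN when a cell has none). Stimulus types without a grand peak are
    skipped with a warning.

    Returns a DataFrame with one row per (participant, stimulus, condition)
    and columns amplitude, delay_ms, n_trials, n_significant.
    """
    rows = []
    missing = set()
    for tr in trials:
        key = (tr.stimulus_label, tr.condition_label)
        if key in grand_peak_delays:
            delay = grand_peak_delays[key]
        elif tr.stimulus_label in grand_peak_delays:
            delay = grand_peak_delays[tr.stimulus_label]
        else:
            missing.add(tr.stimulus_label)
            continue
        rows.append({
            "participant_id": tr.participant_id,
            "stimulus": tr.stimulus_label,
            "condition": tr.condition_label,
            "amplitude": amplitude_at(tr.correlogram, delay),
            "delay_ms": tr.peak.delay_ms if tr.peak.significant else np.nan,
            "significant": tr.peak.significant,
        })
    for label in sorted(missing):
        warnings.warn(f"no grand-average peak for stimulus '{label}'; skipped",
                      stacklevel=2)
    if not rows:
        raise ValueError("no trials could be summarized")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["participant_id", "stimulus", "condition"])
        .agg(
            amplitude=("amplitude", "mean"),
            delay_ms=("delay_ms", "mean"),
            n_trials=("amplitude", "size"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    return out


def _normal(x: np.ndarray, alpha: float) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def compare_conditions(
    summaries: pd.DataFrame,
    design: str = "paired",
    normality_policy: str = "shapiro",
    alpha_normality: float = 0.05,
    value_col: str = "amplitude",
    contrasts: list | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Condition contrasts per stimulus type with FDR correction.

    In the paired design, participants present in both conditions are
    matched and a Shapiro–Wilk check on the paired differences (at
    ``alpha_normality``) selects the paired t-test versus the Wilcoxon
    signed-rank test; in the unpaired design both groups must pass the check
    for the t-test, otherwise Mann–Whitney U is used. Setting
    ``normality_policy`` to "parametric" or "nonparametric" forces one
    branch. All computed contrasts form one Benjamini–Hochberg family.

    Returns a DataFrame of ContrastResult fields, including the ratio of
    group means and its dB value, plus a ``significant_fdr`` flag at
    ``fdr_q``.
    """
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    results: list[ContrastResult] = []
    for stim, sub in summaries.groupby("stimulus"):
        conditions = sorted(sub["condition"].unique())
        pair_list = contrasts or list(itertools.combinations(conditions, 2))
        for cond_a, cond_b in pair_list:
            a = sub[sub["condition"] == cond_a].set_index("participant_id")[value_col]
            b = sub[sub["condition"] == cond_b].set_index("participant_id")[value_col]
            note = ""
            if design == "paired":
                common = a.index.intersection(b.index)
                if len(common) < 3:
                    raise ValueError(
                        f"contrast {stim}:{cond_a} vs {cond_b} has fewer than "
                        "3 paired participants"
                    )
                x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
                diffs = x - y
                use_t = normality_policy == "parametric" or (
                    normality_policy == "shapiro" and _normal(diffs, alpha_normality)
                )
                if np.ptp(diffs) == 0:
                    note = "degenerate: identical paired differences"
                    warnings.warn(note + f" in {stim}:{cond_a} vs {cond_b}",
                                  stacklevel=2)
                    use_t = False
                if use_t:
                    res = sps.ttest_rel(x, y)
                    test, stat, p = "paired_t", res.statistic, res.pvalue
                else:
                    if np.all(diffs == 0):
                        test, stat, p = "wilcoxon", 0.0, 1.0
                    else:
                        res = sps.wilcoxon(x, y)
                        test, stat, p = "wilcoxon", res.statistic, res.pvalue
                n = len(common)
            else:
                x, y = a.to_numpy(), b.to_numpy()
                if min(len(x), len(y)) < 3:
                    raise ValueError(
                        f"contrast {stim}:{cond_a} vs {cond_b} has fewer than "
                        "3 participants per group"
                    )
                use_t = normality_policy == "parametric" or (
                    normality_policy == "shapiro"
                    and _normal(x, alpha_normality)
                    and _normal(y, alpha_normality)
                )
                if use_t:
                    res = sps.ttest_ind(x, y)
                    test, stat, p = "unpaired_t", res.statistic, res.pvalue
                else:
                    res = sps.mannwhitneyu(x, y)
                    test, stat, p = "mann_whitney", res.statistic, res.pvalue
                n = len(x) + len(y)
            ratio, db = amplitude_ratio_db(float(np.mean(x)), float(np.mean(y)))
            results.append(ContrastResult(
                stimulus_label=stim, condition_a=cond_a, condition_b=cond_b,
                test_used=test, statistic=float(stat), p_raw=float(p),
                amplitude_ratio=ratio, ratio_db=db, n=n, note=note,
            ))
    p_fdr = fdr_adjust([r.p_raw for r in results])
    for r, q in zip(results, p_fdr):
        r.p_fdr = float(q)
    df = pd.DataFrame([vars(r) for r in results])
    df["significant_fdr"] = df["p_fdr"] <= fdr_q
    return df


def exclude_outliers_mad(values: pd.Series, k: float = 3.0):
    """Optional outlier rule: drop values with |x − median| > k·MAD.

    Off by default everywhere; returns (kept, dropped) so exclusions are
    always visible to the caller.
    """
    x = values.to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return values, values.iloc[0:0]
    keep = np.abs(x - med) <= k * mad
    return values[keep], values[~keep]
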