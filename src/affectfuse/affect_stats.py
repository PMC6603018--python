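"""Behavioural and EEG group statistics.

Covers the report-level analyses: segmentation of the continuous affect
reports into 20 s sub-trials (one per targeted circumplex state),
target-versus-report Pearson correlation, the high/low valence trial
labelling used throughout, two-sample Kolmogorov-Smirnov comparisons of
asymmetry distributions, and step-down Holm-Bonferroni control over the
band battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eeg import AsymmetrySeries, BANDS
from .synth import AffectTrajectory, TrialSchedule, Trial

__all__ = [
    "SubTrial",
    "TestResult",
    "segment_subtrials",
    "target_report_correlation",
    "label_valence_trials",
    "trial_mean_asymmetry",
    "ks_compare",
    "holm_bonferroni",
    "band_asymmetry_battery",
]


@dataclass(frozen=True)
class SubTrial:
    trial_index: int
    half: int
    window: tuple[float, float]
    mean_valence: float
    mean_arousal: float
    target_valence: float
    target_arousal: float


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    method: str
    p_adjusted: float | None = None
    rejected: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def segment_subtrials(
    reported: AffectTrajectory, schedule: TrialSchedule
) -> list[SubTrial]:
    """Two 20 s sub-trials per music trial, with mean report and target."""
    subs: list[SubTrial] = []
    half = schedule.half_duration
    for idx, trial in enumerate(schedule.trials):
        if not trial.is_music:
            continue
        for h, target in ((1, trial.target_1), (2, trial.target_2)):
            start = trial.onset + (h - 1) * half
            end = start + half
            sel = (reported.times >= start) & (reported.times < end)
            if not np.any(sel):
                raise ValueError(
                    f"reports do not cover trial {idx} half {h} ({start}-{end}s)"
                )
            subs.append(
                SubTrial(
                    trial_index=idx,
                    half=h,
                    window=(start, end),
                    mean_valence=float(reported.valence[sel].mean()),
                    mean_arousal=float(reported.arousal[sel].mean()),
                    target_valence=target[0],
                    target_arousal=target[1],
                )
            )
    return subs


def target_report_correlation(subtrials: list[SubTrial], axis: str) -> TestResult:
    """Pearson correlation of mean reported vs targeted affect per sub-trial."""
    if axis not in ("valence", "arousal"):
        raise ValueError("axis must be valence or arousal")
    if len(subtrials) < 3:
        raise ValueError("need at least 3 sub-trials")
    reported = np.array(
        [s.mean_valence if axis == "valence" else s.mean_arousal for s in subtrials]
    )
    target = np.array(
        [s.target_valence if axis == "valence" else s.target_arousal for s in subtrials]
    )
    if np.ptp(target) == 0 or np.ptp(reported) == 0:
        raise ValueError("zero variance in targets or reports")
    r, p = stats.pearsonr(reported, target)
    return TestResult(statistic=float(r), p_raw=float(p), method="pearson")


def label_valence_trials(
    reported: AffectTrajectory,
    schedule: TrialSchedule,
    method: str = "sign",
) -> dict[int, str]:
    """Label each music trial ``high`` or ``low`` by its mean reported valence.

    ``sign``: high iff mean > 0 (a mean of exactly 0 is labelled low).
    ``median``: split at the median of the per-trial means (balanced groups).
    """
    means: dict[int, float] = {}
    for idx, trial in enumerate(schedule.trials):
        if not trial.is_music:
            continue
        sel = (reported.times >= trial.onset) & (reported.times < trial.end)
        if not np.any(sel):
            raise ValueError(f"reports do not cover trial {idx}")
        means[idx] = float(reported.valence[sel].mean())
    if method == "sign":
        threshold = 0.0
    elif method == "median":
        threshold = float(np.median(list(means.values())))
    else:
        raise ValueError(f"unknown labelling method {method!r}")
    return {idx: ("high" if m > threshold else "low") for idx, m in means.items()}


def trial_mean_asymmetry(
    asym: AsymmetrySeries, schedule: TrialSchedule
) -> dict[int, float]:
    """Mean asymmetry per music trial, keyed by trial index."""
    out: dict[int, float] = {}
    for idx, trial in enumerate(schedule.trials):
        if not trial.is_music:
            continue
        sel = (asym.times >= trial.onset) & (asym.times < trial.end)
        if not np.any(sel):
            raise ValueError(f"asymmetry series does not cover trial {idx}")
        out[idx] = float(asym.values[sel].mean())
    return out


def ks_compare(values_a: np.ndarray, values_b: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a - ECDF_b|."""
    import warnings

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 values for the KS test")
    with warnings.catch_warnings():
        # scipy occasionally abandons the exact small-sample computation
        # and falls back to the asymptotic p; the fallback is fine here
        warnings.filterwarnings("ignore", message="ks_2samp", category=RuntimeWarning)
        res = stats.ks_2samp(a, b, method="auto")
    return TestResult(
        statistic=float(res.statistic), p_raw=float(res.pvalue), method="ks_two_sample"
    )


def holm_bonferroni(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm correction; returns (adjusted p's, rejection flags).

    Adjusted p_(i) = max_{j<=i} min(1, (m-j+1) p_(j)) on the sorted p's,
    mapped back to the input order; reject where adjusted p < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted < alpha


def band_asymmetry_battery(
    per_band_asym: dict[str, AsymmetrySeries],
    reported: AffectTrajectory,
    schedule: TrialSchedule,
    alpha: float = 0.05,
    label_method: str = "median",
) -> pd.DataFrame:
    """KS comparison of high- vs low-valence trial-mean asymmetry per band.

    Runs one two-sample KS test per band on per-trial mean asymmetry split
    by reported valence, then applies Holm-Bonferroni across bands.
    Returns a tidy frame (band, statistic, p_raw, p_adjusted, rejected).
    """
    labels = label_valence_trials(reported, schedule, method=label_method)
    rows = []
    for band, asym in per_band_asym.items():
        means = trial_mean_asymmetry(asym, schedule)
        high = np.array([means[i] for i, lab in labels.items() if lab == "high"])
        low = np.array([means[i] for i, lab in labels.items() if lab == "low"])
        res = ks_compare(high, low)
        rows.append({"band": band, "statistic": res.statistic, "p_raw": res.p_raw})
    frame = pd.DataFrame(rows)
    adjusted, rejected = holm_bonferroni(frame["p_raw"].to_numpy(), alpha=alpha)
    frame["p_adjusted"] = adjusted
    frame["rejected"] = rejected
    return frame
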