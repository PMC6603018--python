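"""Shannon entropy of asymmetry time series: disorder per trial and over time.

The disorder of the prefrontal asymmetry series is quantified by the
Shannon entropy H(X) = -sum_x P(x) log2 P(x), with P estimated by an
equal-width histogram over the values in the estimation window and
0 * log2(0) defined as 0.  Higher entropy means the asymmetry wanders over
its range rather than sitting in one state - the signature associated here
with low-valence listening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg import AsymmetrySeries
from .synth import TrialSchedule, Trial

__all__ = [
    "EntropyEstimate",
    "shannon_entropy",
    "trial_entropy",
    "entropy_regressor_series",
]


@dataclass
class EntropyEstimate:
    """Histogram Shannon entropy in bits, with the binning that produced it."""

    value: float
    n_samples: int
    n_bins: int
    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= np.log2(self.n_bins) + 1e-9:
            raise ValueError("entropy outside [0, log2(n_bins)]")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")


def shannon_entropy(
    values: np.ndarray, n_bins: int = 16, edges: np.ndarray | None = None
) -> EntropyEstimate:
    """Histogram estimate of the Shannon entropy of a series, in bits.

    Bins are ``n_bins`` equal-width bins spanning [min, max] of ``values``
    unless explicit ``edges`` are given.  A constant series occupies a
    single degenerate bin and has 0 bits by definition.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 samples to estimate entropy")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if not np.all(np.isfinite(values)):
        raise ValueError("entropy input must be finite")
    if edges is None:
        lo, hi = values.min(), values.max()
        if lo == hi:
            return EntropyEstimate(
                value=0.0,
                n_samples=values.size,
                n_bins=n_bins,
                bin_edges=np.array([lo, hi]),
                probabilities=np.array([1.0]),
            )
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        n_bins = edges.size - 1
    counts, edges = np.histogram(values, bins=edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    h = max(h, 0.0)
    return EntropyEstimate(
        value=h, n_samples=values.size, n_bins=n_bins, bin_edges=edges, probabilities=p
    )


def _trial_slice(asym: AsymmetrySeries, trial: Trial) -> np.ndarray:
    sel = (asym.times >= trial.onset) & (asym.times < trial.end)
    return asym.values[sel]


def trial_entropy(
    asym: AsymmetrySeries, schedule: TrialSchedule, n_bins: int = 16
) -> list[tuple[Trial, EntropyEstimate]]:
    """Per-trial asymmetry entropy for every music-listening trial.

    Each trial uses its own auto-ranged equal-width bins, so the estimate
    reflects the shape of the within-trial distribution, not its scale.
    """
    out = []
    for trial in schedule.music_trials():
        vals = _trial_slice(asym, trial)
        if vals.size < 2:
            raise ValueError(
                f"trial at onset {trial.onset}s has {vals.size} power samples; "
                "cannot estimate entropy"
            )
        out.append((trial, shannon_entropy(vals, n_bins=n_bins)))
    return out


def entropy_regressor_series(
    asym: AsymmetrySeries,
    schedule: TrialSchedule,
    mode: str = "per_trial_boxcar",
    window: float | None = None,
    n_bins: int = 16,
) -> np.ndarray:
    """Entropy as a time series on the asymmetry sample grid.

    ``per_trial_boxcar`` carries each music trial's entropy over its span
    (0 outside trials), the faithful temporal embedding of a per-trial
    measure.  ``sliding_window`` computes entropy over a trailing window
    at every sample (window in seconds).
    """
    if mode == "per_trial_boxcar":
        series = np.zeros_like(asym.values)
        for trial, est in trial_entropy(asym, schedule, n_bins=n_bins):
            sel = (asym.times >= trial.onset) & (asym.times < trial.end)
            series[sel] = est.value
        return series
    if mode == "sliding_window":
        if window is None:
            raise ValueError("sliding_window mode requires a window length")
        n_w = int(round(window * asym.rate))
        if n_w < 4:
            raise ValueError("sliding window must span at least 4 power samples")
        series = np.zeros_like(asym.values)
        for i in range(asym.values.size):
            lo = max(0, i - n_w + 1)
            if i - lo + 1 >= 2:
                series[i] = shannon_entropy(asym.values[lo : i + 1], n_bins=n_bins).value
        return series
    raise ValueError(f"unknown mode {mode!r}")
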