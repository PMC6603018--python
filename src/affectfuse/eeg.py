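"""Prefrontal Laplacian band-power asymmetry features from multichannel EEG.

The feature chain mirrors the standard frontal-asymmetry recipe used in
affective neuroscience: common average reference, broadband Butterworth
filtering, surface-Laplacian derivations centred on F3 (left) and F4
(right), narrow-band power envelopes, and the left-minus-right power
difference.  Greater left-prefrontal activity is the classical EEG
correlate of approach/positive valence, so the asymmetry series is the
quantity the downstream fusion analyses regress BOLD on.

All filters are zero-phase (forward-backward) third-order Butterworth
filters, so no group delay is introduced that would misalign EEG-derived
regressors against the fMRI clock.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "BANDS",
    "EegRecording",
    "LaplacianMontage",
    "LAPLACIAN_LEFT",
    "LAPLACIAN_RIGHT",
    "PowerSeries",
    "AsymmetrySeries",
    "common_average_reference",
    "broadband_filter",
    "laplacian_derivation",
    "bandpower_series",
    "asymmetry_series",
    "prefrontal_asymmetry",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band in Hz.  ``low <= 0`` means a pure low-pass band."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high > max(self.low, 0.0):
            raise ValueError(f"band {self.name}: need low < high, got [{self.low}, {self.high}]")


#: Canonical band set for affect work.  The delta band is nominally 0-4 Hz,
#: but the 1 Hz broadband high-pass makes the effective band 1-4 Hz.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 20.0),
}


@dataclass
class EegRecording:
    """Multichannel EEG: ``samples`` is channels x time, in microvolts."""

    samples: np.ndarray
    rate: float
    labels: tuple[str, ...]
    reference: str = "as_recorded"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = tuple(self.labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present in recording") from None
        return self.samples[idx]


@dataclass(frozen=True)
class LaplacianMontage:
    """Centre electrode minus the mean of its reference ring."""

    centre: str
    references: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.centre in self.references:
            raise ValueError("centre channel cannot be one of its references")
        if len(self.references) == 0:
            raise ValueError("montage needs at least one reference channel")


LAPLACIAN_LEFT = LaplacianMontage("F3", ("FP1", "F7", "Fz", "C3"))
LAPLACIAN_RIGHT = LaplacianMontage("F4", ("FP2", "F8", "Fz", "C4"))


@dataclass
class PowerSeries:
    """Windowed band-power envelope (microvolts squared) at rate 1/step."""

    band: BandDefinition
    times: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class AsymmetrySeries:
    """Left-minus-right prefrontal Laplacian band power over time."""

    band: BandDefinition
    times: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("asymmetry values must be finite")


def common_average_reference(rec: EegRecording) -> EegRecording:
    """Re-reference to the instantaneous mean over all channels (CAR)."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    referenced = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return replace(rec, samples=referenced, reference="CAR")


def _butter_sos(low: float, high: float, order: int, rate: float):
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(
            f"band edge {high} Hz at or above Nyquist ({nyq} Hz); increase the sample rate"
        )
    if low <= 0:
        return signal.butter(order, high / nyq, btype="low", output="sos")
    return signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")


def broadband_filter(
    rec: EegRecording, low: float = 1.0, high: float = 45.0, order: int = 3
) -> EegRecording:
    """Zero-phase broadband Butterworth band-pass (default 1-45 Hz, order 3)."""
    if rec.rate <= 2 * high:
        raise ValueError(
            f"sample rate {rec.rate} Hz too low for a {high} Hz band edge"
        )
    sos = _butter_sos(low, high, order, rec.rate)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def laplacian_derivation(rec: EegRecording, montage: LaplacianMontage) -> np.ndarray:
    """Surface Laplacian: centre channel minus the mean of the reference ring."""
    missing = [
        lab for lab in (montage.centre, *montage.references) if lab not in rec.labels
    ]
    if missing:
        raise KeyError(f"montage channels missing from recording: {', '.join(missing)}")
    centre = rec.channel(montage.centre)
    refs = np.stack([rec.channel(lab) for lab in montage.references])
    return centre - refs.mean(axis=0)


def bandpower_series(
    values: np.ndarray,
    rate: float,
    band: BandDefinition,
    window: float = 2.0,
    step: float = 2.0,
    order: int = 3,
) -> PowerSeries:
    """Sliding-window mean-square band amplitude of a single time series.

    The series is band-passed with a zero-phase Butterworth filter and the
    mean squared amplitude is taken over windows of ``window`` seconds
    hopped by ``step`` seconds.  Window timestamps are window centres, so
    the envelope is symmetric around the energy it summarises.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("bandpower_series expects a 1-D series")
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(round(window * rate))
    n_step = int(round(step * rate))
    if n_win < 2:
        raise ValueError("window too short for the sample rate")
    if n_win > values.size:
        raise ValueError(
            f"window of {n_win} samples longer than series of {values.size}"
        )
    sos = _butter_sos(band.low, band.high, order, rate)
    narrow = signal.sosfiltfilt(sos, values)
    squared = narrow**2
    starts = np.arange(0, values.size - n_win + 1, n_step)
    cumsum = np.concatenate([[0.0], np.cumsum(squared)])
    power = (cumsum[starts + n_win] - cumsum[starts]) / n_win
    times = (starts + n_win / 2.0) / rate
    return PowerSeries(band=band, times=times, values=power, rate=1.0 / step)


def asymmetry_series(left: PowerSeries, right: PowerSeries) -> AsymmetrySeries:
    """Elementwise left-minus-right band power."""
    if left.values.shape != right.values.shape:
        raise ValueError("left and right power series have different lengths")
    if left.rate != right.rate:
        raise ValueError("left and right power series have different rates")
    if left.band != right.band:
        raise ValueError("left and right power series are from different bands")
    return AsymmetrySeries(
        band=left.band,
        times=left.times.copy(),
        values=left.values - right.values,
        rate=left.rate,
    )


def prefrontal_asymmetry(
    rec: EegRecording,
    band: BandDefinition,
    window: float = 2.0,
    step: float = 2.0,
    car: bool = True,
    broadband: bool = True,
) -> AsymmetrySeries:
    """Full feature chain: CAR -> 1-45 Hz -> F3/F4 Laplacians -> band power -> L-R."""
    return per_band_prefrontal_asymmetry(
        rec, {band.name: band}, window=window, step=step, car=car, broadband=broadband
    )[band.name]


def per_band_prefrontal_asymmetry(
    rec: EegRecording,
    bands: dict[str, BandDefinition] | None = None,
    window: float = 2.0,
    step: float = 2.0,
    car: bool = True,
    broadband: bool = True,
) -> dict[str, AsymmetrySeries]:
    """Asymmetry series for several bands, sharing the CAR/broadband stage."""
    bands = bands or BANDS
    if car:
        rec = common_average_reference(rec)
    if broadband:
        rec = broadband_filter(rec)
    left = laplacian_derivation(rec, LAPLACIAN_LEFT)
    right = laplacian_derivation(rec, LAPLACIAN_RIGHT)
    out: dict[str, AsymmetrySeries] = {}
    for name, band in bands.items():
        p_left = bandpower_series(left, rec.rate, band, window=window, step=step)
        p_right = bandpower_series(right, rec.rate, band, window=window, step=step)
        out[name] = asymmetry_series(p_left, p_right)
    return out
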