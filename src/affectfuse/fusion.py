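"""EEG-informed fMRI fusion: regressors on the fMRI clock and full pipelines.

Bridges the fast EEG features to the slow BOLD grid: asymmetry series are
anti-alias filtered, co-registered to the first volume and down-sampled to
the scanner rate (0.5 Hz at TR = 2 s), then HRF-convolved inside the GLM
design.  The three end-to-end analyses are

* the affect GLM (sets A, B and the exclusion contrast C = A \\ B),
* asymmetry-informed mapping (BOLD regressed on prefrontal band-power
  asymmetry), and
* entropy-informed mapping (BOLD regressed on the Shannon-entropy series
  of that asymmetry),

each ending in an FWE-corrected map, exclusion of the reporting-only set B,
and a local-maxima cluster table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import dynamics
from .affect_stats import band_asymmetry_battery
from .eeg import AsymmetrySeries, BANDS, EegRecording, prefrontal_asymmetry
from .glm import (
    StatMap,
    build_design,
    canonical_hrf,
    convolve_regressor,
    exclusion_contrast,
    f_contrast,
    fit_glm,
    fwe_threshold,
    local_maxima_table,
)
from .synth import (
    AffectTrajectory,
    BoldSeries,
    GroundTruth,
    SimulationConfig,
    TrialSchedule,
    generate_affect,
    generate_bold,
    generate_eeg,
    generate_schedule,
    movement_boxcar,
    n_volumes_for,
    stage_rng,
)

__all__ = [
    "FusionConfig",
    "FusionResult",
    "SimulatedDataset",
    "simulate_dataset",
    "resample_to_volumes",
    "build_asymmetry_regressor",
    "build_entropy_regressor",
    "reporting_statmap",
    "run_affect_glm",
    "run_asymmetry_fusion",
    "run_entropy_fusion",
    "select_bands",
]


@dataclass
class FusionConfig:
    """Knobs of the fusion analyses.

    ``alpha`` is the FWE level of the map of interest (the analyses mix
    0.05 and 0.01 depending on the question, so it is always explicit);
    ``exclusion_alpha`` is the level of the reporting-only set B.
    """

    alpha: float
    exclusion_alpha: float = 0.05
    correction: str = "bonferroni"
    entropy_mode: str = "per_trial_boxcar"
    bands: tuple[str, ...] | None = None
    drift_order: int = 3
    n_permutations: int = 500
    entropy_bins: int = 16
    #: add the companion EEG regressor (entropy for the asymmetry analysis
    #: and vice versa) as a confound, so each map reflects the variance
    #: unique to its measure -- the right design for specificity questions
    partial_companion: bool = False


@dataclass
class SimulatedDataset:
    """One complete simulated session plus its generative ground truth."""

    config: SimulationConfig
    schedule: TrialSchedule
    latent: AffectTrajectory
    reported: AffectTrajectory
    eeg: EegRecording
    bold: BoldSeries
    ground_truth: GroundTruth


@dataclass
class FusionResult:
    band: str
    measure: str
    statmap: StatMap
    mask_a: np.ndarray
    mask_b: np.ndarray
    mask_c: np.ndarray
    clusters: pd.DataFrame
    provenance: dict

    def result_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.statmap.f_values.tobytes())
        h.update(self.mask_a.tobytes())
        h.update(self.mask_b.tobytes())
        h.update(self.mask_c.tobytes())
        h.update(json.dumps(self.provenance, sort_keys=True).encode())
        return h.hexdigest()


def resample_to_volumes(
    times: np.ndarray,
    values: np.ndarray,
    n_volumes: int,
    tr: float,
    fmri_start: float = 0.0,
    rate: float | None = None,
    antialias: bool = True,
    slack: float = 2.0,
) -> np.ndarray:
    """Co-register a feature series to the volume grid and down-sample it.

    The series is low-pass filtered below the volume-rate Nyquist
    (1 / (2 TR)) with a zero-phase 3rd-order Butterworth filter, then
    linearly interpolated at the volume acquisition times.  The series
    must span the acquisition up to ``slack`` seconds of edge tolerance
    (windowed power envelopes start half a window late by construction);
    larger gaps are an error.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    vol_times = fmri_start + np.arange(n_volumes) * tr
    gap_lo = times[0] - vol_times[0]
    gap_hi = vol_times[-1] - times[-1]
    if gap_lo > slack or gap_hi > slack:
        raise ValueError(
            "feature series does not span the fMRI acquisition: missing "
            f"[{vol_times[0]:.2f}, {times[0]:.2f}]s at the start and "
            f"[{times[-1]:.2f}, {vol_times[-1]:.2f}]s at the end"
        )
    if antialias and rate is not None:
        nyq_target = 1.0 / (2.0 * tr)
        if rate > 2.0 * nyq_target and np.ptp(values) > 0:
            sos = signal.butter(
                3, nyq_target / (rate / 2.0), btype="low", output="sos"
            )
            values = signal.sosfiltfilt(sos, values)
    return np.interp(vol_times, times, values)


def build_asymmetry_regressor(
    asym: AsymmetrySeries, n_volumes: int, tr: float, fmri_start: float = 0.0
) -> np.ndarray:
    """Asymmetry series on the TR grid, anti-aliased, pre-HRF-convolution."""
    return resample_to_volumes(
        asym.times,
        asym.values,
        n_volumes,
        tr,
        fmri_start=fmri_start,
        rate=asym.rate,
        slack=max(2.0, 2.0 / asym.rate),
    )


def build_entropy_regressor(
    asym: AsymmetrySeries,
    schedule: TrialSchedule,
    n_volumes: int,
    tr: float,
    mode: str = "per_trial_boxcar",
    window: float | None = None,
    n_bins: int = 16,
    fmri_start: float = 0.0,
) -> np.ndarray:
    """Entropy time series (boxcar or sliding) on the TR grid."""
    series = dynamics.entropy_regressor_series(
        asym, schedule, mode=mode, window=window, n_bins=n_bins
    )
    # centre the entropy values across trials (parametric-modulation
    # convention): the regressor then carries per-trial entropy
    # *differences* and is not collinear with the task-on boxcar
    on = series != 0
    if np.any(on):
        series = np.where(on, series - series[on].mean(), 0.0)
    # the boxcar is piecewise constant; anti-aliasing would smear trial
    # edges, so it is resampled directly
    return resample_to_volumes(
        asym.times,
        series,
        n_volumes,
        tr,
        fmri_start=fmri_start,
        rate=asym.rate,
        antialias=(mode == "sliding_window"),
        slack=max(2.0, 2.0 / asym.rate),
    )


def compute_eeg_features(
    eeg: EegRecording,
    schedule: TrialSchedule,
    config: SimulationConfig,
    n_volumes: int,
    which: set[str] | None = None,
) -> dict[str, np.ndarray]:
    """Measured EEG drivers on the TR grid (asymmetry and entropy).

    By default only the features some coupled ROI actually needs are
    computed; pass ``which`` to force a set.
    """
    if which is None:
        which = {r.driver for r in config.coupling.rois if r.amplitude != 0.0}
    features: dict[str, np.ndarray] = {}
    if which & {"asymmetry", "entropy"}:
        asym = prefrontal_asymmetry(
            eeg,
            BANDS[config.asymmetry_band],
            window=config.power_window,
            step=config.power_step,
        )
        if "asymmetry" in which:
            features["asymmetry"] = build_asymmetry_regressor(asym, n_volumes, config.tr)
        if "entropy" in which:
            features["entropy"] = build_entropy_regressor(
                asym, schedule, n_volumes, config.tr, n_bins=config.entropy_bins
            )
    return features


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full joint session: schedule, affect, EEG, features, BOLD.

    EEG-coupled BOLD ROIs are driven by the features *measured* from the
    generated EEG (asymmetry in ``config.asymmetry_band``, and its
    per-trial entropy boxcar), mirroring what the fusion analyses regress
    on.
    """
    schedule = generate_schedule(config)
    latent, reported = generate_affect(schedule, config)
    eeg = generate_eeg(latent, schedule, config)
    n_vol = n_volumes_for(schedule, config)
    features = compute_eeg_features(eeg, schedule, config, n_vol)
    bold, truth = generate_bold(latent, features, schedule, config)
    return SimulatedDataset(
        config=config,
        schedule=schedule,
        latent=latent,
        reported=reported,
        eeg=eeg,
        bold=bold,
        ground_truth=truth,
    )


def _masked_report(
    dataset: SimulatedDataset, axis: str, trial_types: tuple[str, ...]
) -> np.ndarray:
    """Reported affect on the TR grid, zeroed outside the given trial types.

    The generator produces one continuous report trace; restricting it to
    ``music_only`` trials plays the role of the reports copied from the
    matching ``music_reporting`` trials.
    """
    n_vol = dataset.bold.n_volumes
    tr = dataset.bold.tr
    vol_times = np.arange(n_vol) * tr
    series = np.interp(
        vol_times, dataset.reported.times, dataset.reported.axis(axis)
    )
    keep = np.zeros(n_vol, dtype=bool)
    for t in dataset.schedule.of_type(*trial_types):
        keep |= (vol_times >= t.onset) & (vol_times < t.end)
    return np.where(keep, series, 0.0)


def _trial_boxcar(
    dataset: SimulatedDataset, trial_types: tuple[str, ...]
) -> np.ndarray:
    n_vol = dataset.bold.n_volumes
    vol_times = np.arange(n_vol) * dataset.bold.tr
    box = np.zeros(n_vol)
    for t in dataset.schedule.of_type(*trial_types):
        box[(vol_times >= t.onset) & (vol_times < t.end)] = 1.0
    return box


def _movement_confound(dataset: SimulatedDataset) -> np.ndarray:
    """Reporting-task boxcar in haemodynamic space, for use as a confound."""
    box = movement_boxcar(dataset.schedule, dataset.bold.n_volumes, dataset.bold.tr)
    return convolve_regressor(box, canonical_hrf(dt=dataset.bold.tr))


def _threshold(
    statmap: StatMap, fit, dataset: SimulatedDataset, alpha: float, config: FusionConfig
) -> np.ndarray:
    rng = stage_rng(dataset.config.seed, "permutation")
    mask_flat = fwe_threshold(
        statmap,
        alpha,
        method=config.correction,
        fit=fit,
        bold=dataset.bold,
        n_permutations=config.n_permutations,
        rng=rng,
    )
    return mask_flat.reshape(dataset.bold.volume_shape)


def reporting_statmap(
    dataset: SimulatedDataset, config: FusionConfig
) -> tuple[np.ndarray, StatMap]:
    """Set B: voxels co-varying with the reporting task alone.

    Effects of interest are the valence and arousal reports masked to the
    ``reporting_only`` trials plus the joystick-use boxcar over all
    reporting trials (the minimal surrogate for movement kinematics); no
    movement confound, since movement is exactly what this map must
    capture.
    """
    if not dataset.schedule.of_type("reporting_only"):
        raise ValueError("schedule contains no reporting_only trials")
    n_vol = dataset.bold.n_volumes
    regressors = {
        "report_valence_ro": _masked_report(dataset, "valence", ("reporting_only",)),
        "report_arousal_ro": _masked_report(dataset, "arousal", ("reporting_only",)),
        "reporting_boxcar": _trial_boxcar(
            dataset, ("music_reporting", "reporting_only")
        ),
    }
    design = build_design(
        regressors,
        confounds=None,
        n_volumes=n_vol,
        drift_order=config.drift_order,
        tr=dataset.bold.tr,
    )
    fit = fit_glm(dataset.bold, design)
    statmap = f_contrast(fit, design.contrast_for_effects())
    mask_b = _threshold(statmap, fit, dataset, config.exclusion_alpha, config)
    return mask_b, statmap


@dataclass
class AffectGlmResult:
    axis: str
    statmap_a: StatMap
    statmap_b: StatMap
    mask_a: np.ndarray
    mask_b: np.ndarray
    mask_c: np.ndarray
    clusters: pd.DataFrame


def run_affect_glm(
    dataset: SimulatedDataset, axis: str, config: FusionConfig
) -> AffectGlmResult:
    """Affect mapping with the exclusion contrast.

    Set A: voxels co-varying with the reported affect axis during all
    music-listening trials (music_only reports are the copied traces).
    Set B: the reporting-only map.  C = A \\ B isolates affect-related
    voxels from reporting-related ones.
    """
    for ttype in ("music_only", "music_reporting", "reporting_only"):
        if not dataset.schedule.of_type(ttype):
            raise ValueError(f"schedule contains no {ttype} trials")
    n_vol = dataset.bold.n_volumes
    regressors = {
        f"report_{axis}_music": _masked_report(
            dataset, axis, ("music_only", "music_reporting")
        )
    }
    confounds = {"movement": _movement_confound(dataset)}
    design = build_design(
        regressors,
        confounds,
        n_volumes=n_vol,
        drift_order=config.drift_order,
        tr=dataset.bold.tr,
    )
    fit = fit_glm(dataset.bold, design)
    statmap_a = f_contrast(fit, design.contrast_for_effects())
    mask_a = _threshold(statmap_a, fit, dataset, config.alpha, config)
    mask_b, statmap_b = reporting_statmap(dataset, config)
    mask_c = exclusion_contrast(mask_a, mask_b)
    clusters = local_maxima_table(
        statmap_a.volume("f"), statmap_a.volume("p"), mask_c, dataset.bold.affine
    )
    return AffectGlmResult(
        axis=axis,
        statmap_a=statmap_a,
        statmap_b=statmap_b,
        mask_a=mask_a,
        mask_b=mask_b,
        mask_c=mask_c,
        clusters=clusters,
    )


def _fusion(
    dataset: SimulatedDataset,
    band: str,
    config: FusionConfig,
    measure: str,
) -> FusionResult:
    asym = prefrontal_asymmetry(
        dataset.eeg,
        BANDS[band],
        window=dataset.config.power_window,
        step=dataset.config.power_step,
    )
    n_vol = dataset.bold.n_volumes
    tr = dataset.bold.tr
    regs = {
        "asymmetry": build_asymmetry_regressor(asym, n_vol, tr),
        "entropy": build_entropy_regressor(
            asym,
            dataset.schedule,
            n_vol,
            tr,
            mode=config.entropy_mode,
            n_bins=config.entropy_bins,
        ),
    }
    if measure not in regs:
        raise ValueError(f"unknown fusion measure {measure!r}")
    reg = regs[measure]
    if np.ptp(reg) == 0:
        raise ValueError(
            f"{measure} regressor is constant; nothing to standardise or fit"
        )
    confounds = {"movement": _movement_confound(dataset)}
    if config.partial_companion:
        other = "entropy" if measure == "asymmetry" else "asymmetry"
        hrf = canonical_hrf(dt=tr)
        conv = convolve_regressor(regs[other], hrf)
        confounds[other] = (conv - conv.mean()) / conv.std()
    design = build_design(
        {f"{measure}_{band}": reg},
        confounds,
        n_volumes=n_vol,
        drift_order=config.drift_order,
        tr=tr,
    )
    fit = fit_glm(dataset.bold, design)
    statmap = f_contrast(fit, design.contrast_for_effects())
    mask_a = _threshold(statmap, fit, dataset, config.alpha, config)
    mask_b, _ = reporting_statmap(dataset, config)
    mask_c = exclusion_contrast(mask_a, mask_b)
    clusters = local_maxima_table(
        statmap.volume("f"), statmap.volume("p"), mask_c, dataset.bold.affine
    )
    provenance = {
        "seed": dataset.config.seed,
        "band": band,
        "measure": measure,
        "alpha": config.alpha,
        "exclusion_alpha": config.exclusion_alpha,
        "correction": config.correction,
    }
    return FusionResult(
        band=band,
        measure=measure,
        statmap=statmap,
        mask_a=mask_a,
        mask_b=mask_b,
        mask_c=mask_c,
        clusters=clusters,
        provenance=provenance,
    )


def run_asymmetry_fusion(
    dataset: SimulatedDataset, band: str, config: FusionConfig
) -> FusionResult:
    """BOLD regressed on the prefrontal band-power asymmetry series."""
    return _fusion(dataset, band, config, "asymmetry")


def run_entropy_fusion(
    dataset: SimulatedDataset, band: str, config: FusionConfig
) -> FusionResult:
    """BOLD regressed on the Shannon-entropy series of the asymmetry."""
    return _fusion(dataset, band, config, "entropy")


def select_bands(
    dataset: SimulatedDataset, alpha: float = 0.05, label_method: str = "median"
) -> list[str]:
    """Bands whose high/low-valence KS test survives Holm correction.

    Mirrors the data-driven choice of which bands to carry into fusion;
    returns band names in canonical order.
    """
    from .eeg import per_band_prefrontal_asymmetry

    per_band = per_band_prefrontal_asymmetry(
        dataset.eeg,
        BANDS,
        window=dataset.config.power_window,
        step=dataset.config.power_step,
    )
    table = band_asymmetry_battery(
        per_band,
        dataset.reported,
        dataset.schedule,
        alpha=alpha,
        label_method=label_method,
    )
    return list(table.loc[table["rejected"], "band"])
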