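"""Seeded generator for joint EEG + BOLD + affect-report datasets.

The generator emulates a three-trial-type music paradigm: 40 s trials of
``music_only``, ``music_reporting`` and ``reporting_only`` type, where each
musical excerpt targets one of 9 valence-arousal circumplex regions for the
first 20 s half and a different region for the second half.  A latent
valence/arousal trajectory follows the targets through smooth AR(1) noise;
a reported trace lags the latent state through a first-order (joystick-like)
follower.  EEG alpha/beta amplitude at the left prefrontal cortex rises, and
at the right falls, with latent valence, so the Laplacian band-power
asymmetry is positively coupled to valence; at low valence the coupling gain
additionally wanders slowly, making the asymmetry series more disordered
(higher Shannon entropy).  BOLD regions of interest are driven by
HRF-convolved couplings to valence, arousal, the measured asymmetry, the
measured asymmetry entropy, or a reporting-task movement boxcar.

Everything is a pure function of (seed, config): per-stage generators are
derived deterministically from the one top-level seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .eeg import BANDS, EegRecording

__all__ = [
    "TRIAL_TYPES",
    "REQUIRED_CHANNELS",
    "Trial",
    "TrialSchedule",
    "AffectTrajectory",
    "RoiCoupling",
    "CouplingSpec",
    "SimulationConfig",
    "BoldSeries",
    "GroundTruth",
    "default_coupling",
    "stage_rng",
    "circumplex_target",
    "generate_schedule",
    "generate_affect",
    "generate_eeg",
    "generate_bold",
    "calibrate_latent_noise",
]

TRIAL_TYPES = ("music_only", "music_reporting", "reporting_only")
MUSIC_TYPES = ("music_only", "music_reporting")
REPORTING_TYPES = ("music_reporting", "reporting_only")

REQUIRED_CHANNELS = ("F3", "F4", "FP1", "FP2", "F7", "F8", "Fz", "C3", "C4")

DRIVERS = ("valence", "arousal", "asymmetry", "entropy", "movement")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def circumplex_target(region: int, amplitude: float) -> tuple[float, float]:
    """Map a circumplex region index 1..9 to a (valence, arousal) target.

    Regions tile the {low, neutral, high} x {low, neutral, high} grid:
    valence level cycles fastest, arousal level slowest.
    """
    if not 1 <= region <= 9:
        raise ValueError(f"circumplex region must be in 1..9, got {region}")
    v_level = (region - 1) % 3 - 1
    a_level = (region - 1) // 3 - 1
    return (v_level * amplitude, a_level * amplitude)


@dataclass(frozen=True)
class Trial:
    onset: float
    duration: float
    trial_type: str
    stimulus_id: int
    target_region_1: int
    target_region_2: int
    target_1: tuple[float, float]
    target_2: tuple[float, float]
    jitter: float

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def is_music(self) -> bool:
        return self.trial_type in MUSIC_TYPES

    @property
    def is_reporting(self) -> bool:
        return self.trial_type in REPORTING_TYPES


@dataclass
class TrialSchedule:
    """Ordered, non-overlapping trials with per-half circumplex targets."""

    trials: list[Trial]
    half_duration: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        for a, b in zip(self.trials, self.trials[1:]):
            if b.onset < a.end:
                raise ValueError(
                    f"trials overlap: one ends at {a.end}, next starts at {b.onset}"
                )
        for t in self.trials:
            if t.trial_type not in TRIAL_TYPES:
                raise ValueError(f"unknown trial type {t.trial_type!r}")
            if not 0.0 <= t.jitter <= 2.0:
                raise ValueError(f"jitter must lie in [0, 2], got {t.jitter}")
        seen: set[int] = set()
        for i, t in enumerate(self.trials):
            if t.trial_type == "music_reporting":
                seen.add(t.stimulus_id)
            elif t.trial_type == "reporting_only" and t.stimulus_id not in seen:
                raise ValueError(
                    f"trial {i} (reporting_only, stimulus {t.stimulus_id}) is not "
                    "preceded by a music_reporting trial of the same stimulus"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def end_time(self) -> float:
        return self.trials[-1].end if self.trials else 0.0

    def music_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.is_music]

    def of_type(self, *types: str) -> list[Trial]:
        return [t for t in self.trials if t.trial_type in types]


@dataclass
class AffectTrajectory:
    """Time-stamped valence/arousal in [-1, 1]; latent state or reported trace."""

    times: np.ndarray
    valence: np.ndarray
    arousal: np.ndarray
    kind: str = "latent"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.valence = np.asarray(self.valence, dtype=float)
        self.arousal = np.asarray(self.arousal, dtype=float)
        if not (self.times.shape == self.valence.shape == self.arousal.shape):
            raise ValueError("times, valence and arousal must share a shape")
        if self.kind not in ("latent", "reported"):
            raise ValueError(f"kind must be latent or reported, got {self.kind!r}")
        for name, vals in (("valence", self.valence), ("arousal", self.arousal)):
            if vals.size and (np.nanmax(np.abs(vals)) > 1.0 + 1e-9):
                raise ValueError(f"{name} values must lie in [-1, 1]")
        if self.times.size > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")

    @property
    def rate(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    def axis(self, name: str) -> np.ndarray:
        if name == "valence":
            return self.valence
        if name == "arousal":
            return self.arousal
        raise ValueError(f"axis must be valence or arousal, got {name!r}")


@dataclass(frozen=True)
class RoiCoupling:
    """A cubic ROI whose BOLD signal follows one driver at a given amplitude.

    ``amplitude`` is in BOLD units per standard deviation of the
    HRF-convolved driver; 0 marks a null ROI kept for type-I error checks.
    """

    name: str
    driver: str
    origin: tuple[int, int, int]
    size: tuple[int, int, int]
    amplitude: float

    def __post_init__(self) -> None:
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}; one of {DRIVERS}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if any(s < 1 for s in self.size):
            raise ValueError("ROI size must be at least 1 voxel per axis")

    def mask(self, volume_shape: tuple[int, int, int]) -> np.ndarray:
        for o, s, n in zip(self.origin, self.size, volume_shape):
            if o < 0 or o + s > n:
                raise ValueError(
                    f"ROI {self.name!r} does not fit inside volume {volume_shape}"
                )
        m = np.zeros(volume_shape, dtype=bool)
        m[
            self.origin[0] : self.origin[0] + self.size[0],
            self.origin[1] : self.origin[1] + self.size[1],
            self.origin[2] : self.origin[2] + self.size[2],
        ] = True
        return m


@dataclass
class CouplingSpec:
    """Generative couplings: BOLD ROIs plus the EEG valence/entropy gains.

    ``eeg_valence_gain`` is the fractional alpha/beta power modulation per
    unit valence at the prefrontal centre electrodes; ``entropy_gain``
    scales how strongly low valence inflates the slow variance of that
    gain (the mechanism behind higher asymmetry entropy at low valence).
    """

    rois: tuple[RoiCoupling, ...] = ()
    eeg_valence_gain: float = 0.4
    entropy_gain: float = 4.0

    def validate(self, volume_shape: tuple[int, int, int]) -> None:
        total = np.zeros(volume_shape, dtype=int)
        for roi in self.rois:
            total += roi.mask(volume_shape).astype(int)
        if np.any(total > 1):
            raise ValueError("ROI masks must be pairwise disjoint")

    def masks(self, volume_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
        return {roi.name: roi.mask(volume_shape) for roi in self.rois}


def default_coupling(
    volume_shape: tuple[int, int, int] = (12, 12, 12),
    amplitude: float = 0.8,
    eeg_valence_gain: float = 0.4,
    entropy_gain: float = 4.0,
) -> CouplingSpec:
    """One 3-cube ROI per driver plus a null ROI, spread through the volume."""
    nx, ny, nz = volume_shape
    if min(volume_shape) < 6:
        raise ValueError("default coupling needs at least a 6x6x6 volume")
    hi = (nx - 3, ny - 3, nz - 3)
    placements = {
        "valence": (0, 0, 0),
        "arousal": (hi[0], 0, 0),
        "asymmetry": (0, hi[1], 0),
        "entropy": (hi[0], hi[1], 0),
        "movement": (0, 0, hi[2]),
        "null": (hi[0], hi[1], hi[2]),
    }
    rois = []
    for name, origin in placements.items():
        driver = "valence" if name == "null" else name
        amp = 0.0 if name == "null" else amplitude
        rois.append(
            RoiCoupling(name=name, driver=driver, origin=origin, size=(3, 3, 3), amplitude=amp)
        )
    spec = CouplingSpec(
        rois=tuple(rois), eeg_valence_gain=eeg_valence_gain, entropy_gain=entropy_gain
    )
    spec.validate(volume_shape)
    return spec


@dataclass
class SimulationConfig:
    """All study conditions for one simulated recording session.

    Defaults follow the paradigm the analyses assume: 40 s trials split in
    two 20 s circumplex-target halves, TR 2 s, and the nine 10/20 channels
    the prefrontal Laplacians need.
    """

    seed: int = 0
    n_trials: int = 36
    trial_duration: float = 40.0
    half_duration: float = 20.0
    eeg_rate: float = 250.0
    tr: float = 2.0
    volume_shape: tuple[int, int, int] = (12, 12, 12)
    channel_labels: tuple[str, ...] = REQUIRED_CHANNELS
    noise_sd_eeg: float = 3.0
    noise_sd_bold: float = 1.0
    coupling: CouplingSpec | None = None
    report_lag: float = 1.5
    report_noise_sd: float = 0.08
    drift_order: int = 2
    drift_sd: float = 0.5
    inter_trial_interval: float = 2.0
    post_rest: float = 16.0
    affect_rate: float = 8.0
    target_amplitude: float = 0.35
    latent_noise_sd: float = 0.45
    latent_noise_tau: float = 8.0
    gain_noise_tau: float = 4.0
    burst_rate: float = 0.1
    burst_gain: float = 4.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 6.0, "theta": 5.0, "alpha": 10.0, "beta": 6.0}
    )
    asymmetry_band: str = "alpha"
    power_window: float = 2.0
    power_step: float = 0.25
    entropy_bins: int = 16

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = default_coupling(self.volume_shape)
        if abs(self.trial_duration - 2 * self.half_duration) > 1e-9:
            raise ValueError("trial_duration must equal 2 x half_duration")
        if abs(self.eeg_rate * self.tr - round(self.eeg_rate * self.tr)) > 1e-9:
            raise ValueError("eeg_rate x tr must be an integer number of samples")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_labels]
        if missing:
            raise ValueError(f"channel_labels missing required channels: {missing}")
        if self.n_trials < 3:
            raise ValueError("need n_trials >= 3 (one of each trial type)")
        self.coupling.validate(self.volume_shape)

    @property
    def session_duration(self) -> float:
        """Upper bound on session length; the schedule refines it."""
        per_trial = self.trial_duration + self.inter_trial_interval + 2.0
        return self.n_trials * per_trial + self.post_rest


@dataclass
class BoldSeries:
    """4-D BOLD voxel grid with TR and a voxel-to-mm affine."""

    data: np.ndarray
    tr: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def flat(self) -> np.ndarray:
        """Voxels x time view."""
        return self.data.reshape(-1, self.n_volumes)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    seed: int
    roi_masks: dict[str, np.ndarray]
    roi_drivers: dict[str, str]
    roi_amplitudes: dict[str, float]
    signals: dict[str, np.ndarray]
    eeg_valence_gain: float
    entropy_gain: float


# ---------------------------------------------------------------------------
# schedule


def generate_schedule(config: SimulationConfig) -> TrialSchedule:
    """Pseudo-randomised trial order honouring the replay constraint.

    Every ``reporting_only`` trial replays the FEELTRACE record of an
    earlier ``music_reporting`` trial, so its stimulus must occur earlier
    in the session in a ``music_reporting`` trial.  A random order is
    drawn and repaired greedily: constraint-violating replay trials are
    deferred until their source stimulus has been heard.
    """
    rng = stage_rng(config.seed, "schedule")
    n = config.n_trials
    n_each = n // 3
    n_mr = n_each + (1 if n % 3 else 0)
    n_ro = n_each
    n_mo = n - n_mr - n_ro
    if min(n_mr, n_ro, n_mo) < 1:
        raise ValueError(f"cannot place all three trial types in {n} trials")

    # stimulus ids: music_reporting trials introduce stimuli; music_only
    # replays the piece without reporting; reporting_only replays the trace.
    mr_ids = list(range(n_mr))
    mo_ids = [mr_ids[i % n_mr] for i in range(n_mo)]
    ro_ids = [int(rng.integers(0, n_mr)) for _ in range(n_ro)]

    targets: dict[int, tuple[int, int]] = {}
    for sid in mr_ids:
        r1 = int(rng.integers(1, 10))
        r2 = int(rng.integers(1, 10))
        while r2 == r1:
            r2 = int(rng.integers(1, 10))
        targets[sid] = (r1, r2)

    pool = (
        [("music_reporting", sid) for sid in mr_ids]
        + [("music_only", sid) for sid in mo_ids]
        + [("reporting_only", sid) for sid in ro_ids]
    )
    order = [pool[i] for i in rng.permutation(len(pool))]

    placed: list[tuple[str, int]] = []
    heard: set[int] = set()
    pending: list[tuple[str, int]] = []
    for ttype, sid in order:
        if ttype == "reporting_only" and sid not in heard:
            pending.append((ttype, sid))
            continue
        placed.append((ttype, sid))
        if ttype == "music_reporting":
            heard.add(sid)
            still = [p for p in pending if p[1] in heard]
            pending = [p for p in pending if p[1] not in heard]
            placed.extend(still)
    if pending:  # pragma: no cover - mr ids always eventually heard
        raise ValueError("could not satisfy the reporting_only precedence constraint")

    trials: list[Trial] = []
    t = 0.0
    for ttype, sid in placed:
        jitter = float(rng.uniform(0.0, 2.0))
        onset = t + jitter
        r1, r2 = targets[sid]
        trials.append(
            Trial(
                onset=onset,
                duration=config.trial_duration,
                trial_type=ttype,
                stimulus_id=sid,
                target_region_1=r1,
                target_region_2=r2,
                target_1=circumplex_target(r1, config.target_amplitude),
                target_2=circumplex_target(r2, config.target_amplitude),
                jitter=jitter,
            )
        )
        t = onset + config.trial_duration + config.inter_trial_interval
    return TrialSchedule(trials=trials, half_duration=config.half_duration)


# ---------------------------------------------------------------------------
# affect


def _ar1(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary order-1 autoregressive series with time constant tau."""
    if n == 0:
        return np.zeros(0)
    from scipy.signal import lfilter

    phi = float(np.exp(-dt / tau))
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -phi], innov)


def _target_series(schedule: TrialSchedule, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tv = np.zeros_like(times)
    ta = np.zeros_like(times)
    for tr in schedule.trials:
        if not tr.is_music:
            # no music is played in reporting_only trials, so no affect is
            # induced; the latent state just drifts
            continue
        half = schedule.half_duration
        first = (times >= tr.onset) & (times < tr.onset + half)
        second = (times >= tr.onset + half) & (times < tr.end)
        tv[first], ta[first] = tr.target_1
        tv[second], ta[second] = tr.target_2
    return tv, ta


def _exp_follower(x: np.ndarray, dt: float, lag: float) -> np.ndarray:
    """Causal first-order low-pass with time constant ``lag`` (joystick model)."""
    if lag == 0.0:
        return x.copy()
    from scipy.signal import lfilter

    alpha = 1.0 - float(np.exp(-dt / lag))
    return lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def generate_affect(
    schedule: TrialSchedule, config: SimulationConfig
) -> tuple[AffectTrajectory, AffectTrajectory]:
    """Latent circumplex trajectory plus its lagged, noisy report."""
    if config.report_lag < 0:
        raise ValueError("report_lag must be non-negative")
    rng = stage_rng(config.seed, "affect")
    dt = 1.0 / config.affect_rate
    duration = schedule.end_time + config.post_rest
    times = np.arange(0.0, duration, dt)
    tv, ta = _target_series(schedule, times)
    lat_v = np.clip(
        tv + _ar1(rng, times.size, dt, config.latent_noise_tau, config.latent_noise_sd),
        -1.0,
        1.0,
    )
    lat_a = np.clip(
        ta + _ar1(rng, times.size, dt, config.latent_noise_tau, config.latent_noise_sd),
        -1.0,
        1.0,
    )
    rep_v = _exp_follower(lat_v, dt, config.report_lag)
    rep_a = _exp_follower(lat_a, dt, config.report_lag)
    # reporting_only trials replay the FEELTRACE record of the earlier
    # music_reporting trial of the same stimulus: the trace the joystick
    # follows there is the old report, not the current latent state
    source_onset: dict[int, float] = {}
    for tr in schedule.trials:
        if tr.trial_type == "music_reporting" and tr.stimulus_id not in source_onset:
            source_onset[tr.stimulus_id] = tr.onset
    for tr in schedule.trials:
        if tr.trial_type != "reporting_only":
            continue
        n_seg = int(round(tr.duration * config.affect_rate))
        dst = int(round(tr.onset * config.affect_rate))
        src = int(round(source_onset[tr.stimulus_id] * config.affect_rate))
        n_seg = min(n_seg, times.size - dst, times.size - src)
        rep_v[dst : dst + n_seg] = rep_v[src : src + n_seg]
        rep_a[dst : dst + n_seg] = rep_a[src : src + n_seg]
    if config.report_noise_sd > 0:
        rep_v = rep_v + rng.normal(0.0, config.report_noise_sd, size=times.size)
        rep_a = rep_a + rng.normal(0.0, config.report_noise_sd, size=times.size)
    latent = AffectTrajectory(times, lat_v, lat_a, kind="latent")
    reported = AffectTrajectory(
        times, np.clip(rep_v, -1, 1), np.clip(rep_a, -1, 1), kind="reported"
    )
    return latent, reported


def calibrate_latent_noise(
    config: SimulationConfig,
    r_target: float,
    n_subtrials: int = 200,
    seed: int = 0,
    n_iter: int = 12,
) -> SimulationConfig:
    """Monte-Carlo calibration of the latent noise knob.

    Bisects ``latent_noise_sd`` until the correlation between targeted and
    mean reported valence per 20 s sub-trial matches ``r_target``.  The
    oracle is the direct correlation on generated data, so clipping and
    report lag are accounted for automatically.
    """
    from .affect_stats import segment_subtrials, target_report_correlation

    if not 0.05 < r_target < 0.95:
        raise ValueError("r_target must lie well inside (0, 1)")
    # probe with at least 600 sub-trials so the bisection target is not
    # dominated by Monte-Carlo error in the correlation estimate
    n_probe = max(n_subtrials, 600)
    n_trials = max(3, (3 * n_probe) // 4 + 3)
    probe = replace(config, n_trials=n_trials, seed=seed)
    lo, hi = 0.01, 3.0
    sd = probe.latent_noise_sd
    for _ in range(n_iter):
        sd = 0.5 * (lo + hi)
        rs = []
        for probe_seed in (seed, seed + 104729):  # two independent probes
            cfg = replace(probe, latent_noise_sd=sd, seed=probe_seed)
            schedule = generate_schedule(cfg)
            _, reported = generate_affect(schedule, cfg)
            subs = segment_subtrials(reported, schedule)
            rs.append(target_report_correlation(subs, "valence").statistic)
        if np.mean(rs) > r_target:  # too little noise -> raise it
            lo = sd
        else:
            hi = sd
    return replace(config, latent_noise_sd=sd)


# ---------------------------------------------------------------------------
# EEG


def _band_oscillation(
    rng: np.random.Generator, n: int, rate: float, low: float, high: float
) -> np.ndarray:
    """Unit-RMS rhythmic oscillation confined to [low, high] Hz.

    Band-limited noise is envelope-normalised (divided by its Hilbert
    envelope), yielding a coherent constant-envelope rhythm whose phase
    and instantaneous frequency still wander over the band - a closer
    model of cortical alpha/beta rhythms than raw filtered noise, and one
    whose band power responds to amplitude modulation rather than to the
    sampling noise of the source itself.
    """
    from scipy import signal as sig

    sos = sig.butter(3, [low / (rate / 2), high / (rate / 2)], btype="band", output="sos")
    x = sig.sosfiltfilt(sos, rng.standard_normal(n))
    env = np.abs(sig.hilbert(x))
    x = x / np.maximum(env, 1e-12)
    return x * np.sqrt(2.0)


def generate_eeg(
    latent: AffectTrajectory, schedule: TrialSchedule, config: SimulationConfig
) -> EegRecording:
    """Band-structured EEG whose prefrontal alpha/beta power tracks valence.

    Left (F3) alpha/beta amplitude is scaled by sqrt(1 + g v) and right
    (F4) by sqrt(1 - g v), so band *power* changes by a factor (1 +/- g v)
    and the left-minus-right Laplacian band power grows linearly with
    valence.  The instantaneous gain g wanders slowly with a variance that
    increases as valence falls, which raises the Shannon entropy of the
    asymmetry series for low-valence trials.
    """
    beta_high = BANDS["beta"].high
    if config.eeg_rate <= 2 * beta_high:
        raise ValueError(
            f"eeg_rate {config.eeg_rate} Hz below Nyquist for the beta band"
        )
    rng = stage_rng(config.seed, "eeg")
    rate = config.eeg_rate
    n = int(round(latent.times[-1] * rate)) + 1
    t = np.arange(n) / rate
    v = np.interp(t, latent.times, latent.valence)

    # disorder mechanism: the asymmetry drive carries a slow, zero-mean,
    # constant-envelope oscillatory wander (frequency drifting around
    # ~0.1 Hz) whose amplitude grows steeply as valence falls.  A
    # constant-envelope wander spreads the within-trial asymmetry
    # distribution towards its range edges, which is what raises its
    # Shannon entropy; Gaussian wander would leave the marginal Gaussian
    # and the entropy unchanged.
    dt_c = 1.0 / config.affect_rate
    freq_walk = _ar1(rng, latent.times.size, dt_c, config.gain_noise_tau * 4, 1.0)
    freq = 0.08 + 0.12 / (1.0 + np.exp(-freq_walk))  # slowly drifting, 0.08-0.2 Hz
    phase = 2.0 * np.pi * np.cumsum(freq) * dt_c + rng.uniform(0.0, 2.0 * np.pi)
    eta = np.interp(t, latent.times, np.sin(phase))
    g0 = config.coupling.eeg_valence_gain
    sigma_g = config.coupling.entropy_gain * np.clip((1.0 - v) / 2.0, 0.0, 1.0) ** 2
    drive = 0.95 * np.tanh(g0 * (v + sigma_g * eta))

    # high-valence trials additionally show sparse, large, transient power
    # excursions (approach-related desynchronisation bursts), independently
    # in each hemisphere.  Heavy-tailed excursions stretch the within-trial
    # asymmetry range while the bulk stays tight, which *lowers* the
    # histogram entropy -- the complement of the low-valence wander.
    v_coarse = np.interp(latent.times, latent.times, latent.valence)
    burst_amp = config.burst_gain * np.clip((1.0 + v_coarse) / 2.0, 0.0, 1.0) ** 2
    bursts = []
    for _ in range(2):
        b = np.zeros(latent.times.size)
        hits = rng.random(latent.times.size) < config.burst_rate / config.affect_rate
        b[hits] = rng.exponential(1.0, hits.sum())
        width = max(3, int(round(config.affect_rate)))  # ~1 s smear
        kern = np.hanning(width)
        b = np.convolve(b, kern, mode="same") * burst_amp
        bursts.append(np.interp(t, latent.times, b))
    spike_left, spike_right = bursts

    mod_left = np.sqrt((1.0 + drive) * (1.0 + spike_left))
    mod_right = np.sqrt((1.0 - drive) * (1.0 + spike_right))

    samples = np.empty((len(config.channel_labels), n))
    for ci, label in enumerate(config.channel_labels):
        x = np.zeros(n)
        for bname, band in BANDS.items():
            amp = config.band_amplitudes.get(bname, 0.0)
            if amp == 0.0:
                continue
            comp = amp * _band_oscillation(rng, n, rate, band.low, band.high)
            if bname in ("alpha", "beta"):
                if label == "F3":
                    comp = comp * mod_left
                elif label == "F4":
                    comp = comp * mod_right
            x += comp
        if config.noise_sd_eeg > 0:
            x = x + rng.normal(0.0, config.noise_sd_eeg, size=n)
        samples[ci] = x
    return EegRecording(samples=samples, rate=rate, labels=config.channel_labels)


# ---------------------------------------------------------------------------
# BOLD


def movement_boxcar(schedule: TrialSchedule, n_volumes: int, tr: float) -> np.ndarray:
    """1 during trials that involve joystick reporting, 0 elsewhere (TR grid)."""
    times = np.arange(n_volumes) * tr
    box = np.zeros(n_volumes)
    for t in schedule.of_type(*REPORTING_TYPES):
        box[(times >= t.onset) & (times < t.end)] = 1.0
    return box


def n_volumes_for(schedule: TrialSchedule, config: SimulationConfig) -> int:
    return int(np.ceil((schedule.end_time + config.post_rest) / config.tr))


def generate_bold(
    latent: AffectTrajectory,
    eeg_features: dict[str, np.ndarray],
    schedule: TrialSchedule,
    config: SimulationConfig,
) -> tuple[BoldSeries, GroundTruth]:
    """BOLD volume series with HRF-coupled ROIs, drift and Gaussian noise.

    ``eeg_features`` supplies measured EEG-derived drivers on the TR grid
    (keys ``asymmetry`` and/or ``entropy``) so that EEG-coupled ROIs follow
    the *measured* feature, exactly as the fusion analyses assume.
    """
    from .glm import canonical_hrf, convolve_regressor

    rng = stage_rng(config.seed, "bold")
    config.coupling.validate(config.volume_shape)
    n_vol = n_volumes_for(schedule, config)
    vol_times = np.arange(n_vol) * config.tr

    raw_drivers: dict[str, np.ndarray] = {
        "valence": np.interp(vol_times, latent.times, latent.valence),
        "arousal": np.interp(vol_times, latent.times, latent.arousal),
        "movement": movement_boxcar(schedule, n_vol, config.tr),
    }
    for key in ("asymmetry", "entropy"):
        if key in eeg_features:
            feat = np.asarray(eeg_features[key], dtype=float)
            if feat.shape != (n_vol,):
                raise ValueError(
                    f"eeg feature {key!r} must be on the TR grid ({n_vol} volumes)"
                )
            raw_drivers[key] = feat

    kernel = canonical_hrf(dt=config.tr)
    signals: dict[str, np.ndarray] = {}
    for name, series in raw_drivers.items():
        conv = convolve_regressor(series, kernel)
        sd = conv.std()
        signals[name] = (conv - conv.mean()) / sd if sd > 0 else conv - conv.mean()

    shape = config.volume_shape
    data = rng.normal(0.0, config.noise_sd_bold, size=(*shape, n_vol))

    if config.drift_order >= 0:
        x = np.linspace(-1.0, 1.0, n_vol)
        basis = np.stack(
            [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(config.drift_order + 1)]
        )
        n_vox = int(np.prod(shape))
        coeffs = rng.normal(0.0, config.drift_sd, size=(n_vox, config.drift_order + 1))
        data += (coeffs @ basis).reshape(*shape, n_vol)

    masks = config.coupling.masks(shape)
    for roi in config.coupling.rois:
        if roi.amplitude == 0.0:
            continue
        if roi.driver not in signals:
            raise ValueError(
                f"ROI {roi.name!r} needs driver {roi.driver!r}, not provided"
            )
        data[masks[roi.name]] += roi.amplitude * signals[roi.driver]

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    bold = BoldSeries(data=data, tr=config.tr, affine=affine)
    truth = GroundTruth(
        seed=config.seed,
        roi_masks=masks,
        roi_drivers={r.name: r.driver for r in config.coupling.rois},
        roi_amplitudes={r.name: r.amplitude for r in config.coupling.rois},
        signals=signals,
        eeg_valence_gain=config.coupling.eeg_valence_gain,
        entropy_gain=config.coupling.entropy_gain,
    )
    return bold, truth
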