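"""Generator behaviour: schedules, affect traces, EEG coupling, BOLD."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectfuse.synth import (
    AffectTrajectory,
    CouplingSpec,
    RoiCoupling,
    SimulationConfig,
    circumplex_target,
    default_coupling,
    generate_affect,
    generate_bold,
    generate_eeg,
    generate_schedule,
)


def _cfg(**kw) -> SimulationConfig:
    base = dict(seed=1, n_trials=6, eeg_rate=128.0, volume_shape=(6, 6, 6))
    base.update(kw)
    if "coupling" not in base:
        base["coupling"] = default_coupling(base["volume_shape"])
    return SimulationConfig(**base)


class TestSchedule:
    def test_full_session_shape(self):
        cfg = _cfg(n_trials=36, seed=7)
        sched = generate_schedule(cfg)
        assert len(sched) == 36
        assert all(t.duration == 40.0 for t in sched.trials)
        assert all(1 <= t.target_region_1 <= 9 for t in sched.trials)
        assert all(t.target_region_1 != t.target_region_2 for t in sched.trials)

    def test_seeded_determinism(self):
        cfg = _cfg(n_trials=36, seed=7)
        assert generate_schedule(cfg) == generate_schedule(cfg)

    def test_replay_precedence_forced_with_three_trials(self):
        sched = generate_schedule(_cfg(n_trials=3))
        order = [t.trial_type for t in sched.trials]
        assert order.index("music_reporting") < order.index("reporting_only")

    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    @settings(max_examples=40, deadline=None)
    def test_constraint_and_timing_hold_for_any_seed(self, seed, n):
        sched = generate_schedule(_cfg(seed=seed, n_trials=n))
        heard = set()
        prev_end = -np.inf
        for t in sched.trials:
            assert t.onset >= prev_end
            assert 0.0 <= t.jitter <= 2.0
            prev_end = t.end
            if t.trial_type == "music_reporting":
                heard.add(t.stimulus_id)
            elif t.trial_type == "reporting_only":
                assert t.stimulus_id in heard

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="n_trials"):
            _cfg(n_trials=2)

    def test_region_grid_mapping(self):
        assert circumplex_target(1, 0.5) == (-0.5, -0.5)
        assert circumplex_target(5, 0.5) == (0.0, 0.0)
        assert circumplex_target(9, 0.5) == (0.5, 0.5)
        with pytest.raises(ValueError):
            circumplex_target(0, 0.5)


class TestAffect:
    def test_zero_noise_zero_lag_report_equals_latent(self):
        cfg = _cfg(latent_noise_sd=0.0, report_noise_sd=0.0, report_lag=0.0)
        sched = generate_schedule(cfg)
        latent, reported = generate_affect(sched, cfg)
        np.testing.assert_allclose(reported.valence[:_first_replay(sched, cfg)],
                                   latent.valence[:_first_replay(sched, cfg)])

    def test_negative_lag_rejected(self):
        cfg = _cfg(report_lag=-1.0)
        sched = generate_schedule(cfg)
        with pytest.raises(ValueError, match="report_lag"):
            generate_affect(sched, cfg)

    def test_half_targets_separate_latent_means(self):
        cfg = _cfg(latent_noise_sd=0.0, report_noise_sd=0.0, report_lag=0.0)
        sched = generate_schedule(cfg)
        latent, _ = generate_affect(sched, cfg)
        trial = next(t for t in sched.trials if t.target_1[0] != t.target_2[0])
        half = cfg.half_duration
        sel1 = (latent.times >= trial.onset) & (latent.times < trial.onset + half)
        sel2 = (latent.times >= trial.onset + half) & (latent.times < trial.end)
        assert latent.valence[sel1].mean() != pytest.approx(
            latent.valence[sel2].mean(), abs=1e-6
        )

    def test_values_always_clipped(self):
        cfg = _cfg(latent_noise_sd=2.0)
        sched = generate_schedule(cfg)
        latent, reported = generate_affect(sched, cfg)
        for traj in (latent, reported):
            assert np.abs(traj.valence).max() <= 1.0
            assert np.abs(traj.arousal).max() <= 1.0

    def test_trajectory_validation(self):
        with pytest.raises(ValueError, match="\\[-1, 1\\]"):
            AffectTrajectory(np.arange(3.0), np.array([0.0, 1.5, 0.0]), np.zeros(3))

    def test_reporting_only_replays_source_trace(self):
        cfg = _cfg(n_trials=6, report_noise_sd=0.0)
        sched = generate_schedule(cfg)
        _, reported = generate_affect(sched, cfg)
        ro = next(t for t in sched.trials if t.trial_type == "reporting_only")
        src = next(
            t for t in sched.trials
            if t.trial_type == "music_reporting" and t.stimulus_id == ro.stimulus_id
        )
        rate = cfg.affect_rate
        n = int(round(ro.duration * rate))
        seg_ro = reported.valence[int(round(ro.onset * rate)) :][:n]
        seg_src = reported.valence[int(round(src.onset * rate)) :][:n]
        np.testing.assert_allclose(seg_ro, seg_src)


def _first_replay(sched, cfg) -> int:
    ro = [t for t in sched.trials if t.trial_type == "reporting_only"]
    if not ro:
        return len(sched.trials)
    return int(round(ro[0].onset * cfg.affect_rate))


class TestEeg:
    def test_zero_gain_gives_unbiased_asymmetry(self):
        from affectfuse.affect_stats import trial_mean_asymmetry
        from affectfuse.eeg import BANDS, prefrontal_asymmetry

        cfg = _cfg(n_trials=12, seed=3)
        cfg.coupling.eeg_valence_gain = 0.0
        cfg.coupling.entropy_gain = 0.0
        cfg = replace(cfg, burst_gain=0.0)
        sched = generate_schedule(cfg)
        latent, _ = generate_affect(sched, cfg)
        eeg = generate_eeg(latent, sched, cfg)
        asym = prefrontal_asymmetry(eeg, BANDS["alpha"])
        means = np.array(list(trial_mean_asymmetry(asym, sched).values()))
        # trial-mean asymmetry should be statistically indistinguishable from 0
        t_stat = means.mean() / (means.std(ddof=1) / np.sqrt(means.size))
        assert abs(t_stat) < 3.5

    def test_constant_valence_flips_asymmetry_sign(self):
        from affectfuse.eeg import BANDS, prefrontal_asymmetry

        cfg = _cfg(noise_sd_eeg=0.0, burst_gain=0.0)
        cfg.coupling.entropy_gain = 0.0
        sched = generate_schedule(cfg)
        latent, _ = generate_affect(sched, cfg)
        means = {}
        for v in (1.0, -1.0):
            const = AffectTrajectory(
                latent.times, np.full_like(latent.valence, v),
                np.zeros_like(latent.arousal),
            )
            eeg = generate_eeg(const, sched, cfg)
            asym = prefrontal_asymmetry(eeg, BANDS["alpha"])
            means[v] = asym.values.mean()
        assert means[1.0] > 0 > means[-1.0]
        assert means[1.0] == pytest.approx(-means[-1.0], rel=0.15)

    def test_low_rate_rejected(self):
        cfg = _cfg()
        cfg = replace(cfg, eeg_rate=32.0)
        sched = generate_schedule(cfg)
        latent, _ = generate_affect(sched, cfg)
        with pytest.raises(ValueError, match="Nyquist"):
            generate_eeg(latent, sched, cfg)


class TestBold:
    def test_overlapping_rois_rejected(self):
        rois = (
            RoiCoupling("a", "valence", (0, 0, 0), (3, 3, 3), 1.0),
            RoiCoupling("b", "arousal", (2, 2, 2), (3, 3, 3), 1.0),
        )
        with pytest.raises(ValueError, match="disjoint"):
            CouplingSpec(rois=rois).validate((6, 6, 6))

    def test_roi_outside_volume_rejected(self):
        roi = RoiCoupling("a", "valence", (5, 5, 5), (3, 3, 3), 1.0)
        with pytest.raises(ValueError, match="fit inside"):
            roi.mask((6, 6, 6))

    def test_missing_feature_driver_rejected(self):
        cfg = _cfg()
        sched = generate_schedule(cfg)
        latent, _ = generate_affect(sched, cfg)
        with pytest.raises(ValueError, match="asymmetry"):
            generate_bold(latent, {}, sched, cfg)

    def test_null_volume_is_just_noise_and_drift(self):
        cfg = _cfg(drift_order=-1)
        cfg = replace(
            cfg,
            coupling=CouplingSpec(
                rois=(RoiCoupling("null", "valence", (0, 0, 0), (2, 2, 2), 0.0),)
            ),
        )
        sched = generate_schedule(cfg)
        latent, _ = generate_affect(sched, cfg)
        bold, truth = generate_bold(latent, {}, sched, cfg)
        flat = bold.flat()
        assert abs(flat.mean()) < 0.05
        assert flat.std() == pytest.approx(cfg.noise_sd_bold, rel=0.05)
        assert truth.roi_amplitudes["null"] == 0.0

    def test_dataset_determinism(self, small_config):
        from affectfuse.fusion import simulate_dataset

        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        np.testing.assert_array_equal(a.bold.data, b.bold.data)
        np.testing.assert_array_equal(a.eeg.samples, b.eeg.samples)
        np.testing.assert_array_equal(a.latent.valence, b.latent.valence)
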