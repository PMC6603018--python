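"""Feature chain: referencing, filtering, Laplacians, band power, asymmetry."""

import numpy as np
import pytest

from affectfuse.eeg import (
    BANDS,
    BandDefinition,
    EegRecording,
    LAPLACIAN_LEFT,
    LaplacianMontage,
    asymmetry_series,
    bandpower_series,
    broadband_filter,
    common_average_reference,
    laplacian_derivation,
    prefrontal_asymmetry,
)
from affectfuse.synth import REQUIRED_CHANNELS

RATE = 128.0


def _rec(samples, labels=None):
    labels = labels or [f"ch{i}" for i in range(samples.shape[0])]
    return EegRecording(samples=samples, rate=RATE, labels=labels)


class TestCommonAverageReference:
    def test_zero_mean_input_unchanged(self):
        rec = _rec(np.array([[1.0, -2.0], [-1.0, 2.0]]))
        np.testing.assert_allclose(
            common_average_reference(rec).samples, rec.samples
        )

    def test_common_offset_removed(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 500))
        base -= base.mean(axis=0, keepdims=True)
        offset = 42.0 + np.sin(np.arange(500))
        rec = _rec(base + offset)
        np.testing.assert_allclose(
            common_average_reference(rec).samples, base, atol=1e-12
        )

    def test_columns_mean_zero(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((4, 1000)))
        out = common_average_reference(rec)
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            common_average_reference(_rec(np.zeros((1, 10))))


class TestBroadbandFilter:
    def test_passband_tone_preserved(self):
        t = np.arange(0, 20, 1 / RATE)
        rec = _rec(np.sin(2 * np.pi * 10 * t)[None, :], ["a"])
        out = broadband_filter(rec).samples[0][200:-200]
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_removed(self):
        t = np.arange(0, 60, 1 / RATE)
        rec = _rec(np.sin(2 * np.pi * 0.1 * t)[None, :], ["a"])
        out = broadband_filter(rec).samples[0][500:-500]
        # 0.1 Hz is a decade below the 1 Hz corner of a 3rd-order filter
        assert np.abs(out).max() < 0.1

    def test_dc_removed(self):
        rec = _rec(np.full((1, 2000), 7.0), ["a"])
        assert abs(broadband_filter(rec).samples.mean()) < 1e-6

    def test_nyquist_violation_rejected(self):
        rec = EegRecording(np.zeros((1, 100)), rate=80.0, labels=["a"])
        with pytest.raises(ValueError, match="too low"):
            broadband_filter(rec)


class TestLaplacian:
    def _recording(self):
        rng = np.random.default_rng(2)
        return EegRecording(
            rng.standard_normal((9, 400)), rate=RATE, labels=REQUIRED_CHANNELS
        )

    def test_centre_equal_to_reference_mean_is_zero(self):
        rec = self._recording()
        refs = np.stack([rec.channel(c) for c in LAPLACIAN_LEFT.references])
        rec.samples[rec.labels.index("F3")] = refs.mean(axis=0)
        np.testing.assert_allclose(
            laplacian_derivation(rec, LAPLACIAN_LEFT), 0.0, atol=1e-12
        )

    def test_zero_references_pass_centre_through(self):
        rec = self._recording()
        for c in LAPLACIAN_LEFT.references:
            rec.samples[rec.labels.index(c)] = 0.0
        np.testing.assert_allclose(
            laplacian_derivation(rec, LAPLACIAN_LEFT), rec.channel("F3")
        )

    def test_matches_hand_computed_arithmetic(self):
        rec = self._recording()
        expected = rec.channel("F3") - (
            rec.channel("FP1") + rec.channel("F7") + rec.channel("Fz") + rec.channel("C3")
        ) / 4.0
        np.testing.assert_allclose(
            laplacian_derivation(rec, LAPLACIAN_LEFT), expected, atol=1e-12
        )

    def test_missing_channel_named_in_error(self):
        rec = _rec(np.zeros((2, 10)), ["F3", "Fz"])
        with pytest.raises(KeyError, match="FP1"):
            laplacian_derivation(rec, LAPLACIAN_LEFT)

    def test_centre_cannot_reference_itself(self):
        with pytest.raises(ValueError):
            LaplacianMontage("F3", ("F3", "Fz"))


class TestBandPower:
    def test_unit_sine_has_half_power(self):
        t = np.arange(0, 30, 1 / RATE)
        x = np.sin(2 * np.pi * 10 * t)
        ps = bandpower_series(x, RATE, BANDS["alpha"], window=2.0, step=2.0)
        assert np.median(ps.values) == pytest.approx(0.5, rel=0.05)

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(0, 30, 1 / RATE)
        in_band = bandpower_series(
            np.sin(2 * np.pi * 10 * t), RATE, BANDS["alpha"], 2.0, 2.0
        )
        out_band = bandpower_series(
            np.sin(2 * np.pi * 25 * t), RATE, BANDS["alpha"], 2.0, 2.0
        )
        assert np.median(out_band.values) <= 0.05 * np.median(in_band.values)

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(30 * RATE))
        p1 = bandpower_series(x, RATE, BANDS["beta"], 2.0, 2.0)
        p2 = bandpower_series(2 * x, RATE, BANDS["beta"], 2.0, 2.0)
        np.testing.assert_allclose(p2.values, 4 * p1.values, rtol=1e-10)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="longer than series"):
            bandpower_series(np.zeros(64), RATE, BANDS["alpha"], window=2.0, step=1.0)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 10.0, 5.0)


class TestAsymmetry:
    def _powers(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(30 * RATE))
        y = rng.standard_normal(int(30 * RATE))
        l = bandpower_series(x, RATE, BANDS["alpha"], 2.0, 2.0)
        r = bandpower_series(y, RATE, BANDS["alpha"], 2.0, 2.0)
        return l, r

    def test_identical_inputs_zero(self):
        l, _ = self._powers()
        assert np.all(asymmetry_series(l, l).values == 0.0)

    def test_exact_antisymmetry(self):
        l, r = self._powers()
        np.testing.assert_array_equal(
            asymmetry_series(l, r).values, -asymmetry_series(r, l).values
        )

    def test_length_mismatch_rejected(self):
        l, r = self._powers()
        r.values = r.values[:-1]
        r.times = r.times[:-1]
        with pytest.raises(ValueError, match="length"):
            asymmetry_series(l, r)

    def test_pipeline_quadratic_in_recording_scale(self, eeg_session):
        _, _, _, _, eeg = eeg_session
        a1 = prefrontal_asymmetry(eeg, BANDS["alpha"], window=2.0, step=2.0)
        scaled = EegRecording(3.0 * eeg.samples, eeg.rate, eeg.labels)
        a3 = prefrontal_asymmetry(scaled, BANDS["alpha"], window=2.0, step=2.0)
        np.testing.assert_allclose(a3.values, 9.0 * a1.values, rtol=1e-8)

    def test_valence_coupling_recovered_in_rank_order(self, eeg_session):
        from scipy.stats import spearmanr

        from affectfuse.affect_stats import trial_mean_asymmetry

        cfg, schedule, latent, _, eeg = eeg_session
        asym = prefrontal_asymmetry(eeg, BANDS["alpha"], window=2.0, step=2.0)
        means = trial_mean_asymmetry(asym, schedule)
        trial_valence = {}
        for idx, trial in enumerate(schedule.trials):
            if trial.is_music:
                sel = (latent.times >= trial.onset) & (latent.times < trial.end)
                trial_valence[idx] = latent.valence[sel].mean()
        rho = spearmanr(
            [trial_valence[i] for i in means], [means[i] for i in means]
        ).statistic
        assert rho > 0.5
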