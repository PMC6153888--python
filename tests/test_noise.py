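"""Stimulus-noise audit: filtering, SNR, differential thresholds, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

import distaniso as da
from distaniso.noise import (
    IMURecording,
    ThresholdModel,
    differential_threshold,
    noise_rms,
    read_imu_csv,
    two_way_anova,
    write_imu_csv,
)


def _recording(cmd, rec, rate=1000.0, **label):
    n = len(cmd)
    return IMURecording(
        time=np.arange(n) / rate,
        commanded=np.asarray(cmd, float),
        recorded=np.asarray(rec, float),
        sample_rate=rate,
        label=label or {"direction_deg": 0.0, "phase": "target", "repeat": 1},
    )


class TestPreprocessImu:
    def test_dc_offset_removed_entirely(self):
        cmd = np.zeros((4000, 3))
        rec = cmd + np.array([9.81, 0.1, -0.2])
        out = da.preprocess_imu(_recording(cmd, rec))
        assert np.allclose(out.recorded, 0.0, atol=1e-9)

    @pytest.mark.parametrize("freq,band", [(10.0, "pass"), (100.0, "stop")])
    def test_sinusoid_attenuation_matches_filter_response(self, freq, band):
        rate = 1000.0
        t = np.arange(20000) / rate
        tone = np.sin(2 * np.pi * freq * t)
        cmd = np.zeros((len(t), 3))
        rec = np.stack([tone, np.zeros_like(t), np.zeros_like(t)], axis=1)
        out = da.preprocess_imu(_recording(cmd, rec, rate=rate))
        mid = slice(5000, 15000)
        measured = np.std(out.recorded[mid, 0]) / np.std(tone[mid])
        sos = sp_signal.butter(4, 80.0, btype="low", fs=rate, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[freq], fs=rate)
        expected = np.abs(h[0]) ** 2  # forward-backward application squares |H|
        assert measured == pytest.approx(expected, rel=0.02)
        if band == "pass":
            assert measured > 0.98
        else:
            assert measured < 0.2

    def test_rate_too_low_rejected(self):
        cmd = np.zeros((100, 3))
        with pytest.raises(ValueError, match="cutoff"):
            da.preprocess_imu(_recording(cmd, cmd, rate=150.0))


class TestSnr:
    def test_equal_signal_and_noise_rms_gives_one(self):
        rng = np.random.default_rng(0)
        cmd = np.zeros((5000, 3))
        cmd[:, 0] = np.sin(np.linspace(0, 20 * np.pi, 5000))
        noise = rng.standard_normal(cmd.shape)
        cmd_rms = np.sqrt(np.mean(np.linalg.norm(cmd, axis=1) ** 2))
        noise_norm_rms = np.sqrt(np.mean(np.linalg.norm(noise, axis=1) ** 2))
        rec = cmd + noise * (cmd_rms / noise_norm_rms)
        assert da.snr(_recording(cmd, rec)) == pytest.approx(1.0, rel=1e-6)

    def test_perfect_recording_is_infinite_sentinel(self):
        cmd = np.ones((100, 3))
        assert da.snr(_recording(cmd, cmd.copy())) == np.inf

    def test_zero_command_gives_zero(self):
        cmd = np.zeros((100, 3))
        rec = cmd + 0.1
        assert da.snr(_recording(cmd, rec)) == 0.0

    def test_closed_form_for_iid_gaussian_noise(self):
        profile = da.target_profile(1.5, sample_rate=2000.0)  # 6001 samples
        rec = da.synthesize_imu(profile, 30.0, noise_sd_per_axis=0.05, seed=12)
        expected = (np.sqrt(np.mean(profile.acceleration**2)) / (0.05 * np.sqrt(3))) ** 2
        assert da.snr(rec) == pytest.approx(expected, rel=0.05)

    def test_scale_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(5)
        cmd = np.zeros((4000, 3))
        cmd[:, 0] = np.sin(np.linspace(0, 12 * np.pi, 4000))
        noise = 0.05 * rng.standard_normal(cmd.shape)
        base = da.snr(_recording(cmd, cmd + noise))
        both = da.snr(_recording(3 * cmd, 3 * cmd + 3 * noise))
        only_cmd = da.snr(_recording(3 * cmd, 3 * cmd + noise))
        assert both == pytest.approx(base, rel=1e-9)
        assert only_cmd == pytest.approx(9 * base, rel=1e-9)


class TestDifferentialThreshold:
    def test_pure_axis_functions(self):
        assert differential_threshold(1.0, 0.0) == pytest.approx(0.08)
        assert differential_threshold(1.0, 180.0) == pytest.approx(0.08)
        assert differential_threshold(1.0, 90.0) == pytest.approx(0.19)
        assert differential_threshold(1.0, -90.0) == pytest.approx(0.17)
        assert differential_threshold(2.0, 90.0) == pytest.approx(0.19 * 2**0.60)
        assert differential_threshold(2.0, -90.0) == pytest.approx(0.17 * 2**0.42)

    @pytest.mark.parametrize("I", [0.0, 0.3, 1.0, 2.5])
    def test_combined_form_reduces_to_horizontal_at_zero(self, I):
        assert differential_threshold(I, 0.0, mode="literal") == pytest.approx(
            0.05 * I + 0.03
        )

    def test_literal_form_keeps_offset_at_pure_vertical(self):
        # as printed, the horizontal offset persists inside the root at +-90
        literal = differential_threshold(1.0, 90.0, mode="literal")
        assert literal == pytest.approx(np.sqrt(0.03**2 + 0.19**2))
        assert literal > differential_threshold(1.0, 90.0, mode="shortcut")

    def test_opposite_vertical_term_zeroed(self):
        up = differential_threshold(1.0, 30.0)
        expected = np.sqrt(
            (np.cos(np.deg2rad(30)) * 0.05 + 0.03) ** 2
            + (np.sin(np.deg2rad(30)) * 0.19) ** 2
        )
        assert up == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [0, 30, 90, -90, 150, 180, -45])
    def test_monotone_in_intensity(self, alpha):
        I = np.linspace(0.0, 3.0, 200)
        out = differential_threshold(I, alpha)
        assert np.all(np.diff(out) >= 0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            differential_threshold(-0.1, 0.0)

    def test_invalid_threshold_model_rejected(self):
        with pytest.raises(ValueError):
            ThresholdModel(upward_exponent=1.4)


class TestNoiseVsThreshold:
    def _recordings(self, noise_target, noise_test, directions=(0.0, 90.0), seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for d in directions:
            for distance in (0.5, 1.5):
                recs.append(da.synthesize_imu(
                    da.target_profile(distance, sample_rate=400.0), d, noise_target,
                    seed=rng, target_distance=distance, phase="target",
                ))
            test_prof = da.build_test_profile(da.solve_test_profile(1.55, 5.0, 2.5), 400.0)
            recs.append(da.synthesize_imu(test_prof, d, noise_test, seed=rng, phase="test"))
        return recs

    def test_equal_noise_levels_all_sub_threshold(self):
        audit = da.noise_vs_threshold(self._recordings(0.02, 0.02))
        assert len(audit.table) == 2
        assert audit.all_sub_threshold()
        assert audit.gaps == []

    def test_large_injected_difference_flagged_perceivable(self):
        recs = self._recordings(0.02, 1.5, directions=(0.0,))
        audit = da.noise_vs_threshold(recs)
        row = audit.table.iloc[0]
        assert row["noise_rms_diff"] > 10 * row["lowest_threshold"]
        assert not row["sub_threshold"]

    def test_missing_phase_reported_as_gap(self):
        recs = self._recordings(0.02, 0.02, directions=(0.0,))
        only_targets = [r for r in recs if r.label["phase"] == "target"]
        audit = da.noise_vs_threshold(only_targets)
        assert audit.table.empty
        assert audit.gaps == [{"orientation": "upright", "direction_deg": 0.0, "missing": "test"}]


class TestTwoWayAnova:
    def _layout(self, n_rep=5):
        dirs = np.repeat(np.arange(-150, 181, 30), 2 * n_rep)
        orients = np.tile(np.repeat(["upright", "pitch30"], n_rep), 12)
        return dirs, orients

    def test_constant_values_report_null_result(self):
        dirs, orients = self._layout()
        table = two_way_anova(np.full(len(dirs), 3.3), dirs, orients)
        assert table.loc["direction", "F"] == 0.0
        assert table.loc["direction", "p"] == 1.0

    def test_pure_direction_effect_without_noise(self):
        dirs, orients = self._layout()
        values = np.cos(np.deg2rad(dirs))
        table = two_way_anova(values, dirs, orients)
        assert np.isinf(table.loc["direction", "F"])
        assert table.loc["direction", "p"] == 0.0
        assert table.loc["orientation", "F"] == 0.0

    def test_detects_direction_effect_in_noise(self):
        rng = np.random.default_rng(8)
        dirs, orients = self._layout()
        values = 0.5 * np.cos(np.deg2rad(dirs)) + rng.normal(0, 0.3, len(dirs))
        table = two_way_anova(values, dirs, orients)
        assert table.loc["direction", "p"] < 0.001
        assert table.loc["orientation", "p"] > 0.01

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(9)
        dirs, orients = self._layout(n_rep=3)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            table = two_way_anova(rng.standard_normal(len(dirs)), dirs, orients)
            hits += table.loc["direction", "p"] < 0.05
        rate = hits / n_rep
        assert 0.02 <= rate <= 0.08

    def test_empty_cells_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            two_way_anova([1.0, 2.0, 3.0], [0, 0, 30], ["upright", "pitch30", "upright"])

    def test_unbalanced_layout_rejected(self):
        dirs = [0, 0, 0, 30, 30, 30]
        orients = ["upright", "upright", "pitch30", "upright", "pitch30", "pitch30"]
        with pytest.raises(ValueError, match="balanced|unbalanced"):
            two_way_anova(np.arange(6.0), dirs, orients)


class TestSynthesizeImu:
    def test_vertical_direction_has_no_horizontal_command(self):
        rec = da.synthesize_imu(da.target_profile(1.0, sample_rate=200.0), 90.0, 0.01, seed=0)
        assert np.allclose(rec.commanded[:, 0], 0.0, atol=1e-12)
        assert np.allclose(rec.commanded[:, 1], 0.0)

    def test_zero_noise_gives_infinite_snr(self):
        rec = da.synthesize_imu(da.target_profile(1.0, sample_rate=200.0), 0.0, 0.0, seed=0)
        assert da.snr(rec) == np.inf

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            da.synthesize_imu(da.target_profile(1.0, sample_rate=200.0), 0.0, -0.1)


def test_imu_csv_round_trip(tmp_path):
    rec = da.synthesize_imu(
        da.target_profile(0.9, sample_rate=250.0), 60.0, 0.03, seed=4,
        target_distance=0.9, phase="target", repeat=2,
    )
    path = tmp_path / "trace.csv"
    write_imu_csv(rec, path)
    back = read_imu_csv(path)
    np.testing.assert_allclose(back.recorded, rec.recorded, atol=1e-10)
    assert back.label["phase"] == "target"
    assert back.label["repeat"] == 2
    assert noise_rms(back) == pytest.approx(noise_rms(rec), rel=1e-9)
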