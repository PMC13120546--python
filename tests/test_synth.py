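"""Synthetic sensor generator: determinism, calibration and constructed
statistical structure."""

import numpy as np
import pandas as pd
import pytest

from gaitwalker import symmetry, synth
from gaitwalker.synth import (
    StrideGroupConfig,
    SubjectProfile,
    default_stride_config,
    generate_accel_sequence,
    generate_emg,
    generate_force_pair,
    generate_stride_series,
    recovery_progress,
    target_fsi,
)


class TestRecoveryTrajectory:
    def test_subject1_anchor_days(self):
        """The exponential trajectory passes through the three published
        Subject-1 FSI values (days 1, 7 and 15)."""
        p = SubjectProfile("Subject 1", 0.953, 0.153)
        assert target_fsi(p, 1, 15) == pytest.approx(0.953, abs=1e-12)
        assert target_fsi(p, 7, 15) == pytest.approx(0.752, abs=5e-4)
        assert target_fsi(p, 15, 15) == pytest.approx(0.153, abs=1e-12)

    def test_monotone_decreasing_both_shapes(self):
        for shape in ("exponential", "linear"):
            p = SubjectProfile("s", 0.95, 0.2, recovery_shape=shape)
            vals = [target_fsi(p, d, 15) for d in range(1, 16)]
            assert (np.diff(vals) < 0).all()

    def test_progress_endpoints(self):
        assert recovery_progress(1, 15) == pytest.approx(0.0, abs=1e-12)
        assert recovery_progress(15, 15) == pytest.approx(1.0, abs=1e-12)
        assert recovery_progress(8, 15, shape="linear") == pytest.approx(0.5)


class TestDeterminism:
    def test_force_streams_bit_identical(self, noisy_cohort):
        p = noisy_cohort.subjects[0]
        a = generate_force_pair(p, 3, noisy_cohort)
        b = generate_force_pair(p, 3, noisy_cohort)
        pd.testing.assert_frame_equal(a, b)

    def test_streams_differ_across_days_and_subjects(self, noisy_cohort):
        p, q = noisy_cohort.subjects[:2]
        a = generate_force_pair(p, 3, noisy_cohort)
        b = generate_force_pair(p, 4, noisy_cohort)
        c = generate_force_pair(q, 3, noisy_cohort)
        assert not np.allclose(a["f_right_n"], b["f_right_n"])
        assert not np.allclose(a["f_right_n"], c["f_right_n"])

    def test_emg_accel_stride_bit_identical(self, noisy_cohort):
        p = noisy_cohort.subjects[0]
        e1 = generate_emg(p, 2, noisy_cohort, duration_s=1.0)
        e2 = generate_emg(p, 2, noisy_cohort, duration_s=1.0)
        np.testing.assert_array_equal(e1.samples, e2.samples)
        s1, t1 = generate_accel_sequence([("upright", 1.0)], fs=100, seed=7)
        s2, t2 = generate_accel_sequence([("upright", 1.0)], fs=100, seed=7)
        pd.testing.assert_frame_equal(s1, s2)
        assert t1 == t2
        cfg = default_stride_config("control", seed=11)
        np.testing.assert_array_equal(generate_stride_series(cfg).intervals_s,
                                      generate_stride_series(cfg).intervals_s)


class TestForcePair:
    def test_zero_noise_session_fsi_exact(self, clean_cohort):
        p = clean_cohort.subjects[0]
        df = generate_force_pair(p, 1, clean_cohort)
        assert symmetry.session_fsi(df) == pytest.approx(p.fsi_day1, abs=1e-12)

    def test_fully_symmetric_profile_identical_channels(self, clean_cohort):
        p = SubjectProfile("sym", 0.0, 0.0)
        df = generate_force_pair(p, 5, clean_cohort)
        np.testing.assert_allclose(df["f_right_n"], df["f_left_n"])

    def test_day_out_of_range_rejected(self, clean_cohort):
        with pytest.raises(ValueError, match="day"):
            generate_force_pair(clean_cohort.subjects[0], 16, clean_cohort)

    def test_physical_ranges(self, noisy_cohort):
        df = generate_force_pair(noisy_cohort.subjects[0], 1, noisy_cohort)
        assert (df["f_right_n"] >= 0).all() and (df["f_left_n"] >= 0).all()
        for c in ("adc_right", "adc_left"):
            assert df[c].between(0, 1023).all()
            assert df[c].dtype.kind == "i"

    def test_published_table_reproduced_at_endpoints(self, clean_cohort):
        """Zero-noise generation reproduces every published Day-1/Day-15 FSI
        to 4 decimals through the symmetry module."""
        for p in clean_cohort.subjects:
            d1 = symmetry.session_fsi(generate_force_pair(p, 1, clean_cohort))
            d15 = symmetry.session_fsi(
                generate_force_pair(p, clean_cohort.n_days, clean_cohort))
            assert round(d1, 4) == round(p.fsi_day1, 4)
            assert round(d15, 4) == round(p.fsi_day15, 4)

    def test_noisy_day1_cohort_mean_near_published(self, noisy_cohort):
        fsis = [symmetry.session_fsi(generate_force_pair(p, 1, noisy_cohort))
                for p in noisy_cohort.subjects]
        assert np.mean(fsis) == pytest.approx(0.9691, abs=0.02)


class TestEMGGeneration:
    def test_clean_amplitude_hits_target(self, clean_cohort):
        p = clean_cohort.subjects[0]
        rec = generate_emg(p, 1, clean_cohort, drift_amplitude_mv=0.0,
                           hf_amplitude_mv=0.0, duration_s=2.0)
        target = synth.target_emg_mv(p, 1, clean_cohort.n_days)
        assert np.mean(np.abs(rec.samples)) == pytest.approx(target, rel=1e-9)

    def test_cohort_day_targets_match_published_means(self, clean_cohort):
        n = clean_cohort.n_days
        day1 = np.mean([synth.target_emg_mv(p, 1, n) for p in clean_cohort.subjects])
        day15 = np.mean([synth.target_emg_mv(p, n, n) for p in clean_cohort.subjects])
        assert day1 == pytest.approx(0.885, abs=1e-12)
        assert day15 == pytest.approx(5.138, abs=1e-12)

    def test_contamination_adds_out_of_band_power(self, clean_cohort):
        p = clean_cohort.subjects[0]
        clean = generate_emg(p, 1, clean_cohort, 0.0, 0.0, duration_s=1.0)
        dirty = generate_emg(p, 1, clean_cohort, duration_s=1.0)
        assert np.std(dirty.samples) > np.std(clean.samples)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile("bad", 0.9, 0.1, emg_day1_mv=-1.0, emg_day15_mv=2.0)


class TestAccelSequence:
    def test_upright_zero_noise_tilt_zero(self):
        stream, _ = generate_accel_sequence([("upright", 1.0)], fs=50,
                                            noise_sd_g=0.0)
        from gaitwalker.falls import tilt_angle
        tilt = tilt_angle(stream["ax_g"], stream["ay_g"], stream["az_g"])
        np.testing.assert_allclose(tilt, 0.0, atol=1e-9)

    def test_single_transition_ground_truth(self):
        _, truth = generate_accel_sequence([("upright", 2.0), ("falling", 1.0)],
                                           fs=100, noise_sd_g=0.0)
        assert truth == [(0.0, "upright"), (2.0, "falling")]

    def test_empty_and_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            generate_accel_sequence([], fs=100)
        with pytest.raises(ValueError):
            generate_accel_sequence([("flying", 1.0)], fs=100)
        with pytest.raises(ValueError):
            generate_accel_sequence([("upright", -1.0)], fs=100)


class TestStrideSeries:
    def test_zero_jitter_exactly_periodic(self):
        cfg = StrideGroupConfig("control", 1.1, 0.0, n_strides=10, seed=0)
        iv = generate_stride_series(cfg).intervals_s
        np.testing.assert_allclose(iv, 1.1)
        assert np.var(iv, ddof=1) <= 1e-28

    def test_interval_variance_matches_two_sigma_squared(self):
        cfg = StrideGroupConfig("control", 1.1, 0.05, n_strides=10_000, seed=3)
        iv = generate_stride_series(cfg).intervals_s
        assert np.var(iv, ddof=1) == pytest.approx(2 * 0.05**2, rel=0.05)

    def test_als_like_noisier_than_control_across_replicates(self):
        wins = 0
        for rep in range(200):
            a = generate_stride_series(default_stride_config("als_like", seed=rep))
            c = generate_stride_series(default_stride_config("control", seed=rep))
            wins += np.var(a.intervals_s, ddof=1) > np.var(c.intervals_s, ddof=1)
        assert wins >= 0.95 * 200

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            StrideGroupConfig("control", 1.1, -0.01)
        with pytest.raises(ValueError):
            StrideGroupConfig("control", 1.1, 0.01, n_strides=2)


def test_fsr_series_shape_and_convergence(noisy_cohort):
    df = synth.generate_fsr_resistance_series(noisy_cohort, n_points=300)
    assert list(df.columns) == ["x", "day", "r_right", "r_left"]
    # channels start far apart (high asymmetry) and converge toward 0.5
    gap = (df["r_right"] - df["r_left"]).to_numpy()
    assert gap[:20].mean() > 0.9
    assert gap[-20:].mean() < 0.3
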