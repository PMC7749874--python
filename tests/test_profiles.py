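"""Dose-rate profile analysis: window detection, theta, DM_Max, DM_Total."""

import numpy as np
import pytest

from oemdose.errors import DegenerateProfileError, InvalidInputError
from oemdose.oem import AngularOutputProfile
from oemdose.profiles import (
    DoseRateProfile,
    analyze_pair,
    detect_modulation_window,
    dm_max,
    dm_total,
    modulation_angle,
    read_profile_csv,
    synthesize_profile,
    write_profile_csv,
)


def square_dip_pair(depth_ratio=0.365, t_start=125.0, t_end=347.2, dt=1.0):
    """Flat OFF profile and an ON profile with a rectangular dip."""
    off = synthesize_profile(500.0, 10.0, None, dt_ms=dt)
    rates = off.dose_rates.copy()
    in_dip = (off.times_ms >= t_start) & (off.times_ms <= t_end)
    rates[in_dip] *= depth_ratio
    on = DoseRateProfile(off.times_ms, rates, rotation_period_ms=500.0)
    return on, off


class TestModulationWindow:
    def test_square_dip_window_matches_support(self):
        on, off = square_dip_pair()
        w = detect_modulation_window(on, off)
        assert w.t_drr_ms == pytest.approx(222.2, abs=1.0 + 1e-9)

    def test_identical_profiles_give_zero_length_window(self):
        off = synthesize_profile(500.0, 10.0, None)
        w = detect_modulation_window(off, off)
        assert w.t_drr_ms == 0.0

    def test_sub_threshold_dip_never_detected(self):
        # 0.5 % dip stays above the 1 % threshold at every sample
        on, off = square_dip_pair(depth_ratio=0.995)
        # independent brute-force check of the threshold rule
        ratio = on.dose_rates / off.dose_rates
        assert not np.any(ratio < 0.99 * np.median(ratio))
        assert detect_modulation_window(on, off).t_drr_ms == 0.0

    def test_all_zero_off_profile_rejected(self):
        t = np.arange(0.0, 601.0)
        off = DoseRateProfile(t, np.zeros_like(t))
        on = DoseRateProfile(t, np.ones_like(t))
        with pytest.raises(DegenerateProfileError):
            detect_modulation_window(on, off)

    def test_disjoint_profiles_rejected(self):
        a = DoseRateProfile(np.arange(0.0, 601.0), np.ones(601))
        b = DoseRateProfile(np.arange(1000.0, 1601.0), np.ones(601))
        with pytest.raises(InvalidInputError):
            detect_modulation_window(a, b)


class TestModulationAngle:
    @pytest.mark.parametrize(
        "t_drr,t_1rot,expected,tol",
        [
            (222.2, 500.0, 160.0, 0.05),
            (0.0, 500.0, 0.0, 0.0),
            (233.3, 525.0, 160.0, 0.05),  # 0.686 deg per ms at 525 ms/rot
        ],
    )
    def test_printed_values(self, t_drr, t_1rot, expected, tol):
        assert modulation_angle(t_drr, t_1rot) == pytest.approx(expected, abs=tol + 1e-12)

    def test_linear_and_scale_invariant(self, rng):
        for _ in range(50):
            t1 = rng.uniform(100.0, 1000.0)
            td = rng.uniform(0.0, t1)
            k = rng.uniform(0.1, 10.0)
            assert modulation_angle(td, t1) == pytest.approx(360.0 * td / t1)
            assert modulation_angle(k * td, k * t1) == pytest.approx(modulation_angle(td, t1))

    def test_t_drr_exceeding_rotation_rejected(self):
        with pytest.raises(InvalidInputError):
            modulation_angle(600.0, 500.0)


class TestModulationRatesFromProfiles:
    def test_square_dip_dm_max(self):
        on, off = square_dip_pair(depth_ratio=0.365)
        assert dm_max(on, off) == pytest.approx(63.5)

    def test_identical_profiles_zero(self):
        off = synthesize_profile(500.0, 10.0, None)
        assert dm_max(off, off) == 0.0
        assert dm_total(off, off) == 0.0

    def test_ratio_floor_080_gives_20_percent(self):
        on, off = square_dip_pair(depth_ratio=0.8)
        assert dm_max(on, off) == pytest.approx(20.0)

    def test_square_dip_dm_total_is_depth_times_arc_fraction(self):
        # 63.5 % deep over 160 of 360 degrees -> 63.5 * 160/360 = 28.2 %
        arc_ms = 160.0 / 360.0 * 500.0
        on, off = square_dip_pair(0.365, 250.0 - arc_ms / 2 + 25.0, 250.0 + arc_ms / 2 + 25.0, dt=0.1)
        assert dm_total(on, off) == pytest.approx(63.5 * 160.0 / 360.0, abs=0.05)


class TestSynthesizeProfile:
    def test_flat_profile(self):
        p = synthesize_profile(500.0, 10.0, None, startup_overhead_ms=0.0)
        assert np.all(p.dose_rates == 10.0)
        assert p.duration_ms == pytest.approx(500.0)

    def test_startup_overhead_extends_duration(self):
        p = synthesize_profile(500.0, 10.0, None, startup_overhead_ms=25.0)
        assert p.duration_ms == pytest.approx(525.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidInputError):
            synthesize_profile(500.0, 10.0, None, noise_sd=-1.0)

    def test_deterministic_for_seed(self):
        a = synthesize_profile(500.0, 10.0, None, noise_sd=0.5, seed=7)
        b = synthesize_profile(500.0, 10.0, None, noise_sd=0.5, seed=7)
        assert np.array_equal(a.dose_rates, b.dose_rates)


class TestRoundTrip:
    @pytest.mark.parametrize("dm,ratio,arc", [(63.5, 16.0 / 63.5, 160.0),
                                              (45.0, 0.3, 120.0),
                                              (70.0, 0.35, 200.0)])
    def test_analysis_recovers_generated_dip(self, dm, ratio, arc):
        dip = AngularOutputProfile("front", dm, dm * ratio, arc)
        on = synthesize_profile(500.0, 10.0, dip, dt_ms=0.1)
        off = synthesize_profile(500.0, 10.0, None, dt_ms=0.1)
        metrics, _ = analyze_pair(on, off)
        assert metrics.theta_deg == pytest.approx(arc, abs=0.2)
        assert metrics.dm_max_pct == pytest.approx(dm, abs=1e-3)
        assert metrics.dm_total_pct == pytest.approx(dm * ratio, abs=1e-3)

    def test_dm_total_never_exceeds_dm_max(self, rng):
        # Jensen-type bound across random dip shapes
        for _ in range(200):
            dm = rng.uniform(5.0, 90.0)
            arc = rng.uniform(60.0, 300.0)
            ratio = rng.uniform(0.15, 1.0) * arc / 360.0
            dip = AngularOutputProfile("front", dm, dm * ratio, arc)
            on = synthesize_profile(500.0, 10.0, dip, dt_ms=1.0)
            off = synthesize_profile(500.0, 10.0, None, dt_ms=1.0)
            assert dm_total(on, off) <= dm_max(on, off) + 1e-9


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path):
        p = synthesize_profile(500.0, 7.5, None, noise_sd=0.2, seed=3, label="OEM_OFF 80kV")
        path = tmp_path / "profile.csv"
        write_profile_csv(path, p, kV=80, mA=500)
        q = read_profile_csv(path)
        assert q.label == "OEM_OFF 80kV"
        assert q.rotation_period_ms == p.rotation_period_ms
        np.testing.assert_allclose(q.dose_rates, p.dose_rates, rtol=1e-6)

    def test_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            DoseRateProfile(np.array([0.0, 1.0, 1.5]), np.ones(3))  # non-uniform
        with pytest.raises(InvalidInputError):
            DoseRateProfile(np.arange(600.0), -np.ones(600))  # negative rates
        with pytest.raises(InvalidInputError):
            DoseRateProfile(np.arange(100.0), np.ones(100), rotation_period_ms=500.0)
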