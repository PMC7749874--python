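"""Calibrated OEM behaviour: current mapping, rate scaling, dip shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from oemdose.errors import InfeasibleShapeError, InvalidInputError
from oemdose.oem import (
    DEFAULT_CALIBRATION_ENTRIES,
    AngularOutputProfile,
    OEMCalibrationTable,
    OEMParameters,
    build_angular_profile,
    modulation_rates,
    oem_displayed_current,
    solve_taper_exponent,
)
from oemdose.profiles import analyze_pair, synthesize_profile

# every requested/displayed OEM_ON current pair printed in the clinical
# protocol table (rows A-H, three rotations each where applicable)
PRINTED_PROTOCOL_PAIRS = [
    (220, 187), (220, 187), (220, 187),
    (172, 149), (217, 185), (202, 172),
    (157, 138), (217, 185), (232, 198),
    (110, 103), (120, 110), (110, 103),
    (100, 95), (110, 103), (105, 99),
    (115, 107), (145, 129), (125, 114),
    (85, 84), (105, 99),
    (80, 80), (90, 88), (85, 84),
]


class TestDisplayedCurrent:
    @pytest.mark.parametrize("requested,displayed", DEFAULT_CALIBRATION_ENTRIES)
    def test_anchors_reproduced_exactly(self, requested, displayed):
        assert oem_displayed_current(requested) == displayed

    @pytest.mark.parametrize("requested,displayed", PRINTED_PROTOCOL_PAIRS)
    def test_protocol_currents_reproduced_exactly(self, requested, displayed):
        assert oem_displayed_current(requested) == displayed

    @given(st.integers(min_value=40, max_value=500), st.integers(min_value=40, max_value=500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        d_lo, d_hi = oem_displayed_current(lo), oem_displayed_current(hi)
        assert d_lo <= d_hi
        assert d_lo <= lo and d_hi <= hi

    def test_out_of_range_behaviour(self):
        with pytest.warns(UserWarning):
            assert oem_displayed_current(30) == 30  # identity below range
        with pytest.warns(UserWarning):
            assert oem_displayed_current(600) == round(600 * 425 / 500)  # last ratio

    def test_table_csv_round_trip(self, tmp_path):
        table = OEMCalibrationTable()
        path = tmp_path / "cal.csv"
        table.to_csv(path)
        assert OEMCalibrationTable.from_csv(path).entries == table.entries

    def test_displayed_above_requested_rejected(self):
        with pytest.raises(InvalidInputError):
            OEMCalibrationTable(((100, 120), (200, 170)))


class TestModulationRates:
    @pytest.mark.parametrize(
        "requested,expected",
        [
            (300, (63.5, 16.0)),   # plateau at and above 200 mA
            (500, (63.5, 16.0)),
            (80, (0.0, 0.0)),      # no modulation at 80 mA and below
            (60, (0.0, 0.0)),
            (100, (63.5 / 3, 16.0 / 3)),  # ramp: s = (1 - 95/100) / 0.15
        ],
    )
    def test_rate_scaling(self, requested, expected):
        d_max, d_tot = modulation_rates(requested)
        assert d_max == pytest.approx(expected[0], abs=1e-9)
        assert d_tot == pytest.approx(expected[1], abs=1e-9)

    def test_rates_monotone_in_current(self):
        currents = [c for c, _ in DEFAULT_CALIBRATION_ENTRIES]
        rates = [modulation_rates(c)[0] for c in currents]
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))


class TestTaperExponent:
    def test_cosine_mean_checkpoints(self):
        # mean(cos) = 2/pi -> p = 1; mean(cos^2) = 1/2 -> p = 2
        arc = 160.0
        dm = 63.5
        p1 = solve_taper_exponent(dm, dm * (2 / np.pi) * arc / 360.0, arc)
        p2 = solve_taper_exponent(dm, dm * 0.5 * arc / 360.0, arc)
        assert p1 == pytest.approx(1.0, abs=1e-6)
        assert p2 == pytest.approx(2.0, abs=1e-6)

    def test_plateau_exponent_matches_independent_solver(self):
        # oracle: dense quadrature of cos^p + brentq, independent of the
        # package's bisection
        target = 16.0 * 360.0 / (63.5 * 160.0)

        def mean_minus_target(p):
            return quad(lambda u: np.cos(np.pi * u / 2.0) ** p, 0.0, 1.0)[0] - target

        oracle = brentq(mean_minus_target, 0.5, 3.0, xtol=1e-12)
        assert solve_taper_exponent(63.5, 16.0, 160.0) == pytest.approx(oracle, abs=1e-6)
        assert 1.0 < oracle < 2.0

    def test_infeasible_ratio_rejected(self):
        # a dip cannot integrate to more than a rectangle of its own depth
        with pytest.raises(InfeasibleShapeError):
            solve_taper_exponent(20.0, 19.0, 90.0)
        with pytest.raises(InvalidInputError):
            solve_taper_exponent(10.0, 20.0, 160.0)


class TestAngularProfile:
    def test_front_dip_depth_and_support(self):
        prof = build_angular_profile("front", 500)
        assert prof.relative_output(0.0) == pytest.approx(0.365)
        assert prof.relative_output(120.0) == 1.0
        assert prof.relative_output(-120.0) == 1.0

    def test_off_profile_is_flat(self):
        prof = build_angular_profile("off", 500)
        phi = np.linspace(0, 360, 1000)
        assert np.all(prof.relative_output(phi) == 1.0)

    def test_mean_output_matches_dm_total(self):
        prof = build_angular_profile("front", 500)
        phi = np.arange(0.0, 360.0, 0.01)
        mean = prof.relative_output(phi).mean()
        assert mean == pytest.approx(1.0 - 16.0 / 100.0, abs=1e-5)
        assert prof.mean_relative_output == pytest.approx(0.84)

    def test_front_back_are_half_turn_rotations(self):
        front = build_angular_profile("front", 500)
        back = build_angular_profile("back", 500)
        phi = np.linspace(0.0, 360.0, 721)
        np.testing.assert_allclose(
            front.relative_output(phi), back.relative_output((phi + 180.0) % 360.0),
            atol=1e-12,
        )

    def test_low_current_profile_is_flat(self):
        prof = build_angular_profile("front", 70)
        assert np.all(prof.relative_output(np.arange(0, 360.0)) == 1.0)

    def test_tabulate_step(self):
        phi, r = build_angular_profile("front", 500).tabulate(0.5)
        assert phi.size == 720
        assert r.min() == pytest.approx(0.365, abs=1e-9)

    @pytest.mark.parametrize("mA", [250, 300, 500])
    def test_built_profile_round_trips_through_analysis(self, mA):
        prof = build_angular_profile("front", mA)
        on = synthesize_profile(500.0, 10.0, prof, dt_ms=0.1)
        off = synthesize_profile(500.0, 10.0, None, dt_ms=0.1)
        metrics, _ = analyze_pair(on, off)
        d_max, d_tot = modulation_rates(mA)
        assert metrics.theta_deg == pytest.approx(160.0, abs=0.2)
        assert metrics.dm_max_pct == pytest.approx(d_max, abs=1e-3)
        assert metrics.dm_total_pct == pytest.approx(d_tot, abs=1e-3)

    def test_invalid_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            AngularOutputProfile("sideways")

    def test_parameter_invariants(self):
        with pytest.raises(InvalidInputError):
            OEMParameters(dm_max_plateau_pct=10.0, dm_total_plateau_pct=20.0)
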