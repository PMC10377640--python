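import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ringmc import (CalibrationCurve, REFERENCE_CALIBRATION_R, PairedIntensity,
                    PhysiologicalState, ReliabilityLimits,
                    calibration_curve, classify_reliable, enhancement,
                    led_duty_cycle, paired_run, perfusion_index, r_ratio,
                    reliability_limits, theta_max)
from ringmc.experiment import (THETA_GRID_DEG, UndefinedRatioError,
                               repetition_statistics)


def _pair(i_sys, i_dia, **kw):
    defaults = dict(wavelength_nm=660.0, theta_pl_deg=25.0, rho=0.0,
                    spo2=1.0, n_photons=1000, seeds=(0, 0))
    defaults.update(kw)
    return PairedIntensity(i_systolic=i_sys, i_diastolic=i_dia, **defaults)


class TestPerfusionIndex:
    def test_no_pulsation_gives_zero(self):
        assert perfusion_index(_pair(0.003, 0.003)) == 0.0

    def test_full_modulation_gives_one(self):
        # ac equals dc when one phase detects nothing
        assert perfusion_index(_pair(0.004, 0.0)) == 1.0

    def test_definition_arithmetic(self):
        pair = _pair(0.0030, 0.0030 * (1 - 0.21))
        assert perfusion_index(pair) == pytest.approx(0.21)

    def test_zero_dc_undefined(self):
        with pytest.raises(UndefinedRatioError):
            perfusion_index(_pair(0.0, 0.0))

    def test_sign_convention(self):
        pair = _pair(0.004, 0.003)
        assert pair.ac_signed == pytest.approx(-0.001)
        assert pair.ac == pytest.approx(0.001)
        assert pair.dc == 0.004
        strict = _pair(0.004, 0.003, strict_phase_convention=True)
        assert strict.ac == pytest.approx(-0.001)
        assert strict.dc == 0.003


class TestRRatio:
    def test_equal_pi_gives_unity(self):
        assert r_ratio(0.2, 0.2) == 1.0

    def test_arithmetic(self):
        assert r_ratio(0.42, 0.41) == pytest.approx(1.0244, abs=1e-4)

    def test_zero_nir_rejected(self):
        with pytest.raises(UndefinedRatioError):
            r_ratio(0.3, 0.0)


class TestPairedRun:
    def test_forced_equal_states_give_zero_ac(self, model):
        state = PhysiologicalState.diastolic(1.0)
        pair = paired_run(model, 25.0, 660.0, 1.0, 0.0, 5_000, 21,
                          states={"systolic": state, "diastolic": state})
        assert pair.ac == 0.0
        assert pair.dc > 0.0

    def test_default_states_produce_pulsatile_signal(self, model):
        pair = paired_run(model, 25.0, 660.0, 1.0, 0.0, 50_000, 22)
        assert pair.ac > 0.0
        assert perfusion_index(pair) == pytest.approx(pair.ac / pair.dc)

    def test_dc_consistent_across_photon_budgets(self, model):
        """Doubling the photon count must not shift the dc estimate
        beyond combined Monte Carlo error (self-consistency)."""
        a = paired_run(model, 25.0, 660.0, 1.0, 0.0, 50_000, 23)
        b = paired_run(model, 25.0, 660.0, 1.0, 0.0, 100_000, 24)
        # weighted detection: bound the SE by the binomial expression at
        # the observed rate (detected weights are <= 1)
        se = math.sqrt(a.dc * (1 - a.dc) / 50_000
                       + b.dc * (1 - b.dc) / 100_000)
        assert abs(a.dc - b.dc) < 4 * se


class TestCalibration:
    def _df(self, r_by_spo2, thetas=THETA_GRID_DEG, jitter=0.0):
        rows = []
        rng = np.random.default_rng(0)
        for spo2_pct, r in r_by_spo2.items():
            for th in thetas:
                rows.append({"theta_deg": th, "spo2": spo2_pct,
                             "r_ratio": r + jitter * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_mean_of_constant_angles(self):
        curve = calibration_curve(self._df(REFERENCE_CALIBRATION_R))
        assert curve.as_dict() == pytest.approx(
            {100.0: 0.9, 90.0: 1.25, 80.0: 1.5, 70.0: 1.9})

    def test_single_outlier_shifts_mean_by_its_share(self):
        df = self._df({100: 1.0, 90: 1.25, 80: 1.5, 70: 1.9})
        df.loc[(df.spo2 == 100) & (df.theta_deg == 25), "r_ratio"] = 2.5
        curve = calibration_curve(df)
        assert curve.as_dict()[100.0] == pytest.approx(1.0 + 1.5 / 15)

    def test_missing_angle_rejected(self):
        df = self._df(REFERENCE_CALIBRATION_R,
                      thetas=[t for t in THETA_GRID_DEG if t != 60])
        with pytest.raises(ValueError, match="60"):
            calibration_curve(df)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(spo2_percent=(100, 90, 80, 70),
                             r=(1.0, 1.0, 1.0, 1.0))

    def test_spo2_fractions_accepted(self):
        df = self._df({1.0: 0.9, 0.9: 1.25, 0.8: 1.5, 0.7: 1.9})
        assert calibration_curve(df).as_dict()[100.0] == pytest.approx(0.9)


class TestReliabilityLimits:
    def test_reference_curve_midpoints(self):
        curve = CalibrationCurve(spo2_percent=(100, 90, 80, 70),
                                 r=(0.9, 1.25, 1.5, 1.9))
        lim = reliability_limits(curve)
        assert lim.as_tuple() == pytest.approx((1.075, 1.375, 1.7))

    @given(st.lists(st.floats(0.1, 5.0), min_size=4, max_size=4,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_limits_interleave_with_curve(self, rs):
        a, b, c, d = sorted(rs)
        curve = CalibrationCurve(spo2_percent=(100, 90, 80, 70),
                                 r=(a, b, c, d))
        l1, l2, l3 = reliability_limits(curve).as_tuple()
        assert a < l1 < b < l2 < c < l3 < d

    def test_unordered_limits_rejected(self):
        with pytest.raises(ValueError):
            ReliabilityLimits(1.5, 1.2, 1.9)


class TestClassifyReliable:
    LIMITS = ReliabilityLimits(1.075, 1.375, 1.7)

    @pytest.mark.parametrize("r,spo2,expected", [
        (1.0, 100, True), (1.2, 100, False),
        (1.2, 90, True), (1.0, 90, False),
        (1.5, 80, True), (1.8, 80, False),
        (1.8, 70, True), (1.5, 70, False),
    ])
    def test_bin_rule(self, r, spo2, expected):
        assert classify_reliable(r, spo2, self.LIMITS) is expected

    def test_boundary_values_unreliable(self):
        """R exactly on a limit belongs to no open bin."""
        l1, l2, l3 = self.LIMITS.as_tuple()
        for r, levels in ((l1, (100, 90)), (l2, (90, 80)), (l3, (80, 70))):
            for spo2 in levels:
                assert not classify_reliable(r, spo2, self.LIMITS)

    def test_against_brute_force_bin_table(self):
        """Dense R grid: the classifier must agree with direct interval
        membership for every level, with zero disagreements."""
        l1, l2, l3 = self.LIMITS.as_tuple()
        bins = {100: (-math.inf, l1), 90: (l1, l2),
                80: (l2, l3), 70: (l3, math.inf)}
        grid = np.arange(0.5, 2.5 + 1e-12, 0.005)
        disagreements = 0
        for spo2, (lo, hi) in bins.items():
            for r in grid:
                oracle = bool(lo < r < hi)
                if classify_reliable(float(r), spo2, self.LIMITS) != oracle:
                    disagreements += 1
        assert disagreements == 0

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            classify_reliable(1.0, 85, self.LIMITS)


class TestThetaMax:
    def _table(self, reliable_by_theta):
        rows = []
        for th, ok in reliable_by_theta.items():
            for spo2 in (70, 80, 90, 100):
                rows.append({"theta_deg": th, "spo2": spo2,
                             "reliable": ok})
        return pd.DataFrame(rows)

    def test_all_reliable_full_grid(self):
        table = self._table({th: True for th in THETA_GRID_DEG})
        assert theta_max(table) == 95.0

    def test_prefix_up_to_65(self):
        table = self._table({th: th <= 65 for th in THETA_GRID_DEG})
        assert theta_max(table) == 65.0

    def test_gap_stops_the_prefix(self):
        ok = {th: th != 40 for th in THETA_GRID_DEG}
        assert theta_max(self._table(ok)) == 35.0

    def test_none_reliable_not_measurable(self):
        table = self._table({th: False for th in THETA_GRID_DEG})
        assert theta_max(table) is None

    def test_single_spo2_failure_breaks_angle(self):
        table = self._table({th: True for th in THETA_GRID_DEG})
        table.loc[(table.theta_deg == 30) & (table.spo2 == 80),
                  "reliable"] = False
        assert theta_max(table) == 25.0


class TestRepetitionStatistics:
    def test_three_sigma_band_arithmetic(self):
        """A normalized-intensity std of 0.0039 corresponds to a +/-1.17%
        3-sigma band."""
        assert 300.0 * 0.0039 == pytest.approx(1.17)

    def test_normalized_spread_of_known_values(self):
        vals = np.array([0.99, 1.00, 1.01])
        assert np.std(vals / vals.mean(), ddof=1) == pytest.approx(
            0.01, rel=1e-3)

    def test_seeded_repeats(self, fast_scattering_model):
        stats = repetition_statistics(
            fast_scattering_model, theta_pl_deg=25.0, n_photons=20_000,
            n_repeats=5, seed=30)
        assert stats.seeds == (30, 31, 32, 33, 34)
        assert np.mean(stats.normalized) == pytest.approx(1.0)
        assert stats.three_sigma_percent == pytest.approx(
            300 * stats.std_normalized)
        assert stats.std_normalized > 0.0

    def test_minimum_repeats_enforced(self, fast_scattering_model):
        with pytest.raises(ValueError):
            repetition_statistics(fast_scattering_model, n_repeats=1)


class TestEnhancement:
    def test_no_change_is_zero(self):
        assert enhancement(0.5, 0.5) == 0.0

    def test_reported_pi_gains(self):
        assert enhancement(0.0030, 0.0037) == pytest.approx(23.3, abs=0.05)
        assert enhancement(0.0047, 0.0059) == pytest.approx(25.5, abs=0.05)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedRatioError):
            enhancement(0.0, 0.1)


def test_led_duty_cycle():
    assert led_duty_cycle() == pytest.approx(0.125)
    assert led_duty_cycle(1.0, 10.0) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        led_duty_cycle(2.0, 1.0)
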