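"""Closed-form curves, derived statistics, and the finite-GTP turnover ODE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from galphakin import (
    CyclePools,
    RateConstants,
    ValidationError,
    fraction_gtp_bound,
    gap_hydrolysis_rate,
    gtpgs_binding_curve,
    percent_gtp_bound,
    single_turnover_curve,
    spr_sensorgram,
    steady_state_turnover,
    turnover_ode,
)
from galphakin.cycle import BindingKinetics
from galphakin.reference import NUCLEOTIDE_CYCLE_RATES, RGS1_BINDING_KINETICS

AT = NUCLEOTIDE_CYCLE_RATES["AtGPA1"]
MP = NUCLEOTIDE_CYCLE_RATES["MpGa1"]

rates_strategy = st.floats(min_value=0.02, max_value=7.0, allow_nan=False)


class TestClosedFormCurves:
    def test_binding_curve_values(self):
        tc = gtpgs_binding_curve(AT, b_max=1.0, times=[1e-12, 1.0])
        assert tc.values[0] == pytest.approx(0.0, abs=1e-10)
        assert tc.values[1] == pytest.approx(1.0 - math.exp(-5.80), rel=1e-12)
        assert tc.values[1] == pytest.approx(0.9970, abs=5e-4)

    def test_binding_half_time_identity(self):
        for rc in NUCLEOTIDE_CYCLE_RATES.values():
            t_half = math.log(2) / rc.k_exchange
            tc = gtpgs_binding_curve(rc, b_max=7.0, times=[t_half])
            assert tc.values[0] == pytest.approx(3.5, rel=1e-12)

    def test_binding_monotone_to_plateau(self):
        tc = gtpgs_binding_curve(AT, 460.0, np.linspace(0.01, 5, 50))
        assert np.all(np.diff(tc.values) > 0)
        assert tc.values[-1] < 460.0
        assert tc.values[-1] == pytest.approx(460.0, rel=1e-6)

    def test_negative_time_rejected_with_index(self):
        with pytest.raises(ValidationError, match="index 1"):
            gtpgs_binding_curve(AT, 1.0, [0.0, -0.5, 1.0])

    def test_single_turnover_values(self):
        tc = single_turnover_curve(AT, p0=1.0, times=[1e-12, 10.0])
        assert tc.values[0] == pytest.approx(0.0, abs=1e-10)
        assert tc.values[1] == pytest.approx(1.0 - math.exp(-0.47), rel=1e-12)
        assert tc.values[1] == pytest.approx(0.375, abs=1e-3)

    def test_single_turnover_half_time(self):
        t_half = math.log(2) / MP.k_cat
        tc = single_turnover_curve(MP, p0=800.0, times=[t_half])
        assert tc.values[0] == pytest.approx(400.0, rel=1e-12)


class TestDerivedStatistics:
    def test_series_turnover_reference_value(self):
        assert steady_state_turnover(AT) == pytest.approx(0.04662, abs=5e-5)

    def test_series_turnover_limits_and_symmetry(self):
        assert steady_state_turnover(RateConstants(2.0, 2.0)) == pytest.approx(1.0)
        # hydrolysis-limited regime
        v = steady_state_turnover(RateConstants(1000.0, 0.05))
        assert v == pytest.approx(0.05, rel=1e-3)
        a = steady_state_turnover(RateConstants(1.3, 0.4))
        b = steady_state_turnover(RateConstants(0.4, 1.3))
        assert a == b
        assert a < 0.4

    def test_series_turnover_zero_rate_error(self):
        with pytest.raises(ValidationError, match="undefined"):
            steady_state_turnover(RateConstants(0.0, 1.0))

    def test_fraction_gtp_bound_symmetry_and_errors(self):
        assert fraction_gtp_bound(RateConstants(0.3, 0.3)) == pytest.approx(0.5)
        with pytest.raises(ValidationError):
            fraction_gtp_bound(RateConstants(0.0, 0.0))

    @pytest.mark.parametrize(
        "name,expected",
        [("AtGPA1", 99), ("AtGPA1-T194N", 99), ("OsRGA1", 95),
         ("OsRGA1-N195T", 93), ("MpGa1", 68)],
    )
    def test_percent_gtp_bound_reference_rows(self, name, expected):
        assert percent_gtp_bound(NUCLEOTIDE_CYCLE_RATES[name]) == expected

    @given(kex=rates_strategy, kcat=rates_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_fraction_monotone_in_each_rate(self, kex, kcat):
        base = fraction_gtp_bound(RateConstants(kex, kcat))
        assert fraction_gtp_bound(RateConstants(kex * 1.1, kcat)) > base
        assert fraction_gtp_bound(RateConstants(kex, kcat * 1.1)) < base


class TestGapHydrolysisRate:
    RC = RateConstants(0.92, 0.052, k_gap_max=1.5, k_half_gap=40.0)

    def test_identities(self):
        assert gap_hydrolysis_rate(self.RC, 0.0) == pytest.approx(0.052)
        assert gap_hydrolysis_rate(self.RC, 40.0) == pytest.approx(0.052 + 0.75)
        assert gap_hydrolysis_rate(self.RC, 1e9) == pytest.approx(0.052 + 1.5, rel=1e-6)

    def test_monotone_and_bounded(self):
        doses = np.linspace(0, 2000, 30)
        rates = [gap_hydrolysis_rate(self.RC, d) for d in doses]
        assert np.all(np.diff(rates) >= 0)
        assert max(rates) <= 0.052 + 1.5

    def test_gap_fields_unset_error(self):
        with pytest.raises(ValidationError, match="GAP"):
            gap_hydrolysis_rate(RateConstants(0.92, 0.052), 50.0)


class TestTurnoverODE:
    def test_gtpgs_mode_monotone_to_g_total(self):
        pools = CyclePools(g_total=276.0, g_gtp=0.0, free_gtp=5000.0, free_gdp=0.0)
        traj = turnover_ode(MP, pools, np.linspace(0.01, 30, 200), hydrolysable=False)
        assert np.all(np.diff(traj.g_gtp) >= -1e-8)
        assert traj.g_gtp[-1] == pytest.approx(276.0, rel=1e-4)

    def test_no_substrate_stays_inactive(self):
        pools = CyclePools(g_total=276.0, g_gtp=0.0, free_gtp=0.0, free_gdp=500.0)
        traj = turnover_ode(MP, pools, np.linspace(0.01, 10, 50))
        assert np.max(traj.g_gtp) == pytest.approx(0.0, abs=1e-9)

    def test_finite_gtp_peak_then_decay(self):
        # liverwort-type rates, 400 nM protein at 0.69 activity, 800 nM GTP
        pools = CyclePools(g_total=400 * 0.69, g_gtp=0.0, free_gtp=800.0, free_gdp=0.0)
        times = np.linspace(0.01, 60, 400)
        traj = turnover_ode(MP, pools, times)
        i_peak = int(np.argmax(traj.g_gtp))
        assert 0 < i_peak < len(times) - 1
        assert traj.g_gtp[-1] < 0.5 * traj.g_gtp[i_peak]

    @pytest.mark.parametrize("name", sorted(NUCLEOTIDE_CYCLE_RATES))
    def test_mass_conservation_all_proteins(self, name):
        rc = NUCLEOTIDE_CYCLE_RATES[name]
        pools = CyclePools(g_total=200.0, g_gtp=0.0, free_gtp=800.0, free_gdp=50.0)
        traj = turnover_ode(rc, pools, np.linspace(0.05, 40, 150))
        total = traj.free_gtp + traj.free_gdp
        assert np.max(np.abs(total - 850.0)) / 850.0 < 1e-6
        assert np.all(traj.g_gtp >= 0) and np.all(traj.g_gtp <= 200.0 + 1e-9)

    def test_occupancy_matches_closed_form_at_unlimited_gtp(self):
        for rc in NUCLEOTIDE_CYCLE_RATES.values():
            pools = CyclePools(g_total=100.0, g_gtp=0.0, free_gtp=1e5, free_gdp=0.0)
            t_eq = 30.0 / (rc.k_exchange + rc.k_cat)
            traj = turnover_ode(rc, pools, [t_eq], unlimited_gtp=True)
            assert traj.g_gtp[-1] / 100.0 == pytest.approx(
                fraction_gtp_bound(rc), abs=1e-4
            )

    def test_pi_accumulation_slope_matches_series_formula(self):
        rc = NUCLEOTIDE_CYCLE_RATES["OsRGA1"]
        k_slow = min(rc.k_exchange, rc.k_cat)
        times = np.linspace(5.0 / k_slow, 10.0 / k_slow, 30)
        pools = CyclePools(g_total=500.0, g_gtp=0.0, free_gtp=1e6, free_gdp=0.0)
        traj = turnover_ode(rc, pools, times, unlimited_gtp=True)
        slope = np.polyfit(times, traj.pi, 1)[0]
        expected = steady_state_turnover(rc) * 500.0
        assert slope == pytest.approx(expected, rel=0.02)


class TestSPRSensorgram:
    KIN = RGS1_BINDING_KINETICS["AtGPA1"]

    def test_zero_at_t0_and_half_saturation_at_kd(self):
        s = spr_sensorgram(self.KIN, self.KIN.k_D, 5000.0, 100.0, 1.0)
        assert s.response[0] == pytest.approx(0.0, abs=1e-12)
        # at C = K_D the equilibrium response is R_max / 2
        end_assoc = s.response[s.times <= s.t_assoc][-1]
        assert end_assoc == pytest.approx(self.KIN.r_max / 2, rel=1e-3)

    def test_equilibrium_ratio_at_400nM(self):
        s = spr_sensorgram(self.KIN, 400e-9, 180.0, 300.0, 1.0)
        k_obs = self.KIN.k_a * 400e-9 + self.KIN.k_d
        assert k_obs == pytest.approx(0.1412 + 0.00616, rel=1e-3)
        plateau = s.response[s.times <= 180.0][-1]
        assert plateau / self.KIN.r_max == pytest.approx(0.958, abs=2e-3)

    def test_phase_shapes_and_continuity(self):
        s = spr_sensorgram(self.KIN, 100e-9, 180.0, 300.0, 1.0)
        assoc = s.response[s.times <= 180.0]
        dissoc = s.response[s.times > 180.0]
        assert np.all(np.diff(assoc) > 0)
        assert np.all(np.diff(dissoc) < 0)
        assert abs(assoc[-1] - dissoc[0]) < 0.01 * self.KIN.r_max

    def test_bad_dt_rejected(self):
        with pytest.raises(ValidationError, match="dt"):
            spr_sensorgram(self.KIN, 100e-9, 180.0, 300.0, 0.0)


def test_rate_constants_validation():
    with pytest.raises(ValidationError):
        RateConstants(-1.0, 0.1)
    with pytest.raises(ValidationError):
        RateConstants(float("nan"), 0.1)
    with pytest.raises(ValidationError):
        CyclePools(g_total=10.0, g_gtp=11.0, free_gtp=0.0, free_gdp=0.0)


def test_binding_kinetics_kd_is_exact_quotient():
    kin = BindingKinetics(k_a=3.53e5, k_d=6.16e-3, r_max=100.0)
    assert kin.k_D == pytest.approx(6.16e-3 / 3.53e5, rel=1e-12)
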