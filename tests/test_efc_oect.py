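"""Fuel-cell OCP model, polarization/power curves, OECT transduction."""

import math

import numpy as np
import pytest

from gbas.efc_oect import (
    FuelCellSpec,
    OectSpec,
    ScheduleEvent,
    coupled_simulation,
    disd_dt,
    nernst_slope_V,
    ocp_nernst,
    ocp_time_course,
    oect_drain_current,
    percent_modulation,
    polarization_curve,
)
from gbas.errors import DomainError, InvalidScheduleError, NoFuelError
from gbas.kinetics import LigandDose
from gbas.synthetic_data import electrode_gdh5e_plus


@pytest.fixture(scope="module")
def fc():
    return FuelCellSpec()


@pytest.fixture(scope="module")
def oect():
    return OectSpec()


class TestOcpNernst:
    def test_equal_concentrations_give_k_total(self, fc):
        assert ocp_nernst(fc, 5.0, 5.0) == fc.k_total_V

    def test_tenfold_excess_adds_nernstian_decade(self, fc):
        # (RT/2F) ln 10 = 29.58 mV at 298.15 K
        assert ocp_nernst(fc, 10.0, 1.0) - fc.k_total_V == pytest.approx(
            0.029578, abs=1e-5
        )

    def test_log_additivity_of_halving(self, fc):
        drop = ocp_nernst(fc, 4.0, 2.0) - ocp_nernst(fc, 2.0, 2.0)
        assert drop == pytest.approx(nernst_slope_V() * math.log(2), rel=1e-12)

    def test_nonpositive_concentration_rejected(self, fc):
        with pytest.raises(DomainError):
            ocp_nernst(fc, 0.0, 1.0)


class TestOcpTimeCourse:
    def test_half_conversion_returns_k_total(self):
        fc = FuelCellSpec(c0_glucose_mM=20.0)
        vmax = 1.0 / 60.0  # 1 mM/min
        t_half = fc.c0_glucose_mM / (2 * vmax)
        assert ocp_time_course(fc, vmax, t_half) == pytest.approx(fc.k_total_V)

    def test_direct_evaluation_example(self):
        # C0=20 mM, Vmax=1 mM/min, t=5 min: OCP = K + (RT/2F) ln 3 ~ K + 14.1 mV
        fc = FuelCellSpec(k_total_V=0.62, c0_glucose_mM=20.0)
        ocp = ocp_time_course(fc, 1.0 / 60.0, 300.0)
        assert ocp == pytest.approx(0.62 + nernst_slope_V() * math.log(3), rel=1e-9)
        assert ocp == pytest.approx(0.634, abs=1e-3)

    def test_strictly_decreasing_on_domain(self):
        fc = FuelCellSpec(c0_glucose_mM=20.0)
        vmax = 0.01
        ts = np.linspace(1.0, fc.c0_glucose_mM / vmax - 1.0, 200)
        ocps = [ocp_time_course(fc, vmax, t) for t in ts]
        assert np.all(np.diff(ocps) < 0)

    def test_lower_vmax_raises_ocp_before_half_conversion(self):
        fc = FuelCellSpec(c0_glucose_mM=20.0)
        t = 200.0  # well before half-conversion for both rates
        assert ocp_time_course(fc, 0.005, t) > ocp_time_course(fc, 0.01, t)

    def test_domain_error_names_interval(self):
        fc = FuelCellSpec(c0_glucose_mM=20.0)
        with pytest.raises(DomainError, match="interval"):
            ocp_time_course(fc, 0.01, 2001.0)
        with pytest.raises(DomainError):
            ocp_time_course(fc, 0.01, 0.0)


class TestPolarization:
    def test_open_circuit_voltage_at_zero_current(self, fc):
        pc = polarization_curve(fc, electrode_gdh5e_plus(), 5.0)
        assert pc.v_volt[0] == pytest.approx(pc.ocp_V)

    def test_voltage_nonincreasing_power_concave(self, fc):
        pc = polarization_curve(fc, electrode_gdh5e_plus(), 5.0)
        assert np.all(np.diff(pc.v_volt) <= 1e-12)
        assert pc.p_uW_cm2[0] == pytest.approx(0.0, abs=1e-9)
        assert pc.p_uW_cm2[-1] == pytest.approx(0.0, abs=1e-6)
        k = np.argmax(pc.p_uW_cm2)
        assert 0 < k < len(pc.p_uW_cm2) - 1

    def test_ohmic_limit_closed_form(self):
        # with an enormous limiting current the sweep is purely ohmic:
        # P_max = OCP^2/(4 R_int) at j = OCP/(2 R_int)
        fc = FuelCellSpec(j_lim_scale=1e9)
        enz = electrode_gdh5e_plus()
        pc = polarization_curve(fc, enz, 5.0, n_points=20001)
        pmax_expected = fc.k_total_V**2 / (4 * fc.r_int_ohm_cm2 * 1e-6)
        j_expected = fc.k_total_V / (2 * fc.r_int_ohm_cm2 * 1e-6)
        assert pc.p_max == pytest.approx(pmax_expected, rel=1e-3)
        assert pc.j_at_pmax == pytest.approx(j_expected, rel=1e-2)

    def test_blood_discharge_calibration_and_ligand_direction(self, fc):
        # estradiol blood anchors: j_max ~ 179 uA/cm2, P_max ~ 32 uW/cm2;
        # 4-HT represses the enzyme, so both drop
        enz = electrode_gdh5e_plus()
        s = 5.6 * 0.2 / 4.2  # 200 uL blood in 4 mL anolyte
        d = 0.2 / 4.2
        es = LigandDose("17β-estradiol", 100e-6 * d, 0.01 * d)
        ht = LigandDose("4-HT", 100e-6 * d, 0.01 * d)
        pc_es = polarization_curve(fc, enz, s, es)
        pc_ht = polarization_curve(fc, enz, s, ht)
        assert pc_es.j_max == pytest.approx(179.0, abs=2.0)
        assert pc_es.p_max == pytest.approx(32.0, abs=0.5)
        assert pc_ht.j_max < pc_es.j_max
        assert pc_ht.p_max < pc_es.p_max

    def test_dead_enzyme_raises_no_fuel(self, fc):
        from dataclasses import replace

        apo = replace(electrode_gdh5e_plus(), holo=False)
        with pytest.raises(NoFuelError):
            polarization_curve(fc, apo, 5.0)


class TestOect:
    def test_zero_gate_gives_baseline(self, oect):
        assert abs(oect_drain_current(oect, 0.0)) == oect.i_sd0_mA

    def test_gate_step_calibration(self, oect):
        # connecting the glucose-free EFC (~620 mV) depletes the channel by
        # ~7.0 mA with g_m ~ 11.3 mS
        drop = abs(oect_drain_current(oect, 0.0)) - abs(oect_drain_current(oect, 0.620))
        assert drop == pytest.approx(7.0, abs=0.01)

    def test_zero_transconductance_means_no_gating(self):
        dead = OectSpec(g_m_mS=0.0)
        assert abs(oect_drain_current(dead, 0.7)) == dead.i_sd0_mA

    def test_sign_follows_vsd(self, oect):
        assert oect_drain_current(oect, 0.1) < 0  # V_sd = -0.6 V


class TestDrainCurrentDerivative:
    def test_paper_variant_vanishes_with_vmax(self, fc, oect):
        small = disd_dt(fc, oect, 1e-9, 100.0, variant="paper")
        assert small == pytest.approx(0.0, abs=1e-8)

    def test_exact_variant_matches_numeric_differentiation(self, fc, oect):
        vmax = 0.01
        t_end = fc.c0_glucose_mM / vmax
        for t in np.linspace(0.05 * t_end, 0.95 * t_end, 100):
            h = 1e-5 * t
            num = abs(
                oect.g_m_mS
                * (ocp_time_course(fc, vmax, t + h) - ocp_time_course(fc, vmax, t - h))
                / (2 * h)
            )
            assert disd_dt(fc, oect, vmax, t, "exact") == pytest.approx(num, rel=1e-6)

    def test_inhibited_vmax_slows_decay_both_variants(self, fc, oect):
        vmax = 0.01
        vmax_ht = vmax * 0.82  # the 18% kinetic inhibition
        t_end = fc.c0_glucose_mM / vmax
        # paper variant: monotone in vmax at every valid t
        for t in np.linspace(0.1 * t_end, 0.9 * t_end, 9):
            assert disd_dt(fc, oect, vmax_ht, t, "paper") < disd_dt(
                fc, oect, vmax, t, "paper"
            )
        # exact variant: past half-conversion of the slower enzyme
        t_half_slow = fc.c0_glucose_mM / (2 * vmax_ht)
        for t in np.linspace(t_half_slow * 1.05, 0.95 * fc.c0_glucose_mM / vmax, 5):
            assert disd_dt(fc, oect, vmax_ht, t, "exact") < disd_dt(
                fc, oect, vmax, t, "exact"
            )

    def test_printed_modulation_statistic(self):
        assert percent_modulation(127.0, 53.0) == pytest.approx(58.3, abs=0.1)


class TestCoupledSimulation:
    def test_no_connection_flat_baseline(self, fc, oect):
        tr = coupled_simulation(fc, oect, electrode_gdh5e_plus(), [], 100.0)
        np.testing.assert_allclose(np.abs(tr.i_sd_mA), oect.i_sd0_mA)

    def test_glucose_free_connect_single_step(self, fc, oect):
        sch = [ScheduleEvent("connect", 50.0)]
        tr = coupled_simulation(fc, oect, electrode_gdh5e_plus(), sch, 200.0)
        pre = np.abs(tr.i_sd_mA[tr.times_s < 50])
        post = np.abs(tr.i_sd_mA[tr.times_s >= 50])
        np.testing.assert_allclose(pre, oect.i_sd0_mA)
        np.testing.assert_allclose(post, post[0])  # no drift without fuel
        assert pre[0] - post[0] == pytest.approx(oect.g_m_mS * fc.k_total_V, rel=1e-9)

    def test_ligand_slows_decay_but_not_step(self, fc, oect):
        enz = electrode_gdh5e_plus()
        glucose = 19.8

        def run(dose):
            sch = [
                ScheduleEvent("connect", 20.0),
                ScheduleEvent("inject", 100.0, glucose_mM=glucose, dose=dose),
            ]
            return coupled_simulation(fc, oect, enz, sch, duration_s=900.0, dt_s=1.0)

        blank = run(LigandDose("none", 0.0, 0.01))
        ht = run(LigandDose("4-HT", 1e-6, 0.01))
        # injection step sizes nearly identical (ligand acts on the decay)
        def step_at_injection(tr):
            i = np.abs(tr.i_sd_mA)
            k = np.searchsorted(tr.times_s, 100.0)
            return i[k - 1] - i[k + 1]

        s_b, s_h = step_at_injection(blank), step_at_injection(ht)
        assert s_h == pytest.approx(s_b, rel=0.05)
        # decay immediately after the step is slower with 4-HT
        def decay_rate(tr):
            i = np.abs(tr.i_sd_mA)
            k0 = np.searchsorted(tr.times_s, 150.0)
            k1 = np.searchsorted(tr.times_s, 400.0)
            return (i[k1] - i[k0]) / (tr.times_s[k1] - tr.times_s[k0])

        assert decay_rate(ht) < decay_rate(blank)

    def test_disconnect_restores_baseline(self, fc, oect):
        sch = [ScheduleEvent("connect", 20.0), ScheduleEvent("disconnect", 60.0)]
        tr = coupled_simulation(fc, oect, electrode_gdh5e_plus(), sch, 100.0)
        assert abs(tr.i_sd_mA[-1]) == pytest.approx(oect.i_sd0_mA)

    def test_out_of_order_schedule_rejected(self, fc, oect):
        with pytest.raises(InvalidScheduleError):
            coupled_simulation(
                fc, oect, electrode_gdh5e_plus(),
                [ScheduleEvent("inject", 10.0, glucose_mM=20.0)], 100.0,
            )
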