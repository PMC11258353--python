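"""Allosteric kinetics: inhibition factor, rates, traces, MM fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbas.errors import InsufficientDataError, InvalidInputError
from gbas.kinetics import (
    NO_DOSE,
    EnzymeParams,
    LigandDose,
    activity_from_trace,
    catalytic_rate,
    fit_michaelis_menten,
    inhibition_factor,
    simulate_dcpip_trace,
)


class TestInhibitionFactor:
    def test_no_ligand_no_vehicle_is_unity(self, e5_solution):
        assert inhibition_factor(e5_solution, NO_DOSE) == 1.0

    def test_cognate_in_flat_window_gives_full_attenuation(self, e5_solution):
        # 1 nM 4-HT sits inside [338 pM, 2 uM]: f = 0.82 x dmso factor
        dose = LigandDose("4-HT", 1e-9, 0.01)
        expected = (1 - e5_solution.alpha_max) * e5_solution.dmso_factor
        assert inhibition_factor(e5_solution, dose) == pytest.approx(expected)
        # flat across the whole window, including its upper end
        for c in (338e-12, 5e-9, 480e-9, 2e-6, 1e-5):
            assert inhibition_factor(e5_solution, LigandDose("4-HT", c, 0.01)) == \
                pytest.approx(expected)

    def test_estradiol_is_not_sensed(self, e5_solution):
        dose = LigandDose("17β-estradiol", 1e-9, 0.01)
        assert inhibition_factor(e5_solution, dose) == pytest.approx(
            e5_solution.dmso_factor
        )

    def test_wild_type_ignores_cognate_ligand(self, ewt_solution):
        dose = LigandDose("4-HT", 1e-9, 0.01)
        assert inhibition_factor(ewt_solution, dose) == pytest.approx(
            ewt_solution.dmso_factor
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            LigandDose("4-HT", -1e-9)

    @settings(deadline=None, max_examples=50)
    @given(c1=st.floats(0, 1e-5), c2=st.floats(0, 1e-5))
    def test_monotone_nonincreasing_in_concentration(self, e5_solution, c1, c2):
        lo, hi = sorted((c1, c2))
        f_lo = inhibition_factor(e5_solution, LigandDose("4-HT", lo))
        f_hi = inhibition_factor(e5_solution, LigandDose("4-HT", hi))
        assert f_hi <= f_lo + 1e-12

    def test_subthreshold_rolloff_continuous_at_window_edge(self, e5_solution):
        c_lo = e5_solution.ligand_range_M[0]
        just_below = inhibition_factor(e5_solution, LigandDose("4-HT", c_lo * 0.999))
        at_edge = inhibition_factor(e5_solution, LigandDose("4-HT", c_lo))
        assert just_below == pytest.approx(at_edge, rel=1e-3)
        # and vanishing response far below
        tiny = inhibition_factor(e5_solution, LigandDose("4-HT", c_lo * 1e-4))
        assert tiny == pytest.approx(1.0, abs=2e-4 * e5_solution.alpha_max * 10)


class TestCatalyticRate:
    def test_zero_glucose_gives_zero(self, e5_solution):
        assert catalytic_rate(e5_solution, 0.0) == 0.0

    def test_printed_activity_pair(self, e5_solution):
        # blank (DMSO) rate at 80 mM glucose calibrated to 112 a.u./s;
        # 1 nM 4-HT represses it to ~92 (the 18% attenuation)
        blank = LigandDose("none", 0.0, 0.01)
        ht = LigandDose("4-HT", 1e-9, 0.01)
        assert catalytic_rate(e5_solution, 80.0, blank) == pytest.approx(112.0)
        assert catalytic_rate(e5_solution, 80.0, ht) == pytest.approx(92.0, abs=0.5)

    def test_apo_enzyme_is_dead(self, e5_solution):
        from dataclasses import replace

        apo = replace(e5_solution, holo=False)
        assert catalytic_rate(apo, 80.0) == 0.0
        assert catalytic_rate(apo, 5.0, LigandDose("4-HT", 1e-6)) == 0.0

    def test_half_saturation_identity(self, e5_solution):
        v = catalytic_rate(e5_solution, e5_solution.km_mM)
        assert v == pytest.approx(e5_solution.vmax_blank / 2)

    def test_saturation_limit(self, e5_solution):
        v = catalytic_rate(e5_solution, 1000 * e5_solution.km_mM)
        assert v == pytest.approx(e5_solution.vmax_blank, rel=2e-3)

    def test_negative_glucose_rejected(self, e5_solution):
        with pytest.raises(InvalidInputError):
            catalytic_rate(e5_solution, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(s1=st.floats(0, 200), s2=st.floats(0, 200))
    def test_monotone_nondecreasing_in_glucose(self, e5_solution, s1, s2):
        lo, hi = sorted((s1, s2))
        assert catalytic_rate(e5_solution, hi) >= catalytic_rate(e5_solution, lo) - 1e-12


class TestDcpipTrace:
    def test_noiseless_slope_equals_rate(self, e5_solution):
        tr = simulate_dcpip_trace(e5_solution, 80.0, NO_DOSE, cv=0.0,
                                  a0=1e5, k_abs=1.0)
        v = catalytic_rate(e5_solution, 80.0)
        assert activity_from_trace(tr) == pytest.approx(v, rel=1e-9)

    def test_same_seed_reproduces_trace(self, e5_solution, ht_1nM):
        t1 = simulate_dcpip_trace(e5_solution, 80, ht_1nM, cv=0.076, seed=7)
        t2 = simulate_dcpip_trace(e5_solution, 80, ht_1nM, cv=0.076, seed=7)
        np.testing.assert_array_equal(t1.absorbance_600, t2.absorbance_600)

    def test_replicate_cv_recovered(self, e5_solution):
        # 100 replicates at the purified-protein CV (7.6%) reproduce it
        acts = [
            activity_from_trace(
                simulate_dcpip_trace(e5_solution, 80, NO_DOSE, cv=0.076,
                                     seed=rep, a0=1e5)
            )
            for rep in range(100)
        ]
        acts = np.asarray(acts)
        cv_emp = acts.std(ddof=1) / acts.mean()
        assert cv_emp == pytest.approx(0.076, abs=0.02)

    def test_negative_cv_rejected(self, e5_solution):
        with pytest.raises(InvalidInputError):
            simulate_dcpip_trace(e5_solution, 80, NO_DOSE, cv=-0.1)

    def test_constant_trace_has_zero_activity(self, e5_solution):
        tr = simulate_dcpip_trace(e5_solution, 0.0, NO_DOSE, cv=0.0)
        assert activity_from_trace(tr) == pytest.approx(0.0, abs=1e-12)

    def test_window_too_small_raises(self, e5_solution):
        tr = simulate_dcpip_trace(e5_solution, 80, NO_DOSE, cv=0.0, dt_s=15)
        with pytest.raises(InsufficientDataError):
            activity_from_trace(tr, window_s=(0.0, 20.0))


class TestMichaelisMentenFit:
    def test_exact_recovery_on_noiseless_data(self):
        S = np.array([0.5, 1, 2, 5, 10, 40], dtype=float)
        v = 50.0 * S / (2.0 + S)
        fit = fit_michaelis_menten(S, v)
        assert fit.vmax == pytest.approx(50.0, rel=1e-6)
        assert fit.km_mM == pytest.approx(2.0, rel=1e-6)

    def test_roundtrip_through_traces(self, e5_solution):
        # simulate noiseless traces over a glucose series, extract
        # activities, refit: parameters come back
        S = np.array([0.2, 0.5, 1, 2, 5, 10, 20, 80], dtype=float)
        v = np.array([
            activity_from_trace(
                simulate_dcpip_trace(e5_solution, s, NO_DOSE, cv=0.0, a0=1e6)
            )
            for s in S
        ])
        fit = fit_michaelis_menten(S, v)
        assert fit.vmax == pytest.approx(e5_solution.vmax_blank, rel=1e-4)
        assert fit.km_mM == pytest.approx(e5_solution.km_mM, rel=1e-4)

    def test_ligand_lowers_vmax_but_not_wild_type(self, e5_solution, ewt_solution,
                                                  blank_dose, ht_1uM):
        S = np.array([0.2, 0.5, 1, 2, 5, 10, 20, 80], dtype=float)
        for enz, should_drop in ((e5_solution, True), (ewt_solution, False)):
            v_b = np.array([catalytic_rate(enz, s, blank_dose) for s in S])
            v_h = np.array([catalytic_rate(enz, s, ht_1uM) for s in S])
            fb = fit_michaelis_menten(S, v_b)
            fh = fit_michaelis_menten(S, v_h)
            if should_drop:
                assert fh.vmax < 0.9 * fb.vmax
            else:
                assert fh.vmax == pytest.approx(fb.vmax, rel=1e-6)

    @pytest.mark.parametrize(
        "S,v,exc",
        [
            ([1, 2, 3], [1, 2, 3], InsufficientDataError),           # <4 points
            ([1, 1, 2, 2], [1, 1, 2, 2], InsufficientDataError),     # <3 distinct
            ([1, 2, 3, 4], [1, -1, 2, 3], InvalidInputError),        # negative rate
        ],
    )
    def test_degenerate_designs_rejected(self, S, v, exc):
        with pytest.raises(exc):
            fit_michaelis_menten(np.asarray(S, float), np.asarray(v, float))


def test_enzyme_invariant_validation():
    with pytest.raises(InvalidInputError):
        EnzymeParams("bad", vmax_blank=-1, km_mM=1)
    with pytest.raises(InvalidInputError):
        EnzymeParams("bad", vmax_blank=1, km_mM=1, alpha_max=1.2)
    with pytest.raises(InvalidInputError):
        EnzymeParams("bad", vmax_blank=1, km_mM=1, ligand_range_M=(1e-6, 1e-9))
    with pytest.raises(InvalidInputError):
        EnzymeParams("bad", vmax_blank=1, km_mM=1, selectivity={"x": 1.5})
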