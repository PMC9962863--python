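"""PK layer: QE binding root, MM-TMDD rat models, human QE-TMDD models."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoscale.pk as P
from hemoscale.pk import (
    ConcProfile,
    DoseEvent,
    PKState,
    apply_dose,
    qe_free_concentration,
    romi_receptor_pool,
    rtot_from_mm,
    simulate_pk,
)


class TestQERoot:
    @pytest.mark.parametrize(
        "c_tot,r_tot,km,expected",
        [
            (0.0, 154.7, 48.1, 0.0),        # no drug
            (100.0, 0.0, 48.1, 100.0),      # no receptor: free = total
            (100.0, 154.7, 48.1, 34.924735736635774),  # positive root
        ],
    )
    def test_reference_values(self, c_tot, r_tot, km, expected):
        c = qe_free_concentration(c_tot, r_tot, km)
        assert c == pytest.approx(expected, rel=1e-12, abs=1e-12)
        # root satisfies the defining quadratic
        resid = c * c + (r_tot + km - c_tot) * c - km * c_tot
        assert abs(resid) <= 1e-10 * max(1.0, km * c_tot)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            qe_free_concentration(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            qe_free_concentration(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            qe_free_concentration(1.0, 1.0, 0.0)

    def test_bounds_residual_and_monotonicity_on_random_grid(self):
        rng = np.random.default_rng(42)
        c_tot = 10.0 ** rng.uniform(-3, 4, 1000)
        r_tot = 10.0 ** rng.uniform(-3, 4, 1000)
        km = 10.0 ** rng.uniform(-3, 3, 1000)
        c = qe_free_concentration(c_tot, r_tot, km)
        assert np.all(c >= 0.0)
        assert np.all(c <= c_tot * (1 + 1e-12))
        resid = c * c + (r_tot + km - c_tot) * c - km * c_tot
        # relative to the magnitude of the quadratic's own terms
        scale = np.maximum(
            c * c + np.abs(r_tot + km - c_tot) * c + km * c_tot, 1e-30
        )
        assert np.max(np.abs(resid) / scale) < 1e-10
        # monotone in c_tot, antitone in r_tot
        up = qe_free_concentration(c_tot * 1.01, r_tot, km)
        assert np.all(up >= c - 1e-12)
        dn = qe_free_concentration(c_tot, r_tot * 1.01, km)
        assert np.all(dn <= c + 1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        c_tot=st.floats(0.0, 1e6),
        r_tot=st.floats(0.0, 1e6),
        km=st.floats(1e-6, 1e6),
    )
    def test_root_always_within_physical_bounds(self, c_tot, r_tot, km):
        c = qe_free_concentration(c_tot, r_tot, km)
        assert 0.0 <= c <= c_tot * (1 + 1e-9) + 1e-9


class TestReceptorPools:
    @pytest.mark.parametrize(
        "v_max,v_c,k_int,expected", [(1, 1, 1, 1.0), (10, 2, 0.5, 10.0)]
    )
    def test_mm_receptor_concentration(self, v_max, v_c, k_int, expected):
        assert rtot_from_mm(v_max, v_c, k_int) == pytest.approx(expected)

    def test_linearity_in_vmax(self):
        assert rtot_from_mm(6.0, 2.0, 0.3) == pytest.approx(
            2 * rtot_from_mm(3.0, 2.0, 0.3)
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rtot_from_mm(1.0, 0.0, 1.0)

    def test_platelet_borne_cmpl_pool(self):
        # 0.0215 fg/platelet at 0.23e12 platelets/L -> ~4.95 ng/mL
        assert romi_receptor_pool(0.0215, 0.23) == pytest.approx(4.945, abs=5e-3)

    def test_pool_lowers_free_concentration_monotonically(self, human_pk):
        _, romi = human_pk
        km = romi.KM_R
        c_tot = 2.0
        pools = [romi_receptor_pool(romi.XI_R, p) for p in (0.23, 0.46)]
        frees = [qe_free_concentration(c_tot, r, km) for r in pools]
        assert pools[1] == pytest.approx(2 * pools[0])
        assert frees[1] < frees[0]


class TestDosing:
    def test_iv_bolus_goes_to_central(self, human_pk):
        epo, _ = human_pk
        ev = DoseEvent(0.0, "EPO", "IV", 100.0, 70.0)
        s = apply_dose(PKState(), ev, epo)
        assert s.central_amount == pytest.approx(7000.0)
        assert s.depot_amount == 0.0

    def test_sc_dose_scaled_by_bioavailability(self, human_pk):
        epo, _ = human_pk  # F_E = 0.513
        ev = DoseEvent(0.0, "EPO", "SC", 100.0, 70.0)
        s = apply_dose(PKState(), ev, epo)
        assert s.depot_amount == pytest.approx(3591.0)
        assert s.central_amount == 0.0

    def test_zero_dose_leaves_state_unchanged(self, human_pk):
        epo, _ = human_pk
        s0 = PKState(1.0, 2.0, 3.0)
        s1 = apply_dose(s0, DoseEvent(0.0, "EPO", "IV", 0.0, 70.0), epo)
        assert s1 == s0

    def test_invalid_event_fields_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, "EPO", "IV", 1.0, 70.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, "EPO", "PO", 1.0, 70.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, "XXX", "IV", 1.0, 70.0)


class TestRatModel:
    def test_zero_state_has_zero_derivatives(self, rat_pk):
        epo, romi = rat_pk
        for p in (epo, romi):
            d = P.rat_mm_rhs(PKState(), p)
            assert d.depot_amount == d.central_amount == d.peripheral_amount == 0

    def test_mass_conservation_without_elimination(self, rat_pk):
        epo, _ = rat_pk
        p = dataclasses.replace(
            epo, CL_EPO=1e-12, V_MEPO=0.0, K_CPEPO=0.0, K_PCEPO=0.0
        )
        ev = [DoseEvent(0.0, "EPO", "SC", 500.0, 0.3)]
        grid = np.linspace(0, 200, 101)
        prof = simulate_pk(p, ev, grid)
        # central concentration approaches F*D/V as the depot empties
        expected = p.F_E * 150.0 / p.V_CEPO
        assert prof.free_conc[-1] == pytest.approx(expected, rel=1e-5)

    def test_linear_limit_matches_monoexponential(self, rat_pk):
        epo, _ = rat_pk
        p = dataclasses.replace(
            epo, V_MEPO=0.0, K_CPEPO=0.0, K_PCEPO=0.0
        )
        ev = [DoseEvent(0.0, "EPO", "IV", 1000.0, 0.3)]
        grid = np.linspace(0, 48, 97)
        prof = simulate_pk(p, ev, grid)
        c0 = 300.0 / p.V_CEPO
        expected = c0 * np.exp(-p.CL_EPO / p.V_CEPO * grid)
        np.testing.assert_allclose(prof.free_conc, expected, rtol=1e-6)

    def test_mm_limit_agrees_with_linear_plus_extra_clearance(self, rat_pk):
        """Sub-saturating MM elimination acts like clearance V_M/K_M."""
        epo, _ = rat_pk
        # big K_M and fast internalization keep C << K_M and R_TOT ~ 0
        p_mm = dataclasses.replace(epo, V_MEPO=0.05, K_MEPO=5e4, K_INTE=50.0)
        p_lin = dataclasses.replace(
            epo, V_MEPO=0.0, CL_EPO=epo.CL_EPO + 0.05 / 5e4
        )
        ev = [DoseEvent(0.0, "EPO", "IV", 300.0, 0.3)]
        grid = np.linspace(0, 96, 193)
        c_mm = simulate_pk(p_mm, ev, grid).free_conc
        c_lin = simulate_pk(p_lin, ev, grid).free_conc
        assert c_mm.max() == pytest.approx(c_lin.max(), rel=0.01)
        assert np.trapezoid(c_mm, grid) == pytest.approx(
            np.trapezoid(c_lin, grid), rel=0.01
        )


class TestHumanEpoModel:
    def test_receptor_steady_without_drug(self, human_pk):
        epo, _ = human_pk
        d = P.human_epo_rhs(PKState(receptor_total_conc=epo.RTOT0), epo)
        assert d.receptor_total_conc == pytest.approx(0.0, abs=1e-12)

    def test_receptor_pool_constant_when_kint_equals_kdeg(self, human_pk):
        epo, _ = human_pk
        p = dataclasses.replace(epo, KINT_E=epo.KDEG_E)
        s = PKState(central_amount=5000.0, receptor_total_conc=epo.RTOT0)
        d = P.human_epo_rhs(s, p)
        assert d.receptor_total_conc == pytest.approx(0.0, abs=1e-12)

    def test_terminal_decline_slower_than_central_elimination_alone(
        self, human_pk
    ):
        epo, _ = human_pk
        ev = [DoseEvent(0.0, "EPO", "IV", 100.0, 70.0)]
        grid = np.arange(0.0, 336.5, 0.5)
        prof = simulate_pk(epo, ev, grid)
        m = (grid >= 200) & (prof.free_conc > 0)
        slope = np.polyfit(grid[m], np.log(prof.free_conc[m]), 1)[0]
        assert prof.free_conc[m].max() < epo.KM_E  # sub-KM window
        assert -slope < epo.CL_E / epo.V2E
        # and the receptor route does change the terminal phase
        lin = simulate_pk(
            dataclasses.replace(epo, RTOT0=1e-9), ev, grid
        )
        slope_lin = np.polyfit(grid[m], np.log(lin.free_conc[m]), 1)[0]
        assert slope != pytest.approx(slope_lin, rel=0.05)


class TestHumanRomiModel:
    def test_collapses_to_linear_without_receptor(self, human_pk):
        _, romi = human_pk
        p0 = dataclasses.replace(romi, XI_R=0.0, KINT_R=1e-9)
        s = PKState(central_amount=35.0)
        d0 = P.human_romi_rhs(s, p0, platelet_pool=0.23)
        c = 35.0 / romi.V2R
        expected = -(romi.CL_R + romi.KCPR * romi.V2R) * c
        assert d0.central_amount == pytest.approx(expected, rel=1e-9)

    def test_doubling_platelets_lowers_free_concentration(self, human_pk):
        _, romi = human_pk
        s = PKState(central_amount=35.0)
        # more receptor -> more drug bound -> slower linear-clearance loss
        d1 = P.human_romi_rhs(s, romi, platelet_pool=0.23)
        d2 = P.human_romi_rhs(s, romi, platelet_pool=0.46)
        assert d2.peripheral_amount < d1.peripheral_amount  # K_CP*V*C smaller


class TestSimulatePK:
    def test_no_events_gives_zero_profile(self, human_pk):
        epo, _ = human_pk
        grid = np.linspace(0, 100, 51)
        prof = simulate_pk(epo, [], grid)
        assert np.all(prof.free_conc == 0.0)

    def test_iv_bolus_matches_two_compartment_closed_form(self, human_pk):
        """Linear limit vs the bi-exponential analytic solution."""
        epo, _ = human_pk
        p = dataclasses.replace(epo, RTOT0=1e-12)
        dose = 7000.0
        k10 = p.CL_E / p.V2E
        k12 = p.Q_E / p.V2E
        k21 = p.Q_E / p.V3E
        s = k10 + k12 + k21
        disc = np.sqrt(s * s - 4 * k10 * k21)
        alpha, beta = (s + disc) / 2, (s - disc) / 2
        grid = np.linspace(0, 72, 145)
        expect = (dose / p.V2E) * (
            (alpha - k21) / (alpha - beta) * np.exp(-alpha * grid)
            + (k21 - beta) / (alpha - beta) * np.exp(-beta * grid)
        )
        prof = simulate_pk(
            p, [DoseEvent(0.0, "EPO", "IV", 100.0, 70.0)], grid
        )
        np.testing.assert_allclose(prof.free_conc, expect, rtol=1e-3)

    def test_repeated_weekly_dosing_reaches_periodic_steady_state(
        self, human_pk
    ):
        epo, _ = human_pk
        weeks = 10
        ev = [
            DoseEvent(168.0 * w, "EPO", "SC", 600.0, 70.0)
            for w in range(weeks)
        ]
        grid = np.arange(0.0, 168.0 * weeks + 1, 1.0)
        prof = simulate_pk(epo, ev, grid)
        troughs = [prof.free_conc[168 * w - 1] for w in range(2, weeks + 1)]
        diffs = np.abs(np.diff(troughs)) / troughs[-1]
        assert diffs[-1] < 1e-3
        assert diffs[-1] < diffs[0]

    def test_event_beyond_grid_rejected(self, human_pk):
        epo, _ = human_pk
        with pytest.raises(ValueError):
            simulate_pk(
                epo,
                [DoseEvent(500.0, "EPO", "IV", 10.0, 70.0)],
                np.linspace(0, 100, 11),
            )

    def test_profiles_never_negative_and_grid_validated(self, human_pk):
        epo, _ = human_pk
        ev = [DoseEvent(24.0 * d, "EPO", "IV", 50.0, 70.0) for d in range(5)]
        grid = np.arange(0.0, 240.5, 0.5)
        prof = simulate_pk(epo, ev, grid)
        assert np.all(prof.free_conc >= 0.0)
        with pytest.raises(ValueError):
            ConcProfile(np.array([1.0, 1.0]), np.array([0.0, 0.0]), "EPO", "IU/L")
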