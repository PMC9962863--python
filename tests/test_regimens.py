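"""Regimen schedules, threshold verdicts, and population bands."""

import numpy as np
import pytest

import hemoscale as hs
from hemoscale.regimens import (
    RegimenError,
    RegimenSpec,
    RegimenVerdict,
    build_schedule,
    classify_regimens,
    first_threshold_crossing,
    population_bands,
    run_regimen,
    table2_regimens,
)


def _romi_days(spec):
    return [
        e.time / 24.0 for e in build_schedule(spec) if e.drug == "ROMI"
    ]


class TestSchedules:
    def test_q4w_from_week_two_doses_in_weeks_2_6_10_14(self):
        spec = table2_regimens()[8]
        assert _romi_days(spec) == [7, 35, 63, 91]

    def test_q3w_from_week_two_doses_in_weeks_2_5_8_11_14(self):
        spec = table2_regimens()[5]
        assert _romi_days(spec) == [7, 28, 49, 70, 91]

    def test_tiw_single_week_has_three_doses(self):
        spec = RegimenSpec(
            epo_dose_per_kg=50, epo_pattern="TIW", duration_weeks=1
        )
        events = build_schedule(spec)
        assert len(events) == 3
        assert [e.time for e in events] == [0.0, 48.0, 96.0]

    @pytest.mark.parametrize("weeks", [1, 4, 16])
    def test_tiw_cardinality(self, weeks):
        spec = RegimenSpec(
            epo_dose_per_kg=50, epo_pattern="TIW", duration_weeks=weeks
        )
        assert len(build_schedule(spec)) == 3 * weeks

    @pytest.mark.parametrize(
        "interval,start,expected",
        [(1, 1, 16), (2, 1, 8), (2, 2, 8), (3, 1, 6), (3, 2, 5),
         (2, 3, 7), (4, 1, 4), (4, 2, 4)],
    )
    def test_romi_cardinality_matches_ceiling_rule(
        self, interval, start, expected
    ):
        spec = RegimenSpec(
            romi_dose_per_kg=1.0, romi_interval_weeks=interval,
            romi_start_week=start, duration_weeks=16,
        )
        assert len(_romi_days(spec)) == expected
        assert spec.n_romi_doses == expected


class TestThresholdCrossing:
    def test_never_crossing_returns_none(self):
        t = np.arange(0, 1000.0)
        assert first_threshold_crossing(t, np.full_like(t, 0.23), 0.35) is None

    def test_crossing_at_hour_250_is_day_11(self):
        t = np.arange(0, 1000.0)
        p = np.where(t >= 250, 0.4, 0.2)
        assert first_threshold_crossing(t, p, 0.35) == 11

    def test_positive_trajectory_crosses_zero_threshold_on_day_one(self):
        t = np.arange(0, 100.0)
        assert first_threshold_crossing(t, np.full_like(t, 0.2), 0.0) == 1

    def test_empty_trajectory_rejected(self):
        with pytest.raises(RegimenError):
            first_threshold_crossing(np.array([]), np.array([]), 0.35)

    def test_verdict_consistency_enforced(self):
        with pytest.raises(RegimenError):
            RegimenVerdict(
                first_crossing_day=5, peak_hgb=14.0, peak_hgb_day=3,
                acceptable=True,
            )


class TestRunRegimen:
    def test_zero_doses_stay_at_baseline_and_acceptable(
        self, human_pk, human_pd
    ):
        spec = RegimenSpec(duration_weeks=2)
        res = run_regimen(spec, *human_pk, human_pd, followup_weeks=0)
        assert res.verdict.acceptable
        assert res.verdict.first_crossing_day is None
        assert res.trajectory.plt == pytest.approx(human_pd.plt0, rel=1e-4)
        assert res.verdict.peak_hgb == pytest.approx(13.29, abs=0.01)

    def test_epo_monotherapy_shows_resistance_and_platelet_dip(
        self, human_pk, human_pd
    ):
        """Continued rHuEPO: hemoglobin peaks then declines while doses
        continue; platelets sink below baseline (MEP competition)."""
        spec = RegimenSpec(
            epo_dose_per_kg=50.0, epo_pattern="TIW", epo_route="IV"
        )
        res = run_regimen(spec, *human_pk, human_pd)
        traj = res.trajectory
        assert traj.plt.min() < 0.9 * human_pd.plt0
        i_peak = np.argmax(traj.hgb)
        assert traj.time[i_peak] < 112 * 24.0  # peak during dosing
        hgb_end_of_dosing = traj.hgb[np.searchsorted(traj.time, 112 * 24.0)]
        assert hgb_end_of_dosing < traj.hgb[i_peak] - 0.1
        assert traj.hgb[i_peak] > 13.3

    def test_romi_monotherapy_crosses_threshold_within_two_weeks(
        self, human_pk, human_pd
    ):
        spec = RegimenSpec(
            romi_dose_per_kg=1.0, romi_interval_weeks=1, romi_start_week=1,
            duration_weeks=4,
        )
        res = run_regimen(spec, *human_pk, human_pd, followup_weeks=1)
        assert res.verdict.first_crossing_day is not None
        assert res.verdict.first_crossing_day <= 14

    def test_coarse_grid_rejected_for_verdicts(self, human_pk, human_pd):
        with pytest.raises(RegimenError):
            run_regimen(
                RegimenSpec(duration_weeks=1), *human_pk,
                hs.default_human_pd(), grid_step_h=6.0,
            )

    def test_delaying_romi_start_never_crosses_earlier(
        self, human_pk, human_pd
    ):
        """Dominance across the Q2W family (start weeks 1, 2, 3)."""
        days = []
        for start in (1, 2, 3):
            spec = RegimenSpec(
                epo_dose_per_kg=50.0, epo_pattern="TIW", epo_route="IV",
                romi_dose_per_kg=1.0, romi_interval_weeks=2,
                romi_start_week=start, duration_weeks=8,
            )
            res = run_regimen(spec, *human_pk, human_pd, followup_weeks=2)
            days.append(res.verdict.first_crossing_day)
        numeric = [d if d is not None else np.inf for d in days]
        assert numeric == sorted(numeric)
        assert numeric[0] < numeric[-1]


class TestClassification:
    def test_empty_battery_gives_empty_table(self, human_pk, human_pd):
        res = classify_regimens({}, *human_pk, human_pd)
        assert len(res.table) == 0
        assert res.recommended is None

    def test_recommendation_prefers_fewest_doses_then_latest_start(self):
        specs = table2_regimens()
        # among regimens 5 (5 doses) and 8 (4 doses), 8 wins
        assert specs[8].n_romi_doses < specs[5].n_romi_doses
        # 7 and 8 tie at 4 doses; 8 starts later
        assert specs[7].n_romi_doses == specs[8].n_romi_doses
        assert specs[8].romi_start_week > specs[7].romi_start_week


class TestPopulationBands:
    def test_zero_cv_collapses_bands_onto_typical_subject(
        self, human_pk, human_pd
    ):
        spec = RegimenSpec(
            epo_dose_per_kg=50.0, epo_pattern="TIW", duration_weeks=1
        )
        bands = population_bands(
            spec, *human_pk, human_pd, n_replicates=3, cv_baseline=0.0,
            seed=5, followup_weeks=0,
        )
        lo, mid, hi = bands.band("hgb")
        np.testing.assert_allclose(lo, hi, rtol=1e-9)
        typical = run_regimen(
            spec, *human_pk, human_pd, followup_weeks=0
        ).trajectory.hgb
        np.testing.assert_allclose(mid, typical, rtol=1e-6)

    def test_band_ordering_and_reproducibility(self, human_pk, human_pd):
        spec = RegimenSpec(
            epo_dose_per_kg=50.0, epo_pattern="TIW", duration_weeks=1
        )
        kw = dict(n_replicates=20, cv_baseline=0.10, seed=11,
                  followup_weeks=0)
        b1 = population_bands(spec, *human_pk, human_pd, **kw)
        b2 = population_bands(spec, *human_pk, human_pd, **kw)
        for obs in ("hgb", "rbc", "plt"):
            lo, mid, hi = b1.band(obs)
            assert np.all(lo <= mid + 1e-12)
            assert np.all(mid <= hi + 1e-12)
            np.testing.assert_array_equal(lo, b1.bands[f"{obs}_p20"])
            np.testing.assert_array_equal(
                b1.bands[f"{obs}_p50"], b2.bands[f"{obs}_p50"]
            )

    def test_baseline_hgb_band_width_matches_lognormal_quantiles(
        self, human_pk, human_pd
    ):
        """10% CV lognormal baselines: the 20th-80th Hgb half-width at
        t = 0 is ~ 13.3 * sigma * z_0.8 ~ 1.1 g/dL."""
        spec = RegimenSpec(duration_weeks=1)  # no drug: pure baseline draws
        bands = population_bands(
            spec, *human_pk, human_pd, n_replicates=200, cv_baseline=0.10,
            seed=3, followup_weeks=0,
        )
        lo, _, hi = bands.band("hgb")
        half_width = (hi[0] - lo[0]) / 2
        assert half_width == pytest.approx(1.1, abs=0.25)

    def test_invalid_cv_rejected(self, human_pk, human_pd):
        with pytest.raises(RegimenError):
            population_bands(
                RegimenSpec(duration_weeks=1), *human_pk, human_pd,
                n_replicates=2, cv_baseline=-0.1,
            )
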