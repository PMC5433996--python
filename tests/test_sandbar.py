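"""The emergent-sandbar habitat model: per-year windows and summaries."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from sandwin import (
    PLOVER,
    TERN,
    DailyFlowSeries,
    HydrographParams,
    ReachConfig,
    SpeciesProfile,
    daily_emergence,
    generate_daily_hydrograph,
    generate_rating_curve,
    max_contiguous,
    run_reach,
    sandbar_stage,
    success_window,
    summarize,
)
from sandwin.sandbar import results_to_frame
from conftest import flow_series


class TestSandbarStage:
    @pytest.mark.parametrize(
        "stage_hab,bar,expected",
        [(2.00, 0.46, 1.54), (3.00, 0.61, 2.39), (1.7, 0.0, 1.7)],
    )
    def test_subtraction(self, stage_hab, bar, expected):
        assert sandbar_stage(stage_hab, bar) == pytest.approx(expected)

    def test_negative_bar_rejected(self):
        with pytest.raises(ValueError):
            sandbar_stage(2.0, -0.1)


class TestSpeciesProfiles:
    def test_default_success_periods(self):
        assert PLOVER.success_period == 8 + 28 + 28 == 64
        assert TERN.success_period == 3 + 21 + 21 == 45

    def test_season_lengths_constant_across_leap_years(self):
        assert PLOVER.season_length == 118
        assert TERN.season_length == 95
        assert len(PLOVER.season_dates(2000)) == 118  # leap year, May–Aug unaffected


class TestDailyEmergence:
    def make_curve(self):
        return generate_rating_curve(0.1, 0.5, 1.0, 5000.0, n_points=2000)

    def test_all_emergent_when_stage_bar_high(self):
        curve = self.make_curve()
        flows = flow_series("2000-05-01", [100.0] * 118)
        season = PLOVER.season_dates(2000)
        emergent = daily_emergence(flows, curve, stage_bar=5.0, season=season)
        assert emergent.all()

    def test_tie_with_inundating_discharge_counts_as_inundated(self):
        curve = self.make_curve()
        flows = flow_series("2000-05-01", [100.0] * 118)
        season = PLOVER.season_dates(2000)
        stage_bar = float(curve.stage_at(100.0))  # daily stage == sandbar stage
        emergent = daily_emergence(flows, curve, stage_bar, season)
        assert not emergent.any()

    def test_midseason_spike_splits_into_two_runs(self):
        curve = self.make_curve()
        values = np.full(118, 50.0)
        values[40:45] = 2000.0  # 5-day mid-June spike over the bars
        flows = flow_series("2000-05-01", values)
        season = PLOVER.season_dates(2000)
        stage_bar = float(curve.stage_at(500.0))
        emergent = daily_emergence(flows, curve, stage_bar, season)
        assert max_contiguous(emergent) == 118 - 45
        assert emergent[:40].all() and not emergent[40:45].any() and emergent[45:].all()

    def test_missing_days_are_not_emergent_and_reported(self):
        curve = self.make_curve()
        idx = PLOVER.season_dates(2000)[:-10]
        flows = DailyFlowSeries("x", pd.Series(10.0, index=idx))
        emergent, present = daily_emergence(
            flows, curve, 5.0, PLOVER.season_dates(2000), return_present=True
        )
        assert present.sum() == 108
        assert not emergent[-10:].any()

    def test_season_outside_record_errors(self):
        curve = self.make_curve()
        flows = flow_series("1990-01-01", [10.0] * 100)
        with pytest.raises(ValueError):
            daily_emergence(flows, curve, 5.0, PLOVER.season_dates(2000))


class TestMaxContiguous:
    @pytest.mark.parametrize(
        "seq,expected",
        [([True, True, False, True, True, True], 3), ([], 0), ([False] * 6, 0), ([True] * 4, 4)],
    )
    def test_examples(self, seq, expected):
        assert max_contiguous(seq) == expected

    def test_equals_brute_force_on_all_sequences_up_to_length_12(self):
        def brute(bits):
            best = 0
            for i in range(len(bits)):
                for j in range(i, len(bits)):
                    if all(bits[i : j + 1]):
                        best = max(best, j - i + 1)
            return best

        for n in range(13):
            for bits in itertools.product([False, True], repeat=n):
                assert max_contiguous(bits) == brute(bits), bits


class TestSuccessWindow:
    @pytest.mark.parametrize(
        "run,period,expected",
        [(118, 64, 54), (30, 64, 0), (45, 45, 0), (46, 45, 1), (0, 0, 0)],
    )
    def test_examples(self, run, period, expected):
        assert success_window(run, period) == expected


def build_reach(values, start="1999-01-01", bar=0.46, coeff=0.1, exp=0.5, years=(2000, 2000)):
    flows = flow_series(start, values)
    curve = generate_rating_curve(coeff, exp, 1.0, 10_000.0, n_points=2000)
    return ReachConfig("synthetic", curve, bar, flows, years)


class TestRunReach:
    def test_large_prior_peak_low_season_gives_season_long_window(self):
        n = (pd.Timestamp("2000-12-31") - pd.Timestamp("1999-01-01")).days + 1
        values = np.full(n, 30.0)
        values[150] = 2000.0  # big habitat-forming peak mid-1999
        reach = build_reach(values)
        (res,) = run_reach(reach, PLOVER)
        assert res.disch_hab == 2000.0
        assert res.season_long
        assert res.success_window == 118 - 64
        assert res.max_contiguous_emergent == 118

    def test_late_june_spike_zeroes_plover_window(self):
        n = (pd.Timestamp("2000-12-31") - pd.Timestamp("1999-01-01")).days + 1
        values = np.full(n, 30.0)
        values[150] = 800.0
        # 3-day spike from 21 June 2000 tops the bars and splits the season
        # into runs of 51 d (1 May–20 Jun) and 64 d (24 Jun–26 Aug): both
        # shorter than the 65 d a plover nest start needs
        spike = (pd.Timestamp("2000-06-21") - pd.Timestamp("1999-01-01")).days
        values[spike : spike + 3] = 700.0
        reach = build_reach(values)
        (res,) = run_reach(reach, PLOVER)
        assert res.max_contiguous_emergent == 64
        assert res.success_window == 0
        # the same split leaves the least tern a usable window
        (tern_res,) = run_reach(reach, TERN)
        assert tern_res.success_window > 0

    def test_zero_bar_height_with_subpeak_flows_never_inundates(self):
        n = (pd.Timestamp("2000-12-31") - pd.Timestamp("1999-01-01")).days + 1
        values = np.full(n, 50.0)
        values[100] = 500.0
        reach = build_reach(values, bar=0.0)
        (res,) = run_reach(reach, PLOVER)
        assert res.season_long
        assert res.inundating_discharge == pytest.approx(res.disch_hab, rel=1e-9)

    def test_inundating_discharge_below_habitat_forming_peak(self):
        rng = np.random.default_rng(5)
        n = 365 * 2 + 1
        values = rng.uniform(20, 60, n)
        values[180] = 900.0
        reach = build_reach(values, bar=0.46)
        (res,) = run_reach(reach, PLOVER)
        assert res.inundating_discharge < res.disch_hab

    def test_results_frame_has_one_row_per_year(self):
        flows = generate_daily_hydrograph(HydrographParams(), 1995, 6, seed=2)
        curve = generate_rating_curve(0.1, 0.5, 1.0, 10_000.0)
        reach = ReachConfig("r", curve, 0.46, flows, (1996, 2000))
        frame = results_to_frame(run_reach(reach, TERN))
        assert len(frame) == 5
        assert list(frame["year"]) == [1996, 1997, 1998, 1999, 2000]


def make_result(**overrides):
    from sandwin import HabitatYearResult

    base = dict(
        year=2000,
        species="piping_plover",
        disch_hab=100.0,
        stage_hab=1.0,
        stage_bar=0.5,
        inundating_discharge=25.0,
        max_contiguous_emergent=0,
        success_window=0,
        season_long=False,
        coverage_ok=True,
    )
    base.update(overrides)
    return HabitatYearResult(**base)


class TestSummarize:
    def make(self, windows, season_long=None):
        season_long = season_long or [False] * len(windows)
        return [
            make_result(year=2000 + i, success_window=w, season_long=sl)
            for i, (w, sl) in enumerate(zip(windows, season_long))
        ]

    def test_small_set_arithmetic(self):
        s = summarize(self.make([0, 0, 10]))
        assert s.median_window == 0
        assert s.pct_no_window == pytest.approx(200 / 3)

    def test_even_count_median_mean_of_central_pair(self):
        s = summarize(self.make([4, 4]))
        assert s.median_window == 4
        s2 = summarize(self.make([0, 10]))
        assert s2.median_window == 5

    def test_all_season_long(self):
        s = summarize(self.make([54, 54], season_long=[True, True]))
        assert s.pct_season_long == 100.0
        assert s.median_window == 118 - 64

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize([])


class TestMonotonicityProperties:
    """Monotone responses across ≥ 100 random synthetic scenarios."""

    def scenarios(self, n=100):
        rng = np.random.default_rng(77)
        for i in range(n):
            params = HydrographParams(
                baseflow=float(rng.uniform(10, 80)),
                early_rise_peak=float(rng.uniform(0, 300)),
                late_rise_peak=float(rng.uniform(50, 800)),
                rise_width_days=float(rng.uniform(8, 25)),
                noise_sigma=float(rng.uniform(0, 0.5)),
                noise_rho=float(rng.uniform(0, 0.95)),
                interannual_cv=float(rng.uniform(0, 0.8)),
            )
            flows = generate_daily_hydrograph(params, 2000, 3, seed=int(rng.integers(2**31)))
            curve = generate_rating_curve(
                float(rng.uniform(0.03, 0.3)),
                float(rng.uniform(0.2, 0.8)),
                1.0,
                20_000.0,
                n_points=200,
            )
            yield flows, curve, float(rng.uniform(0, 1.0))

    def test_deeper_bars_never_lengthen_windows(self):
        for flows, curve, bar in self.scenarios():
            lo = ReachConfig("a", curve, bar, flows, (2001, 2002))
            hi = ReachConfig("b", curve, bar + 0.25, flows, (2001, 2002))
            for r_lo, r_hi in zip(run_reach(lo, PLOVER), run_reach(hi, PLOVER)):
                assert r_hi.success_window <= r_lo.success_window

    def test_longer_success_period_never_lengthens_windows(self):
        short = SpeciesProfile("short", (5, 1), (8, 26), 3, 21, 21)
        long = SpeciesProfile("long", (5, 1), (8, 26), 8, 28, 28)
        for flows, curve, bar in self.scenarios():
            reach = ReachConfig("r", curve, bar, flows, (2001, 2002))
            for r_s, r_l in zip(run_reach(reach, short), run_reach(reach, long)):
                assert r_l.success_window <= r_s.success_window

    def test_stage_scaling_direction(self):
        # with bars a fixed depth below peak stage, the emergence condition is
        # factor · (STAGE_HAB − STAGE_DAILY) > bar_height: windows are weakly
        # monotone increasing in the stage-per-discharge factor
        for flows, curve, bar in self.scenarios():
            soft = curve.scale_stage_response(0.7, pivot_discharge=float(curve.discharge[0]))
            steep = curve.scale_stage_response(1.3, pivot_discharge=float(curve.discharge[0]))
            base = ReachConfig("b", curve, bar, flows, (2001, 2002))
            softer = ReachConfig("s", soft, bar, flows, (2001, 2002))
            steeper = ReachConfig("t", steep, bar, flows, (2001, 2002))
            for r_soft, r_base, r_steep in zip(
                run_reach(softer, TERN), run_reach(base, TERN), run_reach(steeper, TERN)
            ):
                assert r_soft.success_window <= r_base.success_window
                assert r_base.success_window <= r_steep.success_window

    def test_median_zero_consistency_with_no_window_share(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            windows = rng.integers(0, 5, size=rng.integers(1, 12))
            results = [
                make_result(year=2000 + i, success_window=int(w))
                for i, w in enumerate(windows)
            ]
            s = summarize(results)
            if s.pct_no_window > 50:
                assert s.median_window == 0
            if s.median_window == 0:
                assert s.pct_no_window >= 50
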