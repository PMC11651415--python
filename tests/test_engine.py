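"""Growth engine: AFGEN tables, process steps, conservation laws."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from napus.engine import (SimulationState, daily_gross_assimilation,
                          leaf_dynamics, maintenance_respiration,
                          partition_and_grow, phenology_step, pod_area_update,
                          run_simulation, water_balance_step, CO2_TO_CH2O)
from napus.params import (AfgenTable, ConfigurationError, CropParameterSet,
                          afgen_eval)
from napus.synth import WeatherGenSpec, generate_truth, generate_weather
from napus.weather import Station, WeatherSeries


def _state(**kw):
    return SimulationState(day=dt.date(2021, 1, 1), **kw)


class TestAfgen:
    def test_midpoint_of_a_line(self):
        assert afgen_eval(AfgenTable([(0, 0), (2, 2)]), 1.0) == pytest.approx(1.0)

    def test_clamping_at_both_ends(self):
        t = AfgenTable([(0.3, 5.0), (1.0, 7.0)])
        assert t(-1.0) == 5.0
        assert t(9.0) == 7.0

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(2, 8), st.floats(-1, 3), st.integers(0, 10_000))
    def test_matches_brute_force_segment_search(self, npts, x, seed):
        rng = np.random.default_rng(seed)
        xs = np.sort(rng.uniform(0, 2, npts))
        if np.unique(xs).size < npts or np.diff(xs).min() < 1e-6:
            return
        ys = rng.uniform(-5, 5, npts)
        table = AfgenTable(zip(xs, ys))

        def brute(v):
            if v <= xs[0]:
                return ys[0]
            if v >= xs[-1]:
                return ys[-1]
            for i in range(npts - 1):
                if xs[i] <= v <= xs[i + 1]:
                    w = (v - xs[i]) / (xs[i + 1] - xs[i])
                    return ys[i] * (1 - w) + ys[i + 1] * w

        assert table(x) == pytest.approx(brute(x), abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            AfgenTable([(0, 1)])


class TestPhenology:
    def test_tmean_at_base_keeps_dvs_zero(self):
        p = CropParameterSet()
        s = _state(emerged=True)
        for _ in range(50):
            phenology_step(s, p, p.TBASE)
        assert s.DVS == 0.0

    def test_dvs_one_reached_on_day_seventy(self):
        p = CropParameterSet(TSUM1=700.0)
        s = _state(emerged=True)
        days = 0
        while s.DVS < 1.0:
            phenology_step(s, p, p.TBASE + 10.0)  # effective 10 degC per day
            days += 1
        assert days == 70

    def test_dvs_nondecreasing_under_arbitrary_weather(self):
        p = CropParameterSet()
        s = _state(emerged=True)
        rng = np.random.default_rng(3)
        prev = 0.0
        for t in rng.uniform(-15, 35, 400):
            d = phenology_step(s, p, t)
            assert d >= prev
            prev = d
        assert prev <= 2.0

    def test_nonpositive_tsum_rejected(self):
        p = CropParameterSet()
        p.TSUM1 = 0.0
        with pytest.raises(ConfigurationError):
            phenology_step(_state(emerged=True), p, 15.0)


class TestAssimilation:
    GEOM = dict(daylength=11.0, sinld=0.2, cosld=0.85, dsinbe=28_000.0)

    def test_zero_radiation_gives_zero(self):
        p = CropParameterSet()
        assert daily_gross_assimilation(3.0, 1.0, p, 0.0, 18.0, **self.GEOM) == 0.0

    def test_zero_canopy_gives_zero(self):
        p = CropParameterSet()
        assert daily_gross_assimilation(0.0, 1.0, p, 9000.0, 18.0, **self.GEOM) == 0.0

    def test_negative_radiation_rejected(self):
        with pytest.raises(ValueError):
            daily_gross_assimilation(1.0, 1.0, CropParameterSet(), -1.0, 18.0,
                                     **self.GEOM)

    def test_light_limited_regime_matches_eff_times_absorbed_par(self):
        # huge AMAX, dim light: response is linear, so canopy assimilation
        # equals EFF times the Gaussian-integrated absorbed PAR
        p = CropParameterSet()
        p.AMAXTB = AfgenTable([(0.0, 1e6), (2.0, 1e6)])
        p.TMPFTB = AfgenTable([(0.0, 1.0), (40.0, 1.0)])
        tpai, dvs, rad, tday = 0.05, 1.0, 50.0, 20.0
        got = daily_gross_assimilation(tpai, dvs, p, rad, tday, **self.GEOM)
        eff = afgen_eval(p.EFFTB, tday)
        kdif = afgen_eval(p.KDIFTB, dvs)
        gx = (0.1127016653792583, 0.5, 0.8872983346207417)
        gw = (0.2777777777777778, 0.4444444444444444, 0.2777777777777778)
        expected = 0.0
        for xt, wt in zip(gx, gw):
            hour = 12 + 0.5 * self.GEOM["daylength"] * xt
            sinb = max(0.0, self.GEOM["sinld"] + self.GEOM["cosld"]
                       * math.cos(2 * math.pi * (hour + 12) / 24))
            par = 0.5 * rad * 1000 * sinb * (1 + 0.4 * sinb) / self.GEOM["dsinbe"]
            layer = sum(wd * par * (1 - p.canopy_reflection) * kdif
                        * math.exp(-kdif * tpai * xd)
                        for xd, wd in zip(gx, gw))
            expected += wt * eff * layer * tpai * self.GEOM["daylength"]
        assert got == pytest.approx(expected, rel=0.01)


class TestRespirationAndPartition:
    def test_empty_crop_respires_nothing(self):
        p = CropParameterSet()
        assert maintenance_respiration(_state(), p, 20.0) == 0.0

    def test_reference_temperature_product(self):
        p = CropParameterSet()
        p.RML, p.RMO, p.RMR, p.RMS = 0.03, 0.0, 0.0, 0.0
        s = _state(W_leaf=1000.0)
        assert maintenance_respiration(s, p, 25.0) == pytest.approx(30.0)

    def test_degenerate_partition_sends_everything_to_storage(self):
        p = CropParameterSet()
        p.FLTB = AfgenTable([(0.0, 0.0), (2.0, 0.0)])
        p.FSTB = AfgenTable([(0.0, 0.0), (2.0, 0.0)])
        p.FOTB = AfgenTable([(0.0, 1.0), (2.0, 1.0)])
        p.FRTB = AfgenTable([(0.0, 0.0), (2.0, 0.0)])
        s = _state(emerged=True)
        d = partition_and_grow(s, p, 100.0)
        assert d["d_so"] == pytest.approx(p.CVO * 100.0)
        assert d["d_leaf"] == d["d_stem"] == d["d_root"] == 0.0

    def test_partition_sum_violation_rejected(self):
        p = CropParameterSet()
        p.FLTB = AfgenTable([(0.0, 0.5), (2.0, 0.5)])
        p.FSTB = AfgenTable([(0.0, 0.4), (2.0, 0.4)])
        p.FOTB = AfgenTable([(0.0, 0.0), (2.0, 0.0)])
        with pytest.raises(ConfigurationError):
            partition_and_grow(_state(emerged=True), p, 10.0)

    def test_lossless_conversion_conserves_mass(self):
        p = CropParameterSet()
        p.CVL = p.CVO = p.CVR = p.CVS = 1.0
        s = _state(emerged=True)
        before = s.W_stem + s.W_so + s.W_root
        d = partition_and_grow(s, p, 50.0)
        gained = (s.W_stem + s.W_so + s.W_root - before) + d["d_leaf"]
        assert gained == pytest.approx(50.0, rel=1e-12)


class TestLeafDynamics:
    def test_stasis_when_nothing_grows_or_dies(self):
        p = CropParameterSet()
        s = _state(leaf_cohorts=[[10.0, 0.02, 1.0]], W_leaf=10.0, LAI=0.02)
        lai = leaf_dynamics(s, p, 15.0, 0.0)
        assert lai == pytest.approx(0.02)
        assert s.W_leaf_dead == 0.0

    def test_cohort_death_conserves_mass(self):
        p = CropParameterSet()
        s = _state(leaf_cohorts=[[10.0, 0.02, p.SPAN + 0.5]], W_leaf=10.0)
        leaf_dynamics(s, p, 15.0, 0.0)
        assert s.W_leaf == pytest.approx(0.0)
        assert s.W_leaf_dead == pytest.approx(10.0)
        assert s.LAI == 0.0

    def test_total_leaf_mass_equals_cumulative_allocation(self, weather, truth):
        trace = run_simulation(truth, weather).frame
        total = trace["W_leaf"] + trace["W_leaf_dead"]
        init = total.iloc[5]  # after emergence, before any senescence
        cum = trace["d_leaf"].cumsum()
        assert np.allclose(total[5:], init + cum[5:] - cum.iloc[5], rtol=1e-9)


class TestPodAreaAndWater:
    def test_zero_spa_means_leaf_only_canopy(self, weather, truth):
        p = truth.copy()
        p.SPA = 0.0
        trace = run_simulation(p, weather).frame
        assert np.allclose(trace["PAI"], 0.0)
        assert np.allclose(trace["TPAI"], trace["LAI"])

    def test_pod_area_product(self):
        p = CropParameterSet()
        s = _state(DVS=1.5, W_so=4000.0)
        assert pod_area_update(s, p) == pytest.approx(0.00065 * 4000.0)
        assert s.TPAI == pytest.approx(s.LAI + s.PAI)

    def test_no_pod_area_before_flowering(self):
        s = _state(DVS=0.9, W_so=500.0)
        assert pod_area_update(s, CropParameterSet()) == 0.0

    def test_pai_nondecreasing_while_storage_grows(self, weather, truth):
        trace = run_simulation(truth, weather).frame
        m = trace["DVS"] > 1.0
        dso = np.diff(trace.loc[m, "TWSO"])
        dpai = np.diff(trace.loc[m, "PAI"])
        assert np.all(dpai[dso >= 0] >= -1e-12)

    def test_potential_mode_never_stresses(self, weather, truth):
        trace = run_simulation(truth, weather, mode="potential").frame
        assert np.all(trace["stress"] == 1.0)

    def test_drawdown_without_rain(self):
        p = CropParameterSet()
        s = _state(TPAI=3.0, soil_water=10.0)
        levels = []
        for _ in range(30):
            sw, _, _ = water_balance_step(s, p, 20.0, 14.0, 26.0, 0.0,
                                          30_000.0, 0.7, potential=False)
            levels.append(sw)
        assert all(b < a for a, b in zip([10.0] + levels, levels) if a > 1e-9)
        assert levels[-1] >= 0.0

    def test_water_ledger_closes_daily(self, weather, truth):
        trace = run_simulation(truth, weather, mode="water-limited").frame
        gap = trace["dstorage_cm"] - (trace["rain_cm"] - trace["water_loss_cm"]
                                      - trace["overflow_cm"])
        assert np.abs(gap).max() <= 1e-9


class TestRunSimulation:
    def test_bit_identical_reruns(self, weather, truth):
        a = run_simulation(truth, weather).frame
        b = run_simulation(truth, weather).frame
        pd.testing.assert_frame_equal(a, b)

    def test_twso_nondecreasing_in_spa(self, weather, truth):
        finals = []
        for spa in np.linspace(0.0002, 0.0009, 6):
            p = truth.copy()
            p.SPA = float(spa)
            finals.append(run_simulation(p, weather).final["TWSO"])
        assert all(b >= a - 1e-9 for a, b in zip(finals, finals[1:]))

    def test_tpai_identity_every_day(self, weather, truth):
        trace = run_simulation(truth, weather).frame
        assert np.allclose(trace["TPAI"], trace["LAI"] + trace["PAI"],
                           atol=1e-12)

    def test_twso_bounded_by_tagp_and_state_nonnegative(self, weather, truth):
        trace = run_simulation(truth, weather).frame
        assert (trace["TWSO"] <= trace["TAGP"] + 1e-9).all()
        for col in ("LAI", "PAI", "TPAI", "TWSO", "TAGP", "W_leaf", "W_stem",
                    "W_root", "soil_water"):
            assert (trace[col] >= -1e-12).all()

    def test_spa_zero_collapses_to_leaf_only_mode(self, weather, truth):
        p = truth.copy()
        p.SPA = 0.0
        a = run_simulation(p, weather, tpai_interception=True).frame
        b = run_simulation(p, weather, tpai_interception=False).frame
        pd.testing.assert_frame_equal(a, b)

    def test_respiration_never_exceeds_gross(self, weather, truth):
        trace = run_simulation(truth, weather).frame
        assert (trace["maintenance"] <= trace["gross_ch2o"] + 1e-12).all()

    def test_weather_gap_in_window_rejected(self, truth):
        df = generate_weather(WeatherGenSpec(seed=1)).frame
        with pytest.raises(Exception):
            WeatherSeries(Station("x", 112.0, 27.0),
                          pd.concat([df.iloc[:50], df.iloc[60:]]))
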