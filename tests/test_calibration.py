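"""Calibration: phenology, anchors, and single-parameter recovery."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from napus.calibration import (CalibrationError, ObservationCampaign,
                               calibrate_baseline_lai, calibrate_phenology,
                               emergence_date, exact_quadratic,
                               fit_tpai_quadratic, tpai_spa_calibrate)
from napus.engine import run_simulation
from napus.params import CropParameterSet
from napus.synth import CampaignGenSpec, WeatherGenSpec, generate_campaign, \
    generate_weather
from napus.weather import Station, WeatherSeries


def _constant_weather(tmean, days=250, start=dt.date(2020, 10, 15)):
    dates = [start + dt.timedelta(days=i) for i in range(days)]
    df = pd.DataFrame({"date": dates, "tmin": tmean - 3.0, "tmax": tmean + 3.0,
                       "precip": 1.0, "vap": 1.5, "wind": 2.0, "sunshine": 4.0})
    return WeatherSeries(Station("const", 112.0, 27.0), df)


def _campaign(dates, **cols):
    n = len(dates)
    base = dict(stage=["Seedling", "Budding", "Flowering", "Milky", "Maturity"][:n],
                date=dates, lai=[0.1] * n, sai=[0.0] * n, tpai=[0.1] * n,
                twso=[10.0] * n, tagp=[20.0] * n,
                siliques_present=[False] * n)
    base.update(cols)
    return pd.DataFrame(base)


class TestPhenologyCalibration:
    def test_constant_weather_arithmetic(self):
        p = CropParameterSet()
        w = _constant_weather(p.TBASE + 10.0)  # effective 10 degC per day
        emerg = emergence_date(p, w)
        flowering = emerg + dt.timedelta(days=70)
        maturity = flowering + dt.timedelta(days=74)
        stages = _campaign([emerg + dt.timedelta(days=5),
                            emerg + dt.timedelta(days=30),
                            flowering, flowering + dt.timedelta(days=40),
                            maturity])
        camp = ObservationCampaign(stages, p.sowing_date, maturity)
        tsum1, tsum2 = calibrate_phenology(camp, w, p)
        # 70 days at 10 degC effective, midpoint estimate: 695
        assert tsum1 == pytest.approx(695.0, abs=10.0)
        assert tsum2 == pytest.approx(735.0, abs=10.0)

    def test_flowering_at_emergence_rejected(self):
        p = CropParameterSet()
        w = _constant_weather(p.TBASE + 10.0)
        emerg = emergence_date(p, w)
        stages = _campaign([emerg - dt.timedelta(days=4),
                            emerg - dt.timedelta(days=2), emerg,
                            emerg + dt.timedelta(days=30),
                            emerg + dt.timedelta(days=60)])
        camp = ObservationCampaign(stages, p.sowing_date,
                                   emerg + dt.timedelta(days=60))
        with pytest.raises(CalibrationError):
            calibrate_phenology(camp, w, p)

    def test_twin_round_trip_recovers_thermal_totals(self, weather, truth):
        trace = run_simulation(truth, weather).frame
        flowering = trace.loc[trace["DVS"] >= 1.0, "date"].iloc[0]
        maturity = trace.loc[trace["DVS"] >= 2.0, "date"].iloc[0]
        emerg = emergence_date(truth, weather)
        stages = _campaign([emerg + dt.timedelta(days=10),
                            emerg + dt.timedelta(days=40),
                            flowering, flowering + dt.timedelta(days=20),
                            maturity])
        camp = ObservationCampaign(stages, truth.sowing_date, maturity)
        tsum1, tsum2 = calibrate_phenology(camp, weather, truth)
        # recovery within one day's effective temperature (~12 degC.d here)
        assert tsum1 == pytest.approx(truth.TSUM1, abs=12.0)
        assert tsum2 == pytest.approx(truth.TSUM2, abs=12.0)


class TestQuadraticAnchors:
    def test_parabola_through_canonical_points(self):
        coeff = exact_quadratic([0, 1, 2], [0, 1, 4])
        assert coeff == pytest.approx([1.0, 0.0, 0.0])

    def test_collinear_points_give_zero_curvature(self):
        coeff = exact_quadratic([0, 1, 2], [0, 1, 2])
        assert coeff[0] == pytest.approx(0.0, abs=1e-12)
        assert coeff[1] == pytest.approx(1.0)

    def test_random_anchors_match_lagrange_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.choice(np.arange(60), size=3, replace=False).astype(float)
            y = rng.uniform(0, 6, 3)
            coeff = exact_quadratic(x, y)
            for x0 in np.linspace(x.min(), x.max(), 7):
                lagrange = sum(
                    y[i] * np.prod([(x0 - x[j]) / (x[i] - x[j])
                                    for j in range(3) if j != i])
                    for i in range(3))
                assert np.polyval(coeff, x0) == pytest.approx(lagrange,
                                                              abs=1e-9)
            for xi, yi in zip(x, y):
                assert np.polyval(coeff, xi) == pytest.approx(yi, abs=1e-10)

    def test_duplicate_abscissae_rejected(self):
        with pytest.raises(CalibrationError):
            exact_quadratic([0, 0, 2], [0, 1, 4])

    def test_curve_from_campaign_passes_through_anchors(self, weather, truth,
                                                        campaign):
        trace = run_simulation(truth, weather)
        curve = fit_tpai_quadratic(trace, campaign)
        assert curve.provenance == "quadratic"
        assert len(curve.anchors) == 3
        lookup = dict(zip(curve.dates, curve.values))
        for d, v in curve.anchors:
            assert lookup[d] == pytest.approx(max(v, 0.0), abs=1e-9)
        assert (curve.values >= 0).all()

    def test_no_observation_between_peak_and_final_stage_rejected(
            self, weather, truth):
        trace = run_simulation(truth, weather)
        last = trace.frame["date"].iloc[-1]
        start = trace.frame["date"].iloc[0]
        # four early observations long before the LAI peak, then the final
        # stage: nothing lies strictly between t1 and t3
        dates = [start + dt.timedelta(days=d) for d in (10, 20, 30, 40)] + [last]
        camp = ObservationCampaign(_campaign(dates), truth.sowing_date, last)
        with pytest.raises(CalibrationError):
            fit_tpai_quadratic(trace, camp)


class TestObservationCampaign:
    def test_invariants_enforced(self, campaign):
        df = campaign.stages
        assert len(df) == 5
        assert np.allclose(df["tpai"], df["lai"] + df["sai"])
        assert (df["sai"].iloc[:3] == 0).all()

    def test_inconsistent_tpai_rejected(self, campaign):
        bad = campaign.stages.copy()
        bad.loc[4, "tpai"] = bad.loc[4, "tpai"] + 1.0
        with pytest.raises(CalibrationError):
            ObservationCampaign(bad, campaign.sowing_date, campaign.harvest_date)

    def test_csv_round_trip(self, campaign, tmp_path):
        path = tmp_path / "campaign.csv"
        campaign.to_csv(path)
        again = ObservationCampaign.from_csv(path)
        assert again.sowing_date == campaign.sowing_date
        assert np.allclose(again.stages["tpai"], campaign.stages["tpai"])


class TestBaselineRecovery:
    def test_self_consistent_observations_score_near_zero(self, weather, truth,
                                                          campaign):
        res = calibrate_baseline_lai(campaign, weather, truth,
                                     free_set=["SLATB0.00"])
        # noise-free observations generated by the engine itself: only the
        # stage-date phenology quantisation remains
        assert res.objective < 0.1
        assert res.params.get("SLATB0.00") == pytest.approx(
            truth.get("SLATB0.00"), rel=0.05)

    def test_single_parameter_perturbation_recovered(self, weather, truth,
                                                     campaign):
        p0 = truth.copy()
        p0.set("SLATB0.00", 0.0026)
        res = calibrate_baseline_lai(campaign, weather, p0,
                                     free_set=["SLATB0.00"])
        assert res.params.get("SLATB0.00") == pytest.approx(
            truth.get("SLATB0.00"), rel=0.05)

    def test_fitted_parameters_stay_in_bounds(self, weather, truth, campaign):
        p0 = truth.copy()
        p0.set("SLATB0.00", 0.004)
        res = calibrate_baseline_lai(campaign, weather, p0)
        from napus.params import bounds_for
        for tag in ("SLATB0.00", "KDIFTB2.00", "CVO"):
            lo, hi = bounds_for(tag)
            assert lo - 1e-12 <= res.params.get(tag) <= hi + 1e-12


class TestSpaLineSearch:
    def test_preset_truth_converges_without_stepping(self, weather):
        # a crop whose true SPA equals the preset: the first step away from
        # 0.007 must not improve the pod-stage misfit
        truth = CropParameterSet()
        truth.SPA = 0.007
        w = generate_weather(WeatherGenSpec(seed=21))
        camp = generate_campaign(CampaignGenSpec(truth=truth, noise_cv=0.0,
                                                 seed=0), w)
        res = tpai_spa_calibrate(camp, w, truth.copy(), free_set=["SPA"])
        trail = res.iteration_log[0]["line_search"]
        assert len(trail) <= 2          # initial point plus one rejected probe
        assert trail[0]["SPA"] == pytest.approx(0.007)

    def test_accepted_steps_never_increase_misfit(self, weather, truth,
                                                  campaign):
        p0 = truth.copy()
        p0.SPA = 0.0004
        res = tpai_spa_calibrate(campaign, weather, p0)
        trail = res.iteration_log[0]["line_search"]
        accepted = [trail[0]["rmse"]]
        for probe in trail[1:]:
            if probe["rmse"] < accepted[-1]:
                accepted.append(probe["rmse"])
        assert accepted == sorted(accepted, reverse=True)

    def test_invalid_step_size_rejected(self, weather, truth, campaign):
        with pytest.raises(CalibrationError):
            tpai_spa_calibrate(campaign, weather, truth, spa_step=0.002)
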