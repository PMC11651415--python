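"""Seeded generators for weather, parameter truths, and field campaigns.

The weather generator emulates a winter oilseed rape season in southern
Hunan: sinusoidal seasonal temperature with AR(1) day-to-day noise,
Bernoulli-gamma precipitation, truncated-normal sunshine.  Default means
follow the published growing-season statistics for the Hengyang station
(tmin 9.87 degC, tmax 16.89 degC, precip 1.92 mm/d, vapour pressure
1.60 kPa, wind 2.33 m/s, sunshine 3.08 h/d at 112.37E 26.98N).

Parameter truths are drawn uniformly within the published single-point
min/max ranges (the partition triplet renormalised onto the simplex at every
DVS breakpoint); observation campaigns sample the engine's own trace at five
DVS-triggered stages and add multiplicative lognormal noise.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ObservationCampaign, STAGE_NAMES
from .engine import run_simulation
from .params import (CropParameterSet, PARTITION_DVS, PARTITION_NAMES,
                     PARTITION_ROWS, SINGLE_POINT_SCALARS,
                     _renormalized_partition_tables)
from .weather import Station, WeatherSeries, day_length

HENGYANG = Station("Hengyang", 112.37, 26.98)


class GenerationError(RuntimeError):
    pass


@dataclass
class WeatherGenSpec:
    """Controls for the seasonal weather generator."""

    tmin_mean: float = 9.87       # degC, window mean
    tmax_mean: float = 16.89
    seasonal_amplitude: float = 8.0  # degC, winter dip below the window mean
    temp_sd: float = 2.0          # degC, AR(1) marginal noise SD
    ar1: float = 0.7
    precip_mean: float = 1.92     # mm/d, window mean
    wet_prob: float = 0.45
    precip_shape: float = 0.7     # gamma shape of wet-day amounts
    sunshine_mean: float = 3.08   # h/d
    sunshine_sd: float = 2.0
    vap_mean: float = 1.60        # kPa
    wind_mean: float = 2.33       # m/s
    jitter_sd: float = 0.1        # relative jitter on vap and wind
    start: dt.date = dt.date(2020, 10, 10)
    end: dt.date = dt.date(2021, 5, 31)
    station: Station = field(default_factory=lambda: HENGYANG)
    seed: int = 0

    @property
    def deterministic(self) -> bool:
        return (self.temp_sd == 0 and self.sunshine_sd == 0
                and self.jitter_sd == 0)


def generate_weather(spec: WeatherGenSpec) -> WeatherSeries:
    """Seeded synthetic daily weather series.

    The seasonal temperature term is centred so the window means equal the
    spec means; precipitation is rescaled to the exact target mean (its
    sampling error over a single season would otherwise exceed the declared
    10% envelope).  Fully deterministic per (spec, seed).
    """
    ndays = (spec.end - spec.start).days + 1
    if ndays < 30:
        raise ValueError("window shorter than 30 days")
    rng = np.random.default_rng(spec.seed)
    dates = [spec.start + dt.timedelta(days=i) for i in range(ndays)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    # seasonal dip centred on mid-January (doy 15), zero-mean over the window
    seasonal = -spec.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.0)
    seasonal -= seasonal.mean()

    def ar1_noise(sd):
        if sd == 0:
            return np.zeros(ndays)
        z = rng.standard_normal(ndays)
        e = np.empty(ndays)
        e[0] = z[0] * sd
        c = math.sqrt(1.0 - spec.ar1 ** 2)
        for i in range(1, ndays):
            e[i] = spec.ar1 * e[i - 1] + sd * c * z[i]
        return e

    # noise terms are recentred over the window so the generated means hit
    # the spec means by construction (a single season is too short for the
    # AR(1) sample mean to stay reliably inside the declared envelope)
    shared = ar1_noise(spec.temp_sd)
    shared -= shared.mean()
    spread_noise = ar1_noise(spec.temp_sd * 0.5)
    spread_noise -= spread_noise.mean()
    tmin = spec.tmin_mean + seasonal + shared
    tmax = spec.tmax_mean + seasonal + shared + spread_noise
    tmax = np.maximum(tmax, tmin + 0.3)

    if spec.deterministic:
        precip = np.full(ndays, spec.precip_mean)
    else:
        wet = rng.random(ndays) < spec.wet_prob
        amounts = rng.gamma(spec.precip_shape,
                            spec.precip_mean / max(spec.wet_prob, 1e-9)
                            / spec.precip_shape, size=ndays)
        precip = np.where(wet, amounts, 0.0)
        if precip.mean() > 0:
            precip *= spec.precip_mean / precip.mean()

    nmax = np.array([day_length(d, spec.station.lat) for d in dates])
    if spec.sunshine_sd == 0:
        sunshine = np.minimum(spec.sunshine_mean, nmax)
    else:
        sunshine = np.clip(rng.normal(spec.sunshine_mean, spec.sunshine_sd,
                                      ndays), 0.0, nmax)
        sunshine = np.clip(sunshine + (spec.sunshine_mean - sunshine.mean()),
                           0.0, nmax)
    vap = np.maximum(spec.vap_mean * (1 + spec.jitter_sd
                                      * rng.standard_normal(ndays)), 0.01)
    wind = np.maximum(spec.wind_mean * (1 + spec.jitter_sd
                                        * rng.standard_normal(ndays)), 0.0)

    df = pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax,
                       "precip": precip, "vap": vap, "wind": wind,
                       "sunshine": sunshine})
    series = WeatherSeries(spec.station, df)
    _assert_window_means(series, spec)
    return series


def _assert_window_means(series: WeatherSeries, spec: WeatherGenSpec) -> None:
    df = series.frame
    checks = [("tmin", spec.tmin_mean), ("tmax", spec.tmax_mean),
              ("precip", spec.precip_mean), ("sunshine", spec.sunshine_mean)]
    for col, target in checks:
        got = float(df[col].mean())
        if target != 0 and abs(got - target) > 0.10 * abs(target):
            raise GenerationError(
                f"generated {col} mean {got:.3f} departs more than 10% "
                f"from the target {target:.3f}")


# ---------------------------------------------------------------------------
# Parameter truths
# ---------------------------------------------------------------------------

def generate_truth(seed: int | None = None, bounds_source=None,
                   base: CropParameterSet | None = None) -> CropParameterSet:
    """A crop parameter set within the published single-point ranges.

    With ``seed=None`` the published means are returned verbatim (e.g.
    SPA = 0.00065, TSUM1 = 701); with an integer seed every scalar is drawn
    uniformly within [min, max] and every partition triplet row is drawn and
    renormalised onto the simplex.
    """
    scalars = bounds_source or SINGLE_POINT_SCALARS
    ps = (base or CropParameterSet()).copy()
    if seed is None:
        for name, (mean, _, _) in scalars.items():
            setattr(ps, name, mean)
        for name, tab in _renormalized_partition_tables(
                {n: {d: PARTITION_ROWS[n][d][0] for d in PARTITION_DVS}
                 for n in PARTITION_NAMES}).items():
            setattr(ps, name, tab)
    else:
        rng = np.random.default_rng(seed)
        for name, (_, lo, hi) in scalars.items():
            setattr(ps, name, float(rng.uniform(lo, hi)))
        draws = {n: {} for n in PARTITION_NAMES}
        for d in PARTITION_DVS:
            for n in PARTITION_NAMES:
                _, lo, hi = PARTITION_ROWS[n][d]
                draws[n][d] = float(rng.uniform(lo, hi))
        for name, tab in _renormalized_partition_tables(draws).items():
            setattr(ps, name, tab)
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Observation campaigns
# ---------------------------------------------------------------------------

@dataclass
class CampaignGenSpec:
    """Controls for synthetic five-stage observation campaigns."""

    truth: CropParameterSet
    stage_triggers: tuple = (0.2, 0.6, 1.0, 1.5, 1.9)  # DVS per stage
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.stage_triggers, self.stage_triggers[1:])):
            raise ValueError("stage triggers must increase in DVS")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def generate_campaign(spec: CampaignGenSpec,
                      weather: WeatherSeries) -> ObservationCampaign:
    """Run the engine with the truth and sample a noisy 5-stage campaign.

    Observables are taken at the first day each DVS trigger is reached;
    multiplicative lognormal noise (mean 1, CV as specified) is applied per
    observable; the first three (pre-silique) stages are forced to SAI = 0
    so TPAI = LAI there.  The truth is recorded for recovery experiments.
    """
    trace = run_simulation(spec.truth, weather, mode="potential",
                           tpai_interception=True)
    frame = trace.frame
    dvs = frame["DVS"].to_numpy()
    if dvs[-1] < spec.stage_triggers[-1]:
        raise GenerationError(
            f"final DVS {dvs[-1]:.2f} below the last stage trigger "
            f"{spec.stage_triggers[-1]}: maturity not reached in the window")
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))

    def noisy(v):
        if sigma == 0 or v == 0:
            return float(v)
        return float(v * rng.lognormal(-0.5 * sigma * sigma, sigma))

    rows = []
    for k, (name, trig) in enumerate(zip(STAGE_NAMES, spec.stage_triggers)):
        i = int(np.argmax(dvs >= trig))
        r = frame.iloc[i]
        lai = noisy(r["LAI"])
        if k < 3:
            sai = 0.0
            present = False
        else:
            sai = noisy(r["PAI"])
            present = r["PAI"] > 0
        rows.append({"stage": name, "date": r["date"], "lai": lai, "sai": sai,
                     "tpai": lai + sai, "twso": noisy(r["TWSO"]),
                     "tagp": noisy(r["TAGP"]), "siliques_present": present})
    return ObservationCampaign(pd.DataFrame(rows),
                               sowing_date=spec.truth.sowing_date,
                               harvest_date=frame["date"].iloc[-1],
                               truth=spec.truth)
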