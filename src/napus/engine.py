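"""Daily-timestep crop growth engine with pod-area photosynthesis.

The engine follows the WOFOST potential-production scheme: thermal-time
phenology (DVS 0 at emergence, 1 at flowering, 2 at maturity), canopy gross
CO2 assimilation by three-point Gaussian integration over canopy depth and
over the daylight period, Q10 maintenance respiration, assimilate
partitioning via DVS-indexed AFGEN tables, leaf cohorts that senesce past
their physiological life span, and an optional single-layer water bucket.

The departure from a cereal model is the photosynthetic canopy itself: after
flowering the pod (silique) area index PAI = SPA * W_so joins the leaves, and
light interception and assimilation act on the total photosynthetic area
TPAI = LAI + PAI.  Setting ``tpai_interception=False`` (or SPA = 0) restricts
interception to leaves only, reproducing the classical LAI-driven model.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import AfgenTable, ConfigurationError, CropParameterSet, afgen_eval
from .weather import WeatherSeries, day_length, extraterrestrial_radiation

__all__ = [
    "SimulationState", "SimulationTrace", "run_simulation",
    "phenology_step", "daily_gross_assimilation", "maintenance_respiration",
    "partition_and_grow", "leaf_dynamics", "pod_area_update",
    "water_balance_step", "afgen_eval",
]

log = logging.getLogger(__name__)

CO2_TO_CH2O = 30.0 / 44.0      # kg CH2O per kg CO2 assimilated
PAR_FRACTION = 0.5             # fraction of global radiation that is PAR

# 3-point Gaussian abscissae/weights on (0, 1)
_GAUSS_X = (0.1127016653792583, 0.5, 0.8872983346207417)
_GAUSS_W = (0.2777777777777778, 0.4444444444444444, 0.2777777777777778)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationState:
    """Mutable daily state of the crop and soil."""

    day: dt.date
    DVS: float = 0.0
    tsum_em: float = 0.0     # degC.d accumulated from sowing toward emergence
    tsum: float = 0.0        # degC.d accumulated since emergence (pre-flowering)
    tsum2: float = 0.0       # degC.d accumulated since flowering
    emerged: bool = False
    W_leaf: float = 0.0      # kg ha-1 living leaves
    W_leaf_dead: float = 0.0
    W_stem: float = 0.0
    W_so: float = 0.0        # storage organs (pods + seeds)
    W_root: float = 0.0
    leaf_cohorts: list = field(default_factory=list)  # [mass, area, phys. age]
    LAI: float = 0.0
    PAI: float = 0.0
    TPAI: float = 0.0
    soil_water: float = 0.0  # cm
    stress: float = 1.0
    w_so_at_flowering: float | None = None  # storage mass when DVS crosses 1

    @property
    def TWSO(self) -> float:
        return self.W_so

    @property
    def TAGP(self) -> float:
        return self.W_leaf + self.W_leaf_dead + self.W_stem + self.W_so


@dataclass
class SimulationTrace:
    """Daily trace of a simulation run as a tidy DataFrame."""

    frame: pd.DataFrame
    params: CropParameterSet

    def __len__(self):
        return len(self.frame)

    @property
    def dates(self):
        return list(self.frame["date"])

    def at_date(self, date: dt.date) -> pd.Series:
        m = self.frame["date"] == date
        if not m.any():
            raise KeyError(f"{date} not in trace")
        return self.frame[m].iloc[0]

    def series(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Process steps
# ---------------------------------------------------------------------------

def phenology_step(state: SimulationState, params: CropParameterSet,
                   tmean: float) -> float:
    """Advance DVS by one day of effective temperature; returns new DVS.

    Before flowering DVS = tsum/TSUM1; after, 1 + tsum2/TSUM2; capped at 2.
    """
    if params.TSUM1 <= 0 or params.TSUM2 <= 0:
        raise ConfigurationError("TSUM1 and TSUM2 must be positive")
    teff = max(0.0, tmean - params.TBASE)
    if state.DVS < 1.0:
        state.tsum += teff
        if state.tsum < params.TSUM1:
            state.DVS = state.tsum / params.TSUM1
        else:
            # carry the excess over into the post-flowering phase
            state.tsum2 += state.tsum - params.TSUM1
            state.tsum = params.TSUM1
            state.DVS = min(2.0, 1.0 + state.tsum2 / params.TSUM2)
    else:
        state.tsum2 += teff
        state.DVS = min(2.0, 1.0 + state.tsum2 / params.TSUM2)
    return state.DVS


def daily_gross_assimilation(tpai: float, dvs: float, params: CropParameterSet,
                             radiation: float, tday: float, daylength: float,
                             sinld: float, cosld: float, dsinbe: float) -> float:
    """Daily canopy gross assimilation in kg CO2 ha-1 d-1.

    Three-point Gaussian integration over the daylight period and over
    canopy depth; light is attenuated with the extinction coefficient over
    the *total* photosynthetic area (leaves + pods); the leaf response is
    the negative-exponential light-response curve with asymptote
    AMAX * TMPFTB(Tday) and initial slope EFF(Tday).
    """
    if radiation < 0:
        raise ValueError("negative radiation")
    if tpai <= 0 or radiation == 0 or daylength <= 0:
        return 0.0
    amax = afgen_eval(params.AMAXTB, dvs) * afgen_eval(params.TMPFTB, tday)
    eff = afgen_eval(params.EFFTB, tday)
    kdif = afgen_eval(params.KDIFTB, dvs)
    if amax <= 0 or kdif <= 0:
        return 0.0
    refl = params.canopy_reflection
    rad_j = radiation * 1000.0  # J m-2 d-1
    dtga = 0.0
    for xt, wt in zip(_GAUSS_X, _GAUSS_W):
        hour = 12.0 + 0.5 * daylength * xt
        sinb = max(0.0, sinld + cosld * math.cos(2.0 * math.pi * (hour + 12.0) / 24.0))
        if sinb <= 0:
            continue
        # instantaneous PAR at the canopy top, J m-2 s-1
        par_top = PAR_FRACTION * rad_j * sinb * (1.0 + 0.4 * sinb) / dsinbe
        fgros = 0.0
        for xd, wd in zip(_GAUSS_X, _GAUSS_W):
            depth = tpai * xd
            absorbed = par_top * (1.0 - refl) * kdif * math.exp(-kdif * depth)
            fgros += wd * amax * (1.0 - math.exp(-eff * absorbed / amax))
        dtga += wt * fgros * tpai * daylength
    return dtga


def maintenance_respiration(state: SimulationState, params: CropParameterSet,
                            tmean: float) -> float:
    """Maintenance cost in kg CH2O ha-1 d-1 (Q10 temperature response)."""
    rm = (params.RML * state.W_leaf + params.RMS * state.W_stem
          + params.RMO * state.W_so + params.RMR * state.W_root)
    return rm * params.Q10 ** ((tmean - 25.0) / 10.0)


def partition_and_grow(state: SimulationState, params: CropParameterSet,
                       net_assimilate: float) -> dict:
    """Allocate net assimilate (kg CH2O ha-1) and grow organ masses.

    Root share FRTB(DVS) first; the shoot remainder is split by the
    FLTB/FSTB/FOTB triplet.  Organ growth is CVx times the allocated CH2O.
    Returns the daily increments for the carbon ledger.
    """
    if net_assimilate < 0:
        raise ValueError("net assimilate must be non-negative")
    d = state.DVS
    fr = afgen_eval(params.FRTB, d)
    fl = afgen_eval(params.FLTB, d)
    fs = afgen_eval(params.FSTB, d)
    fo = afgen_eval(params.FOTB, d)
    if abs(fl + fs + fo - 1.0) > 1e-6:
        raise ConfigurationError(
            f"partition sum {fl + fs + fo} != 1 at DVS {d:.3f}")
    shoot = (1.0 - fr) * net_assimilate
    d_rt = params.CVR * fr * net_assimilate
    d_lv = params.CVL * fl * shoot
    d_st = params.CVS * fs * shoot
    d_so = params.CVO * fo * shoot
    state.W_root += d_rt
    state.W_stem += d_st
    state.W_so += d_so
    # leaf mass is added through the cohort bookkeeping in leaf_dynamics
    return {"d_leaf": d_lv, "d_stem": d_st, "d_so": d_so, "d_root": d_rt}


def leaf_dynamics(state: SimulationState, params: CropParameterSet,
                  tmean: float, d_leaf: float) -> float:
    """Grow and senesce leaf cohorts; returns the new LAI.

    In the juvenile phase (DVS < 0.3) area expands exponentially at rate
    RGRLAI per effective degree-day, capped by the source supply
    d_leaf * SLATB(DVS); afterwards growth is purely source-driven.  Each
    cohort ages by (Tmean - TBASE)/(35 - TBASE) physiological days and dies
    past SPAN, its mass moving to the dead pool.
    """
    if params.SPAN <= 0:
        raise ConfigurationError("SPAN must be positive")
    if d_leaf < 0:
        raise ValueError("leaf growth must be non-negative")
    teff = max(0.0, tmean - params.TBASE)
    frai = teff / (params.senescence_t_ref - params.TBASE)
    survivors = []
    lai_now = 0.0
    for cohort in state.leaf_cohorts:
        cohort[2] += frai
        if cohort[2] > params.SPAN:
            state.W_leaf_dead += cohort[0]
            state.W_leaf -= cohort[0]
        else:
            survivors.append(cohort)
            lai_now += cohort[1]
    state.leaf_cohorts = survivors
    if d_leaf > 0:
        sla = afgen_eval(params.SLATB, state.DVS)
        gla_source = d_leaf * sla
        if state.DVS < 0.3 and lai_now > 0:
            gla_exp = lai_now * (math.exp(params.RGRLAI * teff) - 1.0)
            gla = min(gla_exp, gla_source)
        else:
            gla = gla_source
        state.leaf_cohorts.append([d_leaf, gla, 0.0])
        state.W_leaf += d_leaf
        lai_now += gla
    state.LAI = lai_now
    return state.LAI


def pod_area_update(state: SimulationState, params: CropParameterSet) -> float:
    """Pod area index PAI = SPA * pod mass, present only from flowering.

    Storage-organ mass accumulated before flowering represents buds and
    flowers, not pods; only the storage growth after DVS crosses 1 carries
    photosynthetic pod area.  With no pre-flowering storage allocation this
    reduces to the plain product SPA * W_so.
    """
    if params.SPA < 0:
        raise ConfigurationError("SPA must be non-negative")
    if state.W_so < 0:
        raise ValueError("storage-organ mass must be non-negative")
    if state.DVS >= 1.0:
        base = state.w_so_at_flowering or 0.0
        state.PAI = params.SPA * max(0.0, state.W_so - base)
    else:
        state.PAI = 0.0
    state.TPAI = state.LAI + state.PAI
    return state.PAI


def _hargreaves_et0(tmean: float, tmin: float, tmax: float, ra_kj: float) -> float:
    """Reference evapotranspiration in mm d-1 (Hargreaves-Samani)."""
    ra_mm = ra_kj / 1000.0 * 0.408  # MJ m-2 d-1 -> mm d-1 equivalent
    return max(0.0, 0.0023 * (tmean + 17.8) * math.sqrt(max(0.0, tmax - tmin)) * ra_mm)


def water_balance_step(state: SimulationState, params: CropParameterSet,
                       tmean: float, tmin: float, tmax: float, precip: float,
                       ra_kj: float, kdif: float,
                       potential: bool = True) -> tuple[float, float, dict]:
    """One day of the single-layer water bucket.

    Gains precipitation, loses crop transpiration plus soil evaporation
    (reference ET split by canopy cover).  Returns (new storage, stress
    factor for the NEXT day's assimilation, ledger terms).  In potential
    mode the stress factor is identically 1 but the bucket still runs.
    """
    rain_cm = precip / 10.0
    et0_cm = _hargreaves_et0(tmean, tmin, tmax, ra_kj) / 10.0
    cover = 1.0 - math.exp(-kdif * state.TPAI)
    transp_dem = et0_cm * cover
    evap_dem = 0.5 * et0_cm * (1.0 - cover)
    if potential:
        stress = 1.0
    else:
        crit = params.critical_fraction * params.soil_capacity
        stress = min(1.0, max(0.0, state.soil_water / crit)) if crit > 0 else 1.0
    demand = transp_dem * stress + evap_dem
    available = state.soil_water + rain_cm
    loss = min(demand, available)
    new_sw = available - loss
    overflow = max(0.0, new_sw - params.soil_capacity)
    new_sw -= overflow
    ledger = {"rain": rain_cm, "loss": loss, "overflow": overflow,
              "dstorage": new_sw - state.soil_water}
    state.soil_water = new_sw
    state.stress = stress
    return new_sw, stress, ledger


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _prepare_weather(weather: WeatherSeries, start: dt.date, end: dt.date):
    """Per-day meteorological and astronomical drivers as plain tuples.

    Cached on the series instance: calibration and sensitivity loops run the
    engine thousands of times over the same weather.
    """
    cache = weather.__dict__.setdefault("_prepared_days", {})
    key = (start, end)
    if key in cache:
        return cache[key]
    sub = weather.window(start, end).ensure_radiation()
    lat = weather.station.lat
    phi = math.radians(lat)
    rows = []
    for r in sub.frame.itertuples(index=False):
        doy = r.date.timetuple().tm_yday
        delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
        sinld = math.sin(phi) * math.sin(delta)
        cosld = math.cos(phi) * math.cos(delta)
        dl = day_length(r.date, lat)
        # integral of sinb*(1+0.4 sinb) over the day, seconds
        aob = sinld / cosld if cosld != 0 else 0.0
        aob = min(1.0, max(-1.0, aob))
        dsinb = 3600.0 * (dl * sinld + 24.0 / math.pi * cosld
                          * math.sqrt(max(0.0, 1.0 - aob * aob)))
        dsinbe = 3600.0 * (dl * (sinld + 0.4 * (sinld * sinld + 0.5 * cosld * cosld))
                           + 12.0 * cosld * (2.0 + 3.0 * 0.4 * sinld)
                           * math.sqrt(max(0.0, 1.0 - aob * aob)) / math.pi)
        tmean = 0.5 * (r.tmin + r.tmax)
        tday = 0.5 * (r.tmax + tmean)
        ra = extraterrestrial_radiation(r.date, lat)
        rows.append((r.date, r.tmin, r.tmax, tmean, tday, float(r.radiation),
                     r.precip, dl, sinld, cosld, max(dsinbe, 1.0), ra, dsinb))
    cache[key] = rows
    return rows


def run_simulation(params: CropParameterSet, weather: WeatherSeries,
                   window: tuple[dt.date, dt.date] | None = None,
                   mode: str = "potential",
                   tpai_interception: bool = True,
                   stop_at_maturity: bool = True) -> SimulationTrace:
    """Run the engine day by day and return the daily trace.

    ``window`` defaults to (sowing_date, end of weather).  ``mode`` is
    ``"potential"`` (no water stress) or ``"water-limited"``.
    ``tpai_interception=False`` restricts light interception to the leaf
    canopy (the classical LAI-driven model); pods then intercept nothing,
    although PAI is still reported.
    """
    params.validate()
    if mode not in ("potential", "water-limited"):
        raise ValueError(f"unknown mode {mode!r}")
    potential = mode == "potential"
    start = params.sowing_date if window is None else window[0]
    end = weather.end if window is None else window[1]
    days = _prepare_weather(weather, start, end)

    state = SimulationState(day=start, soil_water=params.WAV)
    records = []
    for (date, tmin, tmax, tmean, tday, rad, precip, dl, sinld, cosld,
         dsinbe, ra, _dsinb) in days:
        state.day = date
        gross_ch2o = maint = 0.0
        deltas = {"d_leaf": 0.0, "d_stem": 0.0, "d_so": 0.0, "d_root": 0.0}
        if not state.emerged:
            # pre-emergence: accumulate thermal time from sowing
            state.tsum_em += max(0.0, tmean - params.TBASEM)
            reached = (state.tsum_em >= params.TSUMEM
                       if params.emergence_mode == "tsum"
                       else (params.emergence_date is not None
                             and date >= params.emergence_date))
            if reached:
                state.emerged = True
                _initialize_crop(state, params)
        else:
            phenology_step(state, params, tmean)
            if state.DVS >= 1.0 and state.w_so_at_flowering is None:
                state.w_so_at_flowering = state.W_so
            area = state.TPAI if tpai_interception else state.LAI
            gross_co2 = daily_gross_assimilation(
                area, state.DVS, params, rad, tday, dl, sinld, cosld, dsinbe)
            gross_ch2o = gross_co2 * CO2_TO_CH2O * state.stress
            maint = min(maintenance_respiration(state, params, tmean), gross_ch2o)
            net = gross_ch2o - maint
            deltas = partition_and_grow(state, params, net)
            leaf_dynamics(state, params, tmean, deltas["d_leaf"])
            pod_area_update(state, params)
        kdif = afgen_eval(params.KDIFTB, state.DVS)
        _, _, wledger = water_balance_step(
            state, params, tmean, tmin, tmax, precip, ra, kdif, potential)
        records.append({
            "date": date, "DVS": state.DVS, "LAI": state.LAI, "PAI": state.PAI,
            "TPAI": state.TPAI, "W_leaf": state.W_leaf,
            "W_leaf_dead": state.W_leaf_dead, "W_stem": state.W_stem,
            "TWSO": state.TWSO, "W_root": state.W_root, "TAGP": state.TAGP,
            "soil_water": state.soil_water, "stress": state.stress,
            "gross_ch2o": gross_ch2o, "maintenance": maint,
            "d_leaf": deltas["d_leaf"], "d_stem": deltas["d_stem"],
            "d_so": deltas["d_so"], "d_root": deltas["d_root"],
            "rain_cm": wledger["rain"], "water_loss_cm": wledger["loss"],
            "overflow_cm": wledger["overflow"],
            "dstorage_cm": wledger["dstorage"],
        })
        if stop_at_maturity and state.DVS >= 2.0:
            break
    if not records:
        raise SimulationError("empty simulation window")
    return SimulationTrace(pd.DataFrame.from_records(records), params)


def _initialize_crop(state: SimulationState, params: CropParameterSet) -> None:
    """Distribute the initial dry matter TDWI over organs at emergence."""
    fr = afgen_eval(params.FRTB, 0.0)
    fl = afgen_eval(params.FLTB, 0.0)
    fs = afgen_eval(params.FSTB, 0.0)
    fo = afgen_eval(params.FOTB, 0.0)
    state.W_root = fr * params.TDWI
    shoot = (1.0 - fr) * params.TDWI
    w_leaf = fl * shoot
    state.W_stem = fs * shoot
    state.W_so = fo * shoot
    state.W_leaf = w_leaf
    state.LAI = params.LAIEM
    state.leaf_cohorts = [[w_leaf, params.LAIEM, 0.0]]
    state.PAI = 0.0
    state.TPAI = state.LAI
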