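"""Parameter calibration: the baseline LAI method and the two TPAI methods.

The baseline calibrates the engine against staged LAI observations with
light interception restricted to leaves — the classical cereal-style
procedure, which systematically under-predicts rape yield because pod
photosynthesis after flowering contributes nothing.

TPAI-SPA calibrates against staged TPAI observations: phenology from the
stage dates, then a line search on the specific pod area SPA (preset 0.007,
step 0.0005-0.001, direction set by the sign of the TPAI misfit at
pod-bearing stages), then a bounded least-squares refinement of the
sensitive parameter set.

TPAI-Curve builds a daily TPAI calibration curve — a quadratic through the
simulated-LAI peak, the highest TPAI observation after it, and the last
observation before harvest — and fits the sensitive parameters so the
simulated TPAI tracks that curve day by day.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import SimulationTrace, run_simulation
from .params import CropParameterSet, SINGLE_POINT_SCALARS, bounds_for
from .weather import WeatherSeries

log = logging.getLogger(__name__)

STAGE_NAMES = ["Seedling", "Budding", "Flowering", "Milky", "Maturity"]

#: parameters reported as most influential for LAIMAX/TWSO/TAGP, used as the
#: default refinement set
SENSITIVE_PARAMETERS = ["KDIFTB2.00", "EFFTB0.00", "SPA", "FSTB1.70",
                        "CVO", "EFFTB40.00", "SLATB0.00"]

SPA_PRESET = 0.007          # line-search start
SPA_STEP_RANGE = (0.0005, 0.001)
SPA_HARD_BOUNDS = (0.0, 0.01)  # wide screening bounds for the line search


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Observation campaign
# ---------------------------------------------------------------------------

@dataclass
class ObservationCampaign:
    """Stage-dated field observations for one point.

    ``stages`` has columns stage, date, lai, sai, tpai, twso, tagp,
    siliques_present.  TPAI must equal LAI + SAI per record, and the first
    three stages (pre-silique) must have SAI = 0.
    """

    stages: pd.DataFrame
    sowing_date: dt.date
    harvest_date: dt.date
    truth: CropParameterSet | None = None

    def __post_init__(self):
        df = self.stages.reset_index(drop=True).copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        if not df["date"].is_monotonic_increasing:
            raise CalibrationError("stage dates must increase")
        bad = np.abs(df["tpai"] - (df["lai"] + df["sai"])) > 1e-6
        if bad.any():
            raise CalibrationError("TPAI != LAI + SAI in observation rows "
                                   f"{list(df.index[bad])}")
        pre = df.iloc[:3]
        if (np.abs(pre["sai"]) > 1e-9).any():
            raise CalibrationError("first three stages must have SAI = 0")
        if "siliques_present" not in df.columns:
            df["siliques_present"] = df["sai"] > 0
        self.stages = df

    @property
    def dates(self) -> list[dt.date]:
        return list(self.stages["date"])

    def stage_row(self, name: str) -> pd.Series:
        m = self.stages["stage"] == name
        if not m.any():
            raise CalibrationError(f"campaign has no stage named {name!r}")
        return self.stages[m].iloc[0]

    def to_csv(self, path) -> None:
        df = self.stages.copy()
        df.insert(0, "sowing_date", self.sowing_date)
        df.insert(1, "harvest_date", self.harvest_date)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationCampaign":
        df = pd.read_csv(path)
        sow = dt.date.fromisoformat(str(df["sowing_date"].iloc[0]))
        harv = dt.date.fromisoformat(str(df["harvest_date"].iloc[0]))
        return cls(df.drop(columns=["sowing_date", "harvest_date"]), sow, harv)


@dataclass
class CalibrationCurve:
    """Daily TPAI calibration curve over [t1, t3]."""

    dates: list[dt.date]
    values: np.ndarray
    provenance: str = "quadratic"   # "quadratic" or "trace"
    anchors: list[tuple[dt.date, float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.dates) != len(self.values):
            raise CalibrationError("curve dates/values length mismatch")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise CalibrationError("curve dates must strictly increase")
        self.values = np.maximum(np.asarray(self.values, dtype=float), 0.0)


@dataclass
class CalibrationResult:
    params: CropParameterSet
    objective: float
    residuals: pd.DataFrame
    method: str
    iteration_log: list = field(default_factory=list)
    success: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _trace_values_at(trace: SimulationTrace, date: dt.date) -> pd.Series:
    """Trace row at a date, clamped to the final row once the run has ended."""
    frame = trace.frame
    if date >= frame["date"].iloc[-1]:
        return frame.iloc[-1]
    m = frame["date"] == date
    if not m.any():
        raise CalibrationError(f"{date} precedes the simulation window")
    return frame[m].iloc[0]


def _stage_residual_table(trace: SimulationTrace,
                          campaign: ObservationCampaign) -> pd.DataFrame:
    rows = []
    for r in campaign.stages.itertuples(index=False):
        sim = _trace_values_at(trace, r.date)
        rows.append({
            "stage": r.stage, "date": r.date,
            "lai_resid": sim["LAI"] - r.lai,
            "tpai_resid": sim["TPAI"] - r.tpai,
            "twso_resid": sim["TWSO"] - r.twso,
            "tagp_resid": sim["TAGP"] - r.tagp,
        })
    return pd.DataFrame(rows)


def _effective_sum(weather: WeatherSeries, start: dt.date, end: dt.date,
                   base: float) -> float:
    """Sum of max(0, Tmean - base) over days in (start, end]."""
    df = weather.frame
    m = (df["date"] > start) & (df["date"] <= end)
    tmean = 0.5 * (df.loc[m, "tmin"] + df.loc[m, "tmax"])
    return float(np.maximum(0.0, tmean - base).sum())


def emergence_date(params: CropParameterSet, weather: WeatherSeries) -> dt.date:
    """First day on which thermal time from sowing reaches TSUMEM."""
    df = weather.frame
    m = df["date"] >= params.sowing_date
    acc = 0.0
    for row in df[m].itertuples(index=False):
        acc += max(0.0, 0.5 * (row.tmin + row.tmax) - params.TBASEM)
        if acc >= params.TSUMEM:
            return row.date
    raise CalibrationError("emergence thermal time never reached in weather")


def _clamp_with_warning(name: str, value: float) -> float:
    if name in SINGLE_POINT_SCALARS:
        _, lo, hi = SINGLE_POINT_SCALARS[name]
        if not lo <= value <= hi:
            clamped = min(max(value, lo), hi)
            log.warning("%s=%.4g outside [%g, %g]; clamped to %.4g",
                        name, value, lo, hi, clamped)
            return clamped
    return value


# ---------------------------------------------------------------------------
# Phenology calibration
# ---------------------------------------------------------------------------

def calibrate_phenology(campaign: ObservationCampaign, weather: WeatherSeries,
                        params: CropParameterSet) -> tuple[float, float]:
    """TSUM1/TSUM2 from the flowering and maturity/harvest dates.

    TSUM1 is the effective temperature accumulated emergence -> flowering,
    TSUM2 flowering -> harvest (falling back to the maturity stage date when
    no harvest date is recorded); both clamped to their published bounds
    with a logged warning.
    """
    flowering = campaign.stage_row("Flowering")["date"]
    end = campaign.harvest_date or campaign.stage_row("Maturity")["date"]
    emerg = emergence_date(params, weather)
    if flowering <= emerg:
        raise CalibrationError("flowering date does not follow emergence")
    if end <= flowering:
        raise CalibrationError("maturity/harvest does not follow flowering")
    # a stage date marks the first day its DVS threshold was reached, so the
    # true thermal total lies between the accumulations up to the previous
    # day and up to the stage day; the midpoint halves the quantization error
    one = dt.timedelta(days=1)
    tsum1 = 0.5 * (_effective_sum(weather, emerg, flowering, params.TBASE)
                   + _effective_sum(weather, emerg, flowering - one, params.TBASE))
    tsum2 = 0.5 * (_effective_sum(weather, flowering, end, params.TBASE)
                   + _effective_sum(weather, flowering, end - one, params.TBASE))
    if tsum1 <= 0 or tsum2 <= 0:
        raise CalibrationError("zero effective temperature over a phase")
    return (_clamp_with_warning("TSUM1", tsum1),
            _clamp_with_warning("TSUM2", tsum2))


# ---------------------------------------------------------------------------
# Bounded least-squares core
# ---------------------------------------------------------------------------

def _usable_free_set(free_set) -> list[tuple[str, float, float]]:
    out = []
    for tag in free_set:
        lo, hi = bounds_for(tag)
        if hi > lo:
            out.append((tag, lo, hi))
        else:
            log.info("dropping %s from the free set: degenerate bounds "
                     "[%g, %g]", tag, lo, hi)
    if not out:
        raise CalibrationError("free set is empty after dropping degenerate "
                               "parameters")
    return out


def _yield_residuals(trace: SimulationTrace, campaign: ObservationCampaign,
                     weight: float = 1.0) -> np.ndarray:
    """Dimensionless staged TWSO/TAGP residuals.

    Conversion-efficiency and allocation parameters are not identifiable
    from canopy area alone (many combinations produce the same TPAI curve),
    so the staged yield observations anchor them — the dry-matter conversion
    and allocation coefficients are adjusted on the basis of the yield at
    each time point.  Residuals are normalised by the observed means so they
    share the area indices' scale.
    """
    obs = campaign.stages
    twso_obs = obs["twso"].to_numpy(dtype=float)
    tagp_obs = obs["tagp"].to_numpy(dtype=float)
    sim = [_trace_values_at(trace, d) for d in obs["date"]]
    r = []
    for col, o in (("TWSO", twso_obs), ("TAGP", tagp_obs)):
        m = float(np.abs(o).mean())
        if m > 0:
            s = np.array([row[col] for row in sim])
            r.append((s - o) / m)
    return weight * np.concatenate(r) if r else np.empty(0)


def _refine(residual_fn, params0: CropParameterSet, free_set,
            max_nfev: int = 60, primary_fn=None):
    """Bounded trust-region least squares over the free parameter tags.

    Parameters are mapped to the unit cube for conditioning.  The reported
    objective is the RMSE of ``primary_fn`` (defaults to the fitting
    residuals) at the solution.  Returns (fitted params, objective RMSE,
    iteration log, success flag, message).
    """
    free = _usable_free_set(free_set)
    tags = [t for t, _, _ in free]
    lo = np.array([l for _, l, _ in free])
    hi = np.array([h for _, _, h in free])

    def to_unit(x):
        return (x - lo) / (hi - lo)

    def from_unit(u):
        return lo + np.clip(u, 0.0, 1.0) * (hi - lo)

    x0 = np.array([min(max(params0.get(t), l), h) for (t, l, h) in free])
    iteration_log: list[dict] = []

    def wrapped(u):
        p = params0.copy()
        for t, v in zip(tags, from_unit(u)):
            p.set(t, float(v))
        r = np.asarray(residual_fn(p), dtype=float)
        iteration_log.append({
            "eval": len(iteration_log) + 1,
            "rmse": math.sqrt(float((r * r).mean())) if r.size else 0.0,
            **dict(zip(tags, from_unit(u))),
        })
        return r

    res = least_squares(wrapped, to_unit(x0), bounds=(0.0, 1.0), method="trf",
                        diff_step=0.02, max_nfev=max_nfev)
    fitted = params0.copy()
    for t, v in zip(tags, from_unit(res.x)):
        fitted.set(t, float(v))
    r = np.asarray((primary_fn or residual_fn)(fitted), dtype=float)
    objective = math.sqrt(float((r * r).mean()))
    success = bool(res.status > 0)
    msg = res.message if success else f"optimizer did not converge: {res.message}"
    return fitted, objective, iteration_log, success, msg


# ---------------------------------------------------------------------------
# Baseline LAI calibration
# ---------------------------------------------------------------------------

def calibrate_baseline_lai(campaign: ObservationCampaign,
                           weather: WeatherSeries,
                           params0: CropParameterSet,
                           free_set=None, max_nfev: int = 60,
                           phenology_from_stages: bool = True,
                           mode: str = "potential") -> CalibrationResult:
    """Classical LAI-only calibration with leaf-only light interception.

    ``phenology_from_stages=False`` keeps the TSUM1/TSUM2 already in
    ``params0`` (e.g. known from previous seasons) instead of deriving them
    from the campaign's stage dates.
    """
    if free_set is None:
        free_set = [t for t in SENSITIVE_PARAMETERS if t != "SPA"]
    p0 = params0.copy()
    if phenology_from_stages:
        p0.TSUM1, p0.TSUM2 = calibrate_phenology(campaign, weather, p0)
    obs_dates = campaign.dates
    lai_obs = campaign.stages["lai"].to_numpy(dtype=float)

    def residuals(p):
        trace = run_simulation(p, weather, mode=mode, tpai_interception=False)
        return np.array([_trace_values_at(trace, d)["LAI"] for d in obs_dates]) - lai_obs

    fitted, obj, ilog, ok, msg = _refine(residuals, p0, free_set, max_nfev)
    trace = run_simulation(fitted, weather, mode=mode, tpai_interception=False)
    return CalibrationResult(fitted, obj, _stage_residual_table(trace, campaign),
                             "LAI", ilog, ok, msg)


# ---------------------------------------------------------------------------
# TPAI-SPA calibration
# ---------------------------------------------------------------------------

def _spa_line_search(campaign: ObservationCampaign, weather: WeatherSeries,
                     params: CropParameterSet, preset: float, step: float,
                     mode: str) -> tuple[float, list[dict]]:
    pod = campaign.stages[campaign.stages["siliques_present"]]
    if pod.empty:
        raise CalibrationError("campaign has no pod-bearing TPAI observations")
    pod_dates = list(pod["date"])
    pod_obs = pod["tpai"].to_numpy(dtype=float)

    def misfit(spa):
        p = params.copy()
        p.SPA = spa
        trace = run_simulation(p, weather, mode=mode, tpai_interception=True)
        sim = np.array([_trace_values_at(trace, d)["TPAI"] for d in pod_dates])
        return float(np.sqrt(((sim - pod_obs) ** 2).mean())), float((sim - pod_obs).mean())

    lo, hi = SPA_HARD_BOUNDS
    spa = min(max(preset, lo + step), hi)
    if spa != preset:
        log.warning("preset SPA %.4g clamped to %.4g", preset, spa)
    obj, bias = misfit(spa)
    direction = -1.0 if bias > 0 else 1.0
    trail = [{"SPA": spa, "rmse": obj, "bias": bias}]
    while True:
        nxt = spa + direction * step
        if not lo < nxt <= hi:
            break
        nobj, nbias = misfit(nxt)
        trail.append({"SPA": nxt, "rmse": nobj, "bias": nbias})
        if nobj < obj:
            spa, obj = nxt, nobj
        else:
            break
    return spa, trail


def tpai_spa_calibrate(campaign: ObservationCampaign, weather: WeatherSeries,
                       params0: CropParameterSet, free_set=None,
                       spa_preset: float = SPA_PRESET,
                       spa_step: float = SPA_STEP_RANGE[0],
                       max_nfev: int = 60,
                       refine_phenology: bool = False,
                       phenology_from_stages: bool = True,
                       mode: str = "potential") -> CalibrationResult:
    """TPAI calibration through the specific pod area.

    Phenology from stage dates, SPA line search from the preset, then
    bounded least squares of the sensitive set against all staged TPAI
    observations.  ``refine_phenology`` lets the refinement also polish
    TSUM1/TSUM2 from their stage-date starting values (off by default: the
    day-quantized stage crossings give the optimizer poor thermal-time
    gradients).  The step size must lie in [0.0005, 0.001].
    """
    if not SPA_STEP_RANGE[0] <= spa_step <= SPA_STEP_RANGE[1]:
        raise CalibrationError(
            f"SPA step {spa_step} outside {list(SPA_STEP_RANGE)}")
    if free_set is None:
        free_set = list(SENSITIVE_PARAMETERS)
    p0 = params0.copy()
    if phenology_from_stages:
        p0.TSUM1, p0.TSUM2 = calibrate_phenology(campaign, weather, p0)
    if refine_phenology:
        free_set = list(free_set) + ["TSUM1", "TSUM2"]
    spa, trail = _spa_line_search(campaign, weather, p0, spa_preset, spa_step,
                                  mode)
    slo, shi = bounds_for("SPA")
    p0.SPA = min(max(spa, slo), shi)

    obs_dates = campaign.dates
    tpai_obs = campaign.stages["tpai"].to_numpy(dtype=float)

    def tpai_residuals(p):
        trace = run_simulation(p, weather, mode=mode, tpai_interception=True)
        return np.array([_trace_values_at(trace, d)["TPAI"]
                         for d in obs_dates]) - tpai_obs

    def residuals(p):
        trace = run_simulation(p, weather, mode=mode, tpai_interception=True)
        r = np.array([_trace_values_at(trace, d)["TPAI"]
                      for d in obs_dates]) - tpai_obs
        return np.concatenate([r, _yield_residuals(trace, campaign)])

    fitted, obj, ilog, ok, msg = _refine(residuals, p0, free_set, max_nfev,
                                         primary_fn=tpai_residuals)
    trace = run_simulation(fitted, weather, mode=mode, tpai_interception=True)
    result = CalibrationResult(fitted, obj,
                               _stage_residual_table(trace, campaign),
                               "TPAI-SPA", [{"line_search": trail}] + ilog,
                               ok, msg)
    return result


# ---------------------------------------------------------------------------
# TPAI-Curve calibration
# ---------------------------------------------------------------------------

def exact_quadratic(x, y) -> np.ndarray:
    """Coefficients (highest first) of the quadratic through three points.

    The three abscissae must be distinct; the interpolation is exact
    (Vandermonde solve), so collinear points give a zero leading
    coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != 3 or np.unique(x).size != 3:
        raise CalibrationError("need three points with distinct abscissae")
    return np.linalg.solve(np.vander(x, 3), y)


def fit_tpai_quadratic(lai_trace: SimulationTrace,
                       campaign: ObservationCampaign) -> CalibrationCurve:
    """Quadratic TPAI calibration curve through three anchor points.

    x1 sits at the simulated-LAI peak (earliest day on ties), valued at the
    simulated TPAI of that day — identical to the LAI peak value whenever
    siliques are still absent there, but robust when leaf growth persists
    past flowering and pods already carry area at the LAI peak.  x2 = the
    highest observed TPAI after t1 (and before t3); x3 = the last
    observation before harvest.  The unique quadratic through the three
    anchors is sampled daily over [t1, t3] and clamped at 0.
    """
    frame = lai_trace.frame
    lai = frame["LAI"].to_numpy()
    i1 = int(np.argmax(lai))             # argmax returns the earliest tie
    t1, v1 = frame["date"].iloc[i1], float(frame["TPAI"].iloc[i1])

    obs = campaign.stages
    t3 = obs["date"].iloc[-1]
    v3 = float(obs["tpai"].iloc[-1])
    between = obs[(obs["date"] > t1) & (obs["date"] < t3)]
    if between.empty:
        raise CalibrationError("no TPAI observation between the simulated LAI "
                               "peak and the final stage")
    j = int(between["tpai"].to_numpy().argmax())
    t2, v2 = between["date"].iloc[j], float(between["tpai"].iloc[j])
    if len({t1, t2, t3}) < 3:
        raise CalibrationError(f"degenerate anchors: {t1}, {t2}, {t3}")

    x = np.array([0.0, (t2 - t1).days, (t3 - t1).days], dtype=float)
    y = np.array([v1, v2, v3])
    coeff = exact_quadratic(x, y)
    days = np.arange(0.0, (t3 - t1).days + 1.0)
    vals = np.polyval(coeff, days)
    dates = [t1 + dt.timedelta(days=int(d)) for d in days]
    return CalibrationCurve(dates, vals, "quadratic",
                            anchors=[(t1, v1), (t2, v2), (t3, v3)])


def curve_from_trace(trace: SimulationTrace, start: dt.date,
                     end: dt.date) -> CalibrationCurve:
    """Raw-provenance calibration curve: the trace's own daily TPAI."""
    frame = trace.frame
    m = (frame["date"] >= start) & (frame["date"] <= end)
    sub = frame[m]
    return CalibrationCurve(list(sub["date"]), sub["TPAI"].to_numpy(), "trace")


def tpai_curve_calibrate(campaign: ObservationCampaign, weather: WeatherSeries,
                         params0: CropParameterSet, free_set=None,
                         curve: CalibrationCurve | None = None,
                         max_nfev: int = 60,
                         refine_phenology: bool = False,
                         phenology_from_stages: bool = True,
                         mode: str = "potential") -> CalibrationResult:
    """TPAI calibration against a daily calibration curve.

    When no curve is supplied, a step-a LAI calibration provides the
    simulated LAI peak and the observed-anchored quadratic curve is built
    from it.  The objective is the daily RMSE between simulated TPAI and the
    curve over [t1, t3], plus the LAI residuals at stages before t1.
    """
    if free_set is None:
        free_set = list(SENSITIVE_PARAMETERS)
    p0 = params0.copy()
    if phenology_from_stages:
        p0.TSUM1, p0.TSUM2 = calibrate_phenology(campaign, weather, p0)
    if refine_phenology:
        free_set = list(free_set) + ["TSUM1", "TSUM2"]
    if curve is None:
        step_a = calibrate_baseline_lai(campaign, weather, p0,
                                        max_nfev=30, mode=mode)
        p0 = step_a.params
        lai_trace = run_simulation(p0, weather, mode=mode,
                                   tpai_interception=True)
        curve = fit_tpai_quadratic(lai_trace, campaign)

    t1 = curve.dates[0]
    pre = campaign.stages[campaign.stages["date"] < t1]
    pre_dates = list(pre["date"])
    pre_lai = pre["lai"].to_numpy(dtype=float)

    def curve_residuals(p):
        trace = run_simulation(p, weather, mode=mode, tpai_interception=True)
        sim = np.array([_trace_values_at(trace, d)["TPAI"] for d in curve.dates])
        r = sim - curve.values
        if pre_dates:
            sim_lai = np.array([_trace_values_at(trace, d)["LAI"]
                                for d in pre_dates])
            r = np.concatenate([r, sim_lai - pre_lai])
        return r

    # yield terms carry extra weight so a handful of staged observations can
    # balance ~60 daily curve residuals
    n_curve = len(curve.dates)
    yw = math.sqrt(max(1.0, n_curve / 10.0))

    def residuals(p):
        trace = run_simulation(p, weather, mode=mode, tpai_interception=True)
        sim = np.array([_trace_values_at(trace, d)["TPAI"] for d in curve.dates])
        r = sim - curve.values
        if pre_dates:
            sim_lai = np.array([_trace_values_at(trace, d)["LAI"]
                                for d in pre_dates])
            r = np.concatenate([r, sim_lai - pre_lai])
        return np.concatenate([r, _yield_residuals(trace, campaign, yw)])

    fitted, obj, ilog, ok, msg = _refine(residuals, p0, free_set, max_nfev,
                                         primary_fn=curve_residuals)
    trace = run_simulation(fitted, weather, mode=mode, tpai_interception=True)
    return CalibrationResult(fitted, obj, _stage_residual_table(trace, campaign),
                             "TPAI-Curve", ilog, ok, msg)
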