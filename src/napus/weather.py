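"""Daily weather input: reading, validation, radiation derivation, IDW.

Weather files are plain CSV, one file per station, with columns
``date,tmin,tmax,precip,vap,wind,sunshine[,radiation]``.  Station registries
are CSV with ``name,lon,lat``.  Global radiation, when absent, is derived
from sunshine duration with the Angstrom-Prescott relation.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WEATHER_COLUMNS = ["date", "tmin", "tmax", "precip", "vap", "wind", "sunshine"]

SOLAR_CONSTANT = 1367.0       # W m-2
EARTH_RADIUS_KM = 6371.0


class WeatherFormatError(ValueError):
    """Malformed weather file (missing columns, duplicate or missing dates)."""


class WeatherValidationError(ValueError):
    """Physically inconsistent weather record."""


@dataclass(frozen=True)
class Station:
    name: str
    lon: float
    lat: float

    def __post_init__(self):
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")


@dataclass(frozen=True)
class WeatherRecord:
    date: dt.date
    tmin: float
    tmax: float
    precip: float
    vap: float
    wind: float
    sunshine: float
    radiation: float | None = None  # kJ m-2 d-1

    def __post_init__(self):
        if self.tmax < self.tmin:
            raise WeatherValidationError(
                f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if self.precip < 0:
            raise WeatherValidationError(f"{self.date}: negative precipitation")
        if not 0.0 <= self.sunshine <= 24.0:
            raise WeatherValidationError(f"{self.date}: sunshine outside [0, 24] h")
        if self.radiation is not None and self.radiation < 0:
            raise WeatherValidationError(f"{self.date}: negative radiation")


@dataclass
class WeatherSeries:
    """Ordered, gap-free daily weather for one station."""

    station: Station
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame.reset_index(drop=True)
        dates = pd.to_datetime(df["date"]).dt.date
        if dates.duplicated().any():
            raise WeatherFormatError("duplicate dates in weather series")
        diffs = pd.to_datetime(df["date"]).diff().dropna()
        if (diffs <= pd.Timedelta(0)).any():
            raise WeatherFormatError("weather dates must strictly increase")
        if (diffs > pd.Timedelta(days=1)).any():
            raise WeatherFormatError("gap in weather series dates")
        df = df.copy()
        df["date"] = dates
        bad = df.index[df["tmax"] < df["tmin"]]
        if len(bad):
            i = int(bad[0])
            raise WeatherValidationError(
                f"row {i + 1}: tmax {df['tmax'].iloc[i]} < tmin {df['tmin'].iloc[i]}")
        if (df["precip"] < 0).any():
            raise WeatherValidationError("negative precipitation")
        if ((df["sunshine"] < 0) | (df["sunshine"] > 24)).any():
            raise WeatherValidationError("sunshine outside [0, 24] h")
        if "radiation" not in df.columns:
            df["radiation"] = np.nan
        self.frame = df

    def __len__(self):
        return len(self.frame)

    @property
    def records(self) -> list[WeatherRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            rad = None if pd.isna(row.radiation) else float(row.radiation)
            out.append(WeatherRecord(row.date, row.tmin, row.tmax, row.precip,
                                     row.vap, row.wind, row.sunshine, rad))
        return out

    @property
    def start(self) -> dt.date:
        return self.frame["date"].iloc[0]

    @property
    def end(self) -> dt.date:
        return self.frame["date"].iloc[-1]

    def window(self, start: dt.date, end: dt.date) -> "WeatherSeries":
        """Sub-series over a closed date window; errors if not fully covered."""
        if start < self.start or end > self.end:
            raise WeatherFormatError(
                f"weather covers [{self.start}, {self.end}], "
                f"requested [{start}, {end}]")
        m = (self.frame["date"] >= start) & (self.frame["date"] <= end)
        return WeatherSeries(self.station, self.frame[m])

    def ensure_radiation(self, a: float = 0.25, b: float = 0.50) -> "WeatherSeries":
        """Fill missing radiation from sunshine via Angstrom-Prescott."""
        df = self.frame.copy()
        missing = df["radiation"].isna()
        if missing.any():
            vals = [
                angstrom_radiation(row.sunshine, row.date, self.station.lat, a, b)
                for row in df[missing].itertuples(index=False)
            ]
            df.loc[missing, "radiation"] = vals
        return WeatherSeries(self.station, df)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_weather_csv(path, station: Station | None = None) -> WeatherSeries:
    """Read one station's daily weather CSV.

    The header must name the seven weather variables (radiation optional);
    dates are ISO-8601.
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"{path}: missing columns {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except ValueError as exc:
        raise WeatherFormatError(f"{path}: unparsable dates: {exc}") from exc
    if station is None:
        station = Station(name=str(path), lon=0.0, lat=0.0)
    return WeatherSeries(station, df)


def write_weather_csv(series: WeatherSeries, path) -> None:
    df = series.frame.copy()
    if df["radiation"].isna().all():
        df = df.drop(columns=["radiation"])
    df.to_csv(path, index=False)


def read_stations_csv(path) -> list[Station]:
    df = pd.read_csv(path)
    return [Station(r.name, float(r.lon), float(r.lat))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Solar geometry and Angstrom-Prescott radiation
# ---------------------------------------------------------------------------

def _declination(date: dt.date) -> float:
    doy = date.timetuple().tm_yday
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def day_length(date: dt.date, lat: float) -> float:
    """Astronomical day length in hours."""
    phi = math.radians(lat)
    delta = _declination(date)
    cosw = -math.tan(phi) * math.tan(delta)
    cosw = min(1.0, max(-1.0, cosw))
    return 24.0 / math.pi * math.acos(cosw)


def extraterrestrial_radiation(date: dt.date, lat: float) -> float:
    """Daily extraterrestrial radiation in kJ m-2 d-1."""
    doy = date.timetuple().tm_yday
    phi = math.radians(lat)
    delta = _declination(date)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    cosw = min(1.0, max(-1.0, -math.tan(phi) * math.tan(delta)))
    ws = math.acos(cosw)
    ra = (24.0 * 3600.0 / math.pi) * (SOLAR_CONSTANT / 1000.0) * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))
    return max(0.0, ra)  # kJ m-2 d-1


def angstrom_radiation(sunshine: float, date: dt.date, lat: float,
                       a: float = 0.25, b: float = 0.50) -> float:
    """Global radiation (kJ m-2 d-1) from sunshine duration.

    Angstrom-Prescott: ``Rs = (a + b * n/N) * Ra`` with day length N and
    extraterrestrial radiation Ra.
    """
    n_max = day_length(date, lat)
    if sunshine < 0 or sunshine > n_max + 1e-9:
        raise WeatherValidationError(
            f"sunshine {sunshine} h exceeds day length {n_max:.2f} h on {date}")
    ra = extraterrestrial_radiation(date, lat)
    return (a + b * sunshine / n_max) * ra


# ---------------------------------------------------------------------------
# Inverse-distance weighting
# ---------------------------------------------------------------------------

def great_circle_km(a: Station, b: Station) -> float:
    """Haversine distance in km."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (math.sin((la2 - la1) / 2.0) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def idw_interpolate(target: Station, sources: list[tuple[Station, float]],
                    power: float = 2.0) -> float:
    """Inverse-distance-weighted value at ``target``.

    Distances are great-circle km; an exact station match returns that
    station's value directly.
    """
    if not sources:
        raise ValueError("idw_interpolate needs at least one source")
    if power <= 0:
        raise ValueError("power must be positive")
    num = den = 0.0
    for st, val in sources:
        d = great_circle_km(target, st)
        if d == 0.0:
            return float(val)
        w = d ** (-power)
        num += w * val
        den += w
    return num / den


def interpolate_weather(target: Station, series_list: list[WeatherSeries],
                        power: float = 2.0) -> WeatherSeries:
    """IDW-interpolate every weather variable, day by day, to ``target``.

    All source series must share the same date range.  Interpolating tmin
    and tmax independently cannot produce tmax < tmin when no source does
    (IDW is bounded by source values), but the result is clamped and logged
    defensively anyway.
    """
    if not series_list:
        raise ValueError("no source weather series")
    ref_dates = list(series_list[0].frame["date"])
    for s in series_list[1:]:
        if list(s.frame["date"]) != ref_dates:
            raise WeatherFormatError("source series have differing date ranges")
    cols = [c for c in WEATHER_COLUMNS if c != "date"] + ["radiation"]
    out = {"date": ref_dates}
    for col in cols:
        vals = []
        for i in range(len(ref_dates)):
            src = [(s.station, float(s.frame[col].iloc[i])) for s in series_list
                   if col in s.frame.columns and not pd.isna(s.frame[col].iloc[i])]
            vals.append(idw_interpolate(target, src, power) if src else np.nan)
        out[col] = vals
    df = pd.DataFrame(out)
    crossed = df["tmax"] < df["tmin"]
    if crossed.any():
        log.warning("IDW produced tmax < tmin on %d day(s); clamping",
                    int(crossed.sum()))
        df.loc[crossed, "tmax"] = df.loc[crossed, "tmin"]
    return WeatherSeries(target, df)
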