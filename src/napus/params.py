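"""Crop parameter containers: AFGEN tables and the full parameter set.

The parameter set follows WOFOST naming (TSUM1, SPA, FLTB, ...).  Scalars with
published single-point means carry those means as defaults; everything else
(engine internals such as the light-response tables) defaults to values typical
for winter oilseed rape and is fully configurable.

DVS is the dimensionless development stage: 0 at emergence, 1 at flowering,
2 at maturity.
"""

from __future__ import annotations

import bisect
import copy as _copy
import datetime as dt
import re
from dataclasses import dataclass, field, fields
from importlib import resources

import yaml


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its declared constraints."""


# ---------------------------------------------------------------------------
# AFGEN tables
# ---------------------------------------------------------------------------

class AfgenTable:
    """Piecewise-linear lookup table over DVS or temperature.

    Evaluation clamps at both ends, i.e. ``table(x)`` returns the first
    (last) y for x below (above) the breakpoint range.
    """

    __slots__ = ("x", "y")

    def __init__(self, points):
        pts = sorted((float(x), float(y)) for x, y in points)
        if len(pts) < 2:
            raise ConfigurationError("AFGEN table needs at least 2 breakpoints")
        xs = [p[0] for p in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError(f"AFGEN breakpoints must strictly increase: {xs}")
        self.x = xs
        self.y = [p[1] for p in pts]

    @classmethod
    def from_dict(cls, d: dict) -> "AfgenTable":
        return cls(d.items())

    def __call__(self, v: float) -> float:
        x, y = self.x, self.y
        if v <= x[0]:
            return y[0]
        if v >= x[-1]:
            return y[-1]
        i = bisect.bisect_right(x, v)
        x0, x1 = x[i - 1], x[i]
        return y[i - 1] + (y[i] - y[i - 1]) * (v - x0) / (x1 - x0)

    def as_pairs(self):
        return list(zip(self.x, self.y))

    def value_at(self, xb: float) -> float:
        """y at an existing breakpoint (exact match required)."""
        for xi, yi in zip(self.x, self.y):
            if abs(xi - xb) < 1e-9:
                return yi
        raise KeyError(f"no breakpoint at x={xb}")

    def with_value_at(self, xb: float, yb: float) -> "AfgenTable":
        """Copy of the table with the y at breakpoint ``xb`` replaced."""
        pairs = []
        hit = False
        for xi, yi in zip(self.x, self.y):
            if abs(xi - xb) < 1e-9:
                pairs.append((xi, float(yb)))
                hit = True
            else:
                pairs.append((xi, yi))
        if not hit:
            raise KeyError(f"no breakpoint at x={xb}")
        return AfgenTable(pairs)

    def __eq__(self, other):
        return isinstance(other, AfgenTable) and self.x == other.x and self.y == other.y

    def __repr__(self):
        return f"AfgenTable({self.as_pairs()})"


def afgen_eval(table: AfgenTable, x: float) -> float:
    """Functional form of AFGEN evaluation (alias for ``table(x)``)."""
    return table(x)


# ---------------------------------------------------------------------------
# Published parameter fixture
# ---------------------------------------------------------------------------

def _load_fixture() -> dict:
    with resources.files("napus.data").joinpath("crop_parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


_FIXTURE = _load_fixture()

#: scalar name -> (mean, min, max) for the single-point simulation
SINGLE_POINT_SCALARS: dict[str, tuple[float, float, float]] = {
    k: (v["mean"], v["min"], v["max"])
    for k, v in _FIXTURE["single_point"]["scalars"].items()
}

#: table name -> {DVS: (mean, min, max)} for the partition coefficients
PARTITION_ROWS: dict[str, dict[float, tuple[float, float, float]]] = {
    name: {float(d): tuple(row) for d, row in rows.items()}
    for name, rows in _FIXTURE["single_point"]["partition"].items()
}

#: wide absolute screening bounds per symbol
SCREENING_BOUNDS: dict[str, tuple[float, float]] = {
    k: tuple(v) for k, v in _FIXTURE["screening_bounds"].items()
}

PARTITION_NAMES = ("FLTB", "FSTB", "FOTB")
PARTITION_DVS = sorted(PARTITION_ROWS["FLTB"])


def _renormalized_partition_tables(values: dict[str, dict[float, float]]):
    """Force FLTB+FSTB+FOTB = 1 at every DVS breakpoint by rescaling."""
    out = {n: {} for n in PARTITION_NAMES}
    for d in PARTITION_DVS:
        tot = sum(values[n][d] for n in PARTITION_NAMES)
        if tot <= 0:
            # all-zero row: park everything in the stem fraction
            out["FLTB"][d], out["FOTB"][d], out["FSTB"][d] = 0.0, 0.0, 1.0
        else:
            for n in PARTITION_NAMES:
                out[n][d] = values[n][d] / tot
    return {n: AfgenTable.from_dict(v) for n, v in out.items()}


def default_partition_tables() -> dict[str, AfgenTable]:
    means = {n: {d: PARTITION_ROWS[n][d][0] for d in PARTITION_DVS}
             for n in PARTITION_NAMES}
    return _renormalized_partition_tables(means)


# ---------------------------------------------------------------------------
# Crop parameter set
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"^([A-Z]+)(\d+(?:\.\d+)?)$")


@dataclass
class CropParameterSet:
    """All crop, initial-state and engine parameters for one simulation.

    Scalar symbols and AFGEN tables follow WOFOST conventions.  Fields
    without a published single-point value default to winter oilseed rape
    settings chosen by this package (see the methods note).
    """

    # phenology
    TSUMEM: float = 25.0      # degC.d sowing -> emergence
    TBASEM: float = 3.0       # degC emergence base temperature
    TSUM1: float = 701.0      # degC.d emergence -> flowering
    TSUM2: float = 737.0      # degC.d flowering -> maturity
    TBASE: float = 5.0        # degC base temperature (DVS + leaf ageing)
    # initial state
    TDWI: float = 8.9         # kg.ha-1 total initial dry matter
    LAIEM: float = 0.015      # ha.ha-1 LAI at emergence
    WAV: float = 42.0         # cm initial available soil water
    # leaves
    RGRLAI: float = 0.012     # (degC.d)-1 max relative LAI growth rate
    SPAN: float = 37.4        # d leaf life span (physiological)
    SLATB: AfgenTable = field(
        default_factory=lambda: AfgenTable([(0.0, 0.0030), (2.0, 0.0020)]))
    # pods
    SPA: float = 0.00065      # ha.kg-1 specific pod area
    # light & assimilation
    KDIFTB: AfgenTable = field(
        default_factory=lambda: AfgenTable([(0.0, 0.60), (2.0, 0.75)]))
    EFFTB: AfgenTable = field(
        default_factory=lambda: AfgenTable([(0.0, 0.45), (40.0, 0.45)]))
    AMAXTB: AfgenTable = field(
        default_factory=lambda: AfgenTable(
            [(0.0, 35.0), (1.0, 35.0), (1.7, 25.0), (2.0, 15.0)]))
    TMPFTB: AfgenTable = field(
        default_factory=lambda: AfgenTable(
            [(0.0, 0.01), (3.0, 0.05), (10.0, 0.60), (15.0, 0.85),
             (20.0, 1.00), (30.0, 1.00), (35.0, 0.85), (40.0, 0.60)]))
    # conversion efficiencies
    CVL: float = 0.439
    CVO: float = 0.612
    CVR: float = 0.526
    CVS: float = 0.350
    # maintenance respiration (kg CH2O per kg dry matter per day at 25 degC)
    RML: float = 0.030
    RMO: float = 0.010
    RMR: float = 0.015
    RMS: float = 0.015
    Q10: float = 2.0
    # partitioning
    FLTB: AfgenTable = field(default_factory=lambda: default_partition_tables()["FLTB"])
    FSTB: AfgenTable = field(default_factory=lambda: default_partition_tables()["FSTB"])
    FOTB: AfgenTable = field(default_factory=lambda: default_partition_tables()["FOTB"])
    FRTB: AfgenTable = field(
        default_factory=lambda: AfgenTable([(0.0, 0.40), (1.3, 0.0), (2.0, 0.0)]))
    # water bucket
    soil_capacity: float = 80.0   # cm maximum root-zone storage
    critical_fraction: float = 0.5  # stress onset as fraction of capacity
    # engine constants (documented choices, not published values)
    canopy_reflection: float = 0.08
    senescence_t_ref: float = 15.0  # degC reference for leaf ageing (SPAN = life span in days at this temperature)
    # run configuration
    sowing_date: dt.date = dt.date(2020, 10, 15)
    emergence_mode: str = "tsum"   # "tsum" or "fixed"
    emergence_date: dt.date | None = None

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for name in ("CVL", "CVO", "CVR", "CVS"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in (0, 1]")
        if self.TSUM1 <= 0 or self.TSUM2 <= 0:
            raise ConfigurationError("TSUM1 and TSUM2 must be positive")
        if self.SPAN <= 0:
            raise ConfigurationError("SPAN must be positive")
        if self.SPA < 0:
            raise ConfigurationError("SPA must be non-negative")
        self._check_partition_sum()
        # honour the published bounds: the wide screening range, widened where
        # the single-point table quotes a range beyond it (the two published
        # tables disagree for TDWI)
        for name, (lo, hi) in SCREENING_BOUNDS.items():
            if name in SINGLE_POINT_SCALARS:
                _, slo, shi = SINGLE_POINT_SCALARS[name]
                lo, hi = min(lo, slo), max(hi, shi)
            v = getattr(self, name, None)
            if isinstance(v, (int, float)) and not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ConfigurationError(
                    f"{name}={v} outside its declared bounds [{lo}, {hi}]")

    def _check_partition_sum(self, tol: float = 1e-6) -> None:
        xs = sorted(set(self.FLTB.x) | set(self.FSTB.x) | set(self.FOTB.x))
        for d in xs:
            s = self.FLTB(d) + self.FSTB(d) + self.FOTB(d)
            if abs(s - 1.0) > tol:
                raise ConfigurationError(
                    f"FLTB+FSTB+FOTB = {s!r} != 1 at DVS {d}")

    # -- generic access by symbol tag --------------------------------------

    _TABLE_FIELDS = ("SLATB", "KDIFTB", "EFFTB", "AMAXTB", "TMPFTB",
                     "FLTB", "FSTB", "FOTB", "FRTB")

    @staticmethod
    def parse_tag(tag: str) -> tuple[str, float | None]:
        """Split e.g. ``'SLATB0.00'`` into ``('SLATB', 0.0)``; scalars pass through."""
        m = _TAG_RE.match(tag)
        if m and m.group(1).endswith("TB"):
            return m.group(1), float(m.group(2))
        return tag, None

    def get(self, tag: str) -> float:
        name, x = self.parse_tag(tag)
        obj = getattr(self, name)
        if x is None:
            if isinstance(obj, AfgenTable):
                raise KeyError(f"{tag}: table symbol needs a breakpoint suffix")
            return float(obj)
        return obj.value_at(x)

    def set(self, tag: str, value: float) -> None:
        """Set a scalar or a table breakpoint value in place.

        Setting a partition coefficient (FLTB/FSTB/FOTB at some DVS) rescales
        the other two members at that DVS so the triplet keeps summing to 1.
        """
        name, x = self.parse_tag(tag)
        if x is None:
            if name in self._TABLE_FIELDS:
                raise KeyError(f"{tag}: table symbol needs a breakpoint suffix")
            setattr(self, name, float(value))
            return
        if name in PARTITION_NAMES:
            self._set_partition(name, x, float(value))
        else:
            setattr(self, name, getattr(self, name).with_value_at(x, value))

    def _set_partition(self, name: str, x: float, value: float) -> None:
        value = min(max(value, 0.0), 1.0)
        others = [n for n in PARTITION_NAMES if n != name]
        rest = 1.0 - value
        cur = [getattr(self, n).value_at(x) for n in others]
        tot = sum(cur)
        if tot > 0:
            shares = [c / tot * rest for c in cur]
        else:
            shares = [rest / 2.0, rest / 2.0]
        setattr(self, name, getattr(self, name).with_value_at(x, value))
        for n, s in zip(others, shares):
            setattr(self, n, getattr(self, n).with_value_at(x, s))

    def copy(self) -> "CropParameterSet":
        return _copy.deepcopy(self)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, AfgenTable):
                out[f.name] = [list(p) for p in v.as_pairs()]
            elif isinstance(v, dt.date):
                out[f.name] = v.isoformat()
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CropParameterSet":
        kw = {}
        valid = {f.name for f in fields(cls)}
        for k, v in d.items():
            if k not in valid:
                raise ConfigurationError(f"unknown parameter {k!r}")
            if k in cls._TABLE_FIELDS:
                kw[k] = AfgenTable(v) if not isinstance(v, AfgenTable) else v
            elif k in ("sowing_date", "emergence_date") and isinstance(v, str):
                kw[k] = dt.date.fromisoformat(v)
            else:
                kw[k] = v
        ps = cls(**kw)
        ps.validate()
        return ps

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CropParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def bounds_for(tag: str) -> tuple[float, float]:
    """Calibration bounds for a symbol tag.

    Prefers the published single-point min/max (scalar symbols and partition
    rows); falls back to the wide screening bounds for everything else.
    """
    name, x = CropParameterSet.parse_tag(tag)
    if x is None and name in SINGLE_POINT_SCALARS:
        _, lo, hi = SINGLE_POINT_SCALARS[name]
        return lo, hi
    if x is not None and name in PARTITION_ROWS:
        rows = PARTITION_ROWS[name]
        for d, (_, lo, hi) in rows.items():
            if abs(d - x) < 1e-9:
                return lo, hi
    if name in SCREENING_BOUNDS:
        return SCREENING_BOUNDS[name]
    raise KeyError(f"no bounds known for {tag!r}")
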