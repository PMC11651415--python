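"""Field formulas: organ geometry to area indices and agronomic quantities.

Oilseed rape leaves are treated as ellipses (area = pi/4 * length * width);
siliques (pods) as cylinders (lateral area = pi * diameter * length), with a
prolate-spheroid alternative behind a flag.  LAI and SAI come from the same
linear regression against aggregated organ area (default slope 0.005,
intercept 1.318); their sum is the total photosynthetic area index TPAI.
Before silique emergence SAI is 0 by definition and TPAI equals LAI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LeafGeometry:
    length: float  # cm
    width: float   # cm

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("leaf length and width must be positive")


@dataclass(frozen=True)
class SiliqueGeometry:
    length: float    # cm
    diameter: float  # cm

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("silique length and diameter must be positive")


@dataclass(frozen=True)
class AreaIndexRegression:
    """Linear map from aggregated organ area to an area index."""

    slope: float = 0.005
    intercept: float = 1.318
    r2: float | None = None
    rmse: float | None = None
    nrmse: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class PlotCounts:
    n_a: float               # plants or siliques per quadrat
    quadrat_side: float = 100.0  # cm

    def __post_init__(self):
        if self.n_a < 0:
            raise ValueError("count must be non-negative")
        if self.quadrat_side <= 0:
            raise ValueError("quadrat side must be positive")


@dataclass(frozen=True)
class OrganMass:
    m_d: float  # g dry
    m_w: float  # g wet

    def __post_init__(self):
        if self.m_d < 0:
            raise ValueError("dry mass must be non-negative")
        if self.m_d > self.m_w:
            raise ValueError(f"dry mass {self.m_d} exceeds wet mass {self.m_w}")


@dataclass(frozen=True)
class YieldSample:
    m_b: float  # g per unit plot
    n_b: float  # seed count per unit plot

    def __post_init__(self):
        if self.n_b <= 0:
            raise ValueError("seed count must be positive")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def leaf_area(geom: LeafGeometry) -> float:
    """Single leaf area (cm^2), ellipse approximation."""
    return math.pi / 4.0 * geom.length * geom.width


def silique_surface_area(geom: SiliqueGeometry, shape: str = "cylinder") -> float:
    """Single silique surface area (cm^2).

    ``cylinder`` (default) is the lateral cylinder area pi*d*l; ``spheroid``
    treats the pod as a prolate spheroid of polar axis l and equatorial axis d.
    """
    l, d = geom.length, geom.diameter
    if shape == "cylinder":
        return math.pi * d * l
    if shape == "spheroid":
        a, c = d / 2.0, l / 2.0  # equatorial, polar semi-axes
        if c <= a:
            return 4.0 * math.pi * a * a
        e = math.sqrt(1.0 - (a / c) ** 2)
        return 2.0 * math.pi * a * a * (1.0 + (c / (a * e)) * math.asin(e))
    raise ValueError(f"unknown silique shape {shape!r}")


# ---------------------------------------------------------------------------
# Area indices
# ---------------------------------------------------------------------------

def lai_from_leaf_area(s_l: float,
                       reg: AreaIndexRegression = AreaIndexRegression()) -> float:
    """LAI from aggregated leaf area via the linear regression."""
    if s_l < 0:
        raise ValueError("aggregated leaf area must be non-negative")
    return reg.slope * s_l + reg.intercept


def sai_from_silique_area(s_p: float,
                          reg: AreaIndexRegression = AreaIndexRegression(),
                          siliques_present: bool = True) -> float:
    """SAI from aggregated silique area; exactly 0 before silique emergence."""
    if s_p < 0:
        raise ValueError("aggregated silique area must be non-negative")
    if not siliques_present:
        return 0.0
    return reg.slope * s_p + reg.intercept


def tpai(lai: float, sai: float) -> float:
    """Total photosynthetic area index: LAI + SAI."""
    if lai < 0 or sai < 0:
        raise ValueError("LAI and SAI must be non-negative")
    return lai + sai


def aggregate_organ_area(areas_cm2, plants_per_m2: float | None = None) -> float:
    """Mean per-plant organ area, optionally scaled by plant density.

    With ``plants_per_m2`` given, returns mean area * density (cm^2 m-2);
    otherwise the per-plant mean.  The regression coefficients must match
    whichever aggregation produced them.
    """
    areas = np.asarray(list(areas_cm2), dtype=float)
    if areas.size == 0:
        raise ValueError("no organ areas to aggregate")
    mean = float(areas.mean())
    return mean * plants_per_m2 if plants_per_m2 is not None else mean


# ---------------------------------------------------------------------------
# Plot-level quantities
# ---------------------------------------------------------------------------

def plant_density(counts: PlotCounts) -> float:
    """Plants (or siliques) per m^2 from a quadrat count."""
    return 1.0e4 * counts.n_a / counts.quadrat_side ** 2


def water_content(mass: OrganMass) -> float:
    """Organ water fraction 1 - m_d/m_w."""
    if mass.m_w <= 0:
        raise ValueError("wet mass must be positive")
    return 1.0 - mass.m_d / mass.m_w


def thousand_seed_weight(y: YieldSample) -> float:
    """Thousand-seed weight in g: m_b / n_b * 1000."""
    return y.m_b / y.n_b * 1000.0


# ---------------------------------------------------------------------------
# Regression fit
# ---------------------------------------------------------------------------

def fit_area_index_regression(pairs) -> AreaIndexRegression:
    """Ordinary least squares of area index on aggregated organ area.

    ``pairs`` is a sequence of (area cm^2, measured index).  Reports R^2,
    RMSE and NRMSE (percent of the observed mean) of the fit.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (area, index) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all areas identical")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = math.sqrt(ss_res / len(y))
    nrmse = 100.0 * rmse / y.mean() if y.mean() != 0 else float("nan")
    return AreaIndexRegression(float(slope), float(intercept), r2, rmse, nrmse)
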