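"""Accuracy metrics for observed-vs-simulated series.

R^2 is the coefficient of determination 1 - SS_res/SS_tot by default (a
squared-Pearson variant is available, since the two differ for biased
predictors).  NRMSE normalises by the observed mean (percent); a
range-normalised variant is available.  The estimation bias rate is the
relative difference of the means: positive values mean underestimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairedSeries:
    observed: np.ndarray
    simulated: np.ndarray
    units: str = ""

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float)
        sim = np.asarray(self.simulated, dtype=float)
        if obs.shape != sim.shape or obs.ndim != 1 or obs.size < 2:
            raise ValueError("need two equal-length 1-d series of length >= 2")
        if not (np.isfinite(obs).all() and np.isfinite(sim).all()):
            raise ValueError("series must be finite")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "simulated", sim)


def _unpack(p, sim=None):
    if isinstance(p, PairedSeries):
        return p.observed, p.simulated
    return PairedSeries(np.asarray(p, float), np.asarray(sim, float)).observed, \
        np.asarray(sim, float)


def r_squared(p, sim=None, variant: str = "determination") -> float:
    """Coefficient of determination (default) or squared Pearson correlation."""
    obs, s = _unpack(p, sim)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero observed variance: R^2 undefined")
    if variant == "determination":
        ss_res = float(((obs - s) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    if variant == "pearson":
        if float(((s - s.mean()) ** 2).sum()) == 0:
            raise ValueError("zero simulated variance: Pearson R^2 undefined")
        return float(np.corrcoef(obs, s)[0, 1] ** 2)
    raise ValueError(f"unknown R^2 variant {variant!r}")


def rmse(p, sim=None) -> float:
    obs, s = _unpack(p, sim)
    return math.sqrt(float(((obs - s) ** 2).mean()))


def nrmse(p, sim=None, normalizer: str = "mean") -> float:
    """RMSE as a percentage of the observed mean (or range)."""
    obs, s = _unpack(p, sim)
    if normalizer == "mean":
        denom = float(obs.mean())
    elif normalizer == "range":
        denom = float(obs.max() - obs.min())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom == 0:
        raise ValueError("zero normalizer: NRMSE undefined")
    return 100.0 * rmse(obs, s) / denom


def estimation_bias_rate(p, sim=None) -> float:
    """100*(mean(obs) - mean(sim))/mean(obs); positive = underestimation."""
    obs, s = _unpack(p, sim)
    m = float(obs.mean())
    if m == 0:
        raise ValueError("zero observed mean: bias rate undefined")
    return 100.0 * (m - float(s.mean())) / m


def metrics_report(p, sim=None, units: str = "") -> pd.DataFrame:
    """All four metrics as a tidy report table."""
    obs, s = _unpack(p, sim)
    rows = [
        ("r_squared", r_squared(obs, s), "-"),
        ("rmse", rmse(obs, s), units),
        ("nrmse", nrmse(obs, s), "%"),
        ("estimation_bias_rate", estimation_bias_rate(obs, s), "%"),
    ]
    return pd.DataFrame(rows, columns=["metric", "value", "units"]).assign(n=obs.size)
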