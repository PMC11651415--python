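"""Extended FAST variance-based sensitivity analysis.

Classic EFAST: each parameter in turn is driven at a high frequency along a
space-filling search curve ``x_i(s) = 0.5 + (1/pi) asin(sin(w_i s + phi_i))``
(with seeded random phase shifts), the remaining parameters at low
complementary frequencies; first-order indices come from the spectral power
at the driving frequency and its harmonics, total-order indices from the
complement of the low-frequency power.  The design costs ``n`` model runs
per parameter (``n * p`` total), and ``n`` must exceed 65 per parameter.

Shoot dry-matter partition coefficients (FLTB/FSTB/FOTB at a shared DVS)
must sum to 1; the sequential-conditional transform FL in [0,1],
FS in [0, 1-FL], FO = 1-FL-FS is applied column-wise over the raw design.
Indices for the transformed columns lose the pure search-curve structure
and are flagged approximate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN_SAMPLES_PER_PARAM = 65


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterSpec:
    """One parameter's name, range and optional partition-triplet tag."""

    name: str
    lower: float
    upper: float
    group: str = "free"   # "free" or "partition:<DVS>"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise DesignError(f"{self.name}: lower must be < upper")


@dataclass
class EfastDesign:
    """Sample matrix plus the frequency bookkeeping needed for analysis."""

    samples: np.ndarray            # (n*p, p)
    specs: list[ParameterSpec]
    n: int                         # samples per parameter
    omega_max: int                 # driving frequency
    harmonics: int                 # M
    seed: int
    constrained: set = field(default_factory=set)  # transformed column names

    @property
    def p(self) -> int:
        return len(self.specs)

    @property
    def total_runs(self) -> int:
        return self.n * self.p

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)


@dataclass
class SensitivityResult:
    """Per-parameter S1/ST tables keyed by output label."""

    tables: dict  # label -> DataFrame(parameter, S1, ST, approximate)

    def table(self, label: str) -> pd.DataFrame:
        return self.tables[label]

    def to_csv(self, path) -> None:
        frames = [t.assign(output=lbl) for lbl, t in self.tables.items()]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Design generation
# ---------------------------------------------------------------------------

def _frequencies(p: int, n: int, M: int) -> tuple[int, np.ndarray]:
    """Driving frequency and complementary frequencies (classic FAST)."""
    omega_max = (n - 1) // (2 * M)
    if omega_max < 2:
        raise DesignError(f"n={n} too small for M={M} harmonics")
    m = max(1, omega_max // (2 * M))
    if p == 1:
        others = np.array([], dtype=int)
    elif m >= p - 1:
        others = np.floor(np.linspace(1, m, p - 1)).astype(int)
    else:
        others = (np.arange(p - 1) % m) + 1
    return omega_max, others


def generate_design(specs: list[ParameterSpec], n: int, seed: int,
                    harmonics: int = 4) -> EfastDesign:
    """Seeded EFAST search-curve design with n runs per parameter.

    Enforces the sampling rule n >= 65 * p per parameter set.
    """
    p = len(specs)
    if p == 0:
        raise DesignError("no parameters")
    minimum = MIN_SAMPLES_PER_PARAM * p
    if n < minimum:
        raise DesignError(
            f"n={n} violates the EFAST sampling rule: the number of samples "
            f"must exceed 65 times the number of parameters "
            f"(required minimum {minimum} for p={p})")
    omega_max, others = _frequencies(p, n, harmonics)
    rng = np.random.default_rng(seed)
    s = (2.0 * np.pi / n) * np.arange(n)
    blocks = []
    for i in range(p):
        omega = np.empty(p)
        omega[i] = omega_max
        idx = [j for j in range(p) if j != i]
        omega[idx] = others
        phi = rng.uniform(0.0, 2.0 * np.pi, size=p)
        angle = np.outer(s, omega) + phi
        x = 0.5 + np.arcsin(np.sin(angle)) / np.pi   # uniform on (0, 1)
        blocks.append(x)
    unit = np.vstack(blocks)
    lo = np.array([sp.lower for sp in specs])
    hi = np.array([sp.upper for sp in specs])
    samples = lo + unit * (hi - lo)
    return EfastDesign(samples, list(specs), n, omega_max, harmonics, seed)


# ---------------------------------------------------------------------------
# Partition-coefficient constraint
# ---------------------------------------------------------------------------

_PART_RE = re.compile(r"^(FLTB|FSTB|FOTB)(\d+(?:\.\d+)?)$")


def _find_triplets(names: list[str]) -> dict[str, dict[str, int]]:
    found: dict[str, dict[str, int]] = {}
    for j, name in enumerate(names):
        m = _PART_RE.match(name)
        if m:
            found.setdefault(m.group(2), {})[m.group(1)] = j
    return found


def apply_partition_constraint(design: EfastDesign,
                               triplets: list[str] | None = None) -> EfastDesign:
    """Re-map each FLTB/FSTB/FOTB triplet onto the unit simplex, row-wise.

    For every row and DVS tag: FL is rescaled to [0, 1], FS to [0, 1-FL],
    and FO is set to 1-FL-FS, replacing all three columns.  Row count and
    all non-triplet columns are untouched.
    """
    names = design.names
    available = _find_triplets(names)
    tags = triplets if triplets is not None else sorted(available)
    samples = design.samples.copy()
    constrained = set(design.constrained)
    for tag in tags:
        cols = available.get(tag, {})
        missing = [m for m in ("FLTB", "FSTB", "FOTB") if m not in cols]
        if missing:
            raise DesignError(
                f"partition triplet at DVS {tag} is missing {missing}")
        jl, js, jo = cols["FLTB"], cols["FSTB"], cols["FOTB"]
        for j in (jl, js, jo):
            sp = design.specs[j]
            lo, hi = sp.lower, sp.upper
            if hi > lo:
                samples[:, j] = (samples[:, j] - lo) / (hi - lo)
            else:
                samples[:, j] = 0.0
        fl = samples[:, jl]
        fs = samples[:, js] * (1.0 - fl)
        samples[:, js] = fs
        samples[:, jo] = 1.0 - fl - fs
        constrained.update(names[j] for j in (jl, js, jo))
    return EfastDesign(samples, design.specs, design.n, design.omega_max,
                       design.harmonics, design.seed, constrained)


# ---------------------------------------------------------------------------
# Index estimation
# ---------------------------------------------------------------------------

def _indices_for_block(y: np.ndarray, omega_max: int, M: int) -> tuple[float, float]:
    n = y.size
    f = np.fft.fft(y - y.mean())
    half = (n - 1) // 2
    spectrum = (np.abs(f[1:half + 1]) / n) ** 2
    total_var = 2.0 * spectrum.sum()
    if total_var <= 0:
        raise ValueError("zero output variance: indices undefined")
    hidx = np.array([h * omega_max for h in range(1, M + 1)])
    hidx = hidx[hidx <= half]
    d1 = 2.0 * spectrum[hidx - 1].sum()
    cutoff = omega_max // 2
    dcomp = 2.0 * spectrum[:cutoff].sum()
    return d1 / total_var, 1.0 - dcomp / total_var


def compute_indices(design: EfastDesign, outputs) -> SensitivityResult:
    """First-order (S1) and total (ST) indices per parameter.

    ``outputs`` is a 1-d vector of length n*p, or a mapping of output label
    to such a vector (e.g. LAIMAX/TWSO/TAGP).
    """
    if not isinstance(outputs, dict):
        outputs = {"output": np.asarray(outputs, dtype=float)}
    tables = {}
    for label, y in outputs.items():
        y = np.asarray(y, dtype=float)
        if y.size != design.total_runs:
            raise ValueError(
                f"{label}: expected {design.total_runs} outputs, got {y.size}")
        if not np.isfinite(y).all():
            raise ValueError(f"{label}: outputs must be finite")
        rows = []
        for i, sp in enumerate(design.specs):
            block = y[i * design.n:(i + 1) * design.n]
            s1, st = _indices_for_block(block, design.omega_max, design.harmonics)
            rows.append({"parameter": sp.name, "S1": s1, "ST": st,
                         "approximate": sp.name in design.constrained})
        tables[label] = pd.DataFrame(rows)
    return SensitivityResult(tables)


def rank_parameters(result: SensitivityResult, k: int,
                    output: str | None = None) -> list[str]:
    """Top-k parameter names by total-order index (ties by S1, then name)."""
    labels = list(result.tables)
    tbl = result.tables[output if output is not None else labels[0]]
    if k > len(tbl):
        raise ValueError(f"k={k} exceeds parameter count {len(tbl)}")
    ordered = tbl.sort_values(["ST", "S1", "parameter"],
                              ascending=[False, False, True],
                              kind="mergesort")
    return list(ordered["parameter"].head(k))


def run_model_over_design(design: EfastDesign, model) -> np.ndarray:
    """Evaluate ``model(row_dict) -> float`` over every design row."""
    names = design.names
    out = np.empty(design.samples.shape[0])
    for r, row in enumerate(design.samples):
        out[r] = model(dict(zip(names, row)))
    return out
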