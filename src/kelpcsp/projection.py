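"""Temperature-driven projection of kelp densities, export and CSP.

Yearly minimum (February) and maximum (August) sea surface temperatures
are smoothed with a LOESS-type local quadratic (tricube weights,
span 1).  Densities then scale linearly between thermal thresholds,
anchored at the 2016 reference year for which densities were measured:

    cold-temperate:  N_C = N * (T_U - T_max) / (T_U - T_max2016)
    warm-temperate:  N_W = N * (T_min - T_L) / (T_min2016 - T_L)

floored at zero beyond the threshold.  The warm species cannot occupy
the upper (emersion-stressed) zone, so N_W is capped at the total 2016
sporophyte density of the lower band; the cold species are optionally
capped at their own 2016 zone density (no re-expansion above observed
carrying capacity).  Projected export and CSP at a fixed sequestration
horizon t (days) are

    CE_T  = N_M * CE
    CSP_T = N_M * CE * (1 - t * D)

with product-of-means CIs per species and variance-sum CIs on the
forest totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .csp import CarbonBudget, Z_975, product_ci, variance_sum_se
from .species import Species


@dataclass(frozen=True)
class TemperatureSeries:
    scenario: str  # historical | RCP2.6 | RCP6.0 | RCP8.5
    years: np.ndarray
    t_min: np.ndarray  # February SST (degC)
    t_mean: np.ndarray  # annual mean SST
    t_max: np.ndarray  # August SST

    def __post_init__(self) -> None:
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.t_min > self.t_mean) or np.any(self.t_mean > self.t_max):
            raise ValueError("need t_min <= t_mean <= t_max elementwise")


@dataclass(frozen=True)
class ThermalThresholds:
    """Thermal limits anchoring the density models.

    ``t_upper``: upper limit for cold-temperate sporophyte growth (degC);
    has no default because it is read off the species' tolerance curve,
    not printed.  ``t_lower``: lower threshold for warm-temperate
    gametophyte fertility, 9.53 degC (the maximum SST when the warm
    species first established locally in 1946).
    """

    t_upper: float
    t_min2016: float
    t_max2016: float
    t_lower: float = 9.53

    def __post_init__(self) -> None:
        if self.t_lower >= self.t_upper:
            raise ValueError("need T_L < T_U")
        if self.t_upper <= self.t_max2016:
            raise ValueError("T_U must exceed the 2016 maximum SST")
        if self.t_min2016 <= self.t_lower:
            raise ValueError("2016 minimum SST must exceed T_L")


def loess(x, y, span: float = 1.0, degree: int = 2):
    """Tricube-weighted local polynomial smoother, evaluated at each x.

    With span 1 every point participates in every local fit, weighted by
    tricube distance; a local fit of ``degree`` 2 reproduces quadratics
    exactly.  Needs more points than the polynomial order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 1, int(math.ceil(span * n)))
    if n <= degree:
        raise ValueError(f"need more than {degree} points for a degree-{degree} fit")
    k = min(k, n)
    out = np.empty(n)
    for i, x0 in enumerate(x):
        dist = np.abs(x - x0)
        cutoff = np.sort(dist)[k - 1]
        if cutoff == 0:
            cutoff = np.max(dist) if np.max(dist) > 0 else 1.0
        w = np.clip(1 - (dist / cutoff) ** 3, 0, None) ** 3
        w[dist <= cutoff] = np.maximum(w[dist <= cutoff], 1e-12)
        xc = x - x0
        basis = np.vander(xc, degree + 1, increasing=True)
        wsqrt = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(basis * wsqrt[:, None], y * wsqrt, rcond=None)
        out[i] = coef[0]
    return out


def smooth_temperature(
    raw: TemperatureSeries, span: float = 1.0, degree: int = 2
) -> TemperatureSeries:
    """LOESS-smooth t_min/t_mean/t_max independently over the years."""
    if len(raw.years) < 10:
        raise ValueError("need >= 10 years of temperature data to smooth")
    smoothed = {
        name: loess(raw.years, getattr(raw, name), span=span, degree=degree)
        for name in ("t_min", "t_mean", "t_max")
    }
    # Independent smooths can cross where the bands nearly touch; restore order.
    t_mean = np.maximum(smoothed["t_min"], np.minimum(smoothed["t_mean"], smoothed["t_max"]))
    return replace(raw, t_min=smoothed["t_min"], t_mean=t_mean, t_max=smoothed["t_max"])


def density_cold(
    n_2016: float,
    thresholds: ThermalThresholds,
    t_max: "float | np.ndarray",
    cap: float | None = None,
) -> "float | np.ndarray":
    """Cold-temperate density under an August SST, floored at extinction."""
    scale = (thresholds.t_upper - np.asarray(t_max, dtype=float)) / (
        thresholds.t_upper - thresholds.t_max2016
    )
    n = np.maximum(0.0, n_2016 * scale)
    if cap is not None:
        n = np.minimum(n, cap)
    return float(n) if np.ndim(t_max) == 0 else n


def density_warm(
    n_2016: float,
    thresholds: ThermalThresholds,
    t_min: "float | np.ndarray",
    cap: float,
) -> "float | np.ndarray":
    """Warm-temperate density under a February SST, capped at the total
    observed lower-band density (the species cannot colonise the upper
    zone)."""
    scale = (np.asarray(t_min, dtype=float) - thresholds.t_lower) / (
        thresholds.t_min2016 - thresholds.t_lower
    )
    n = np.minimum(np.maximum(0.0, n_2016 * scale), cap)
    return float(n) if np.ndim(t_min) == 0 else n


def project_forest(
    budgets: dict[Species, CarbonBudget],
    temps: TemperatureSeries,
    thresholds: ThermalThresholds,
    horizon_t: float = 50.0,
    warm_cap: float | None = None,
    cap_cold: bool = False,
    z: float = Z_975,
) -> pd.DataFrame:
    """Yearly per-species densities, CE_T and CSP_T plus forest totals.

    ``budgets`` carry 2016 zone-weighted densities and annual export;
    ``warm_cap`` defaults to the summed 2016 densities of the two
    lower-band species.  CSP_T uses the sequestration horizon
    ``horizon_t`` (days), default 50.
    """
    missing = [s for s in Species if s not in budgets]
    if missing:
        raise ValueError(f"missing budgets for {[s.value for s in missing]}")
    if warm_cap is None:
        warm_cap = (
            budgets[Species.HYPERBOREA].n_density
            + budgets[Species.OCHROLEUCA].n_density
        )
    rows = []
    for i, year in enumerate(temps.years):
        row: dict = {"year": int(year), "scenario": temps.scenario}
        tot_ce = tot_csp = 0.0
        ce_halves, csp_halves = [], []
        for sp, b in budgets.items():
            if sp.thermal_affinity == "cold":
                n_m = density_cold(
                    b.n_density,
                    thresholds,
                    temps.t_max[i],
                    cap=b.n_density if cap_cold else None,
                )
            else:
                n_m = density_warm(b.n_density, thresholds, temps.t_min[i], warm_cap)
            # SE of the modelled density scales with the same linear factor.
            se_n = b.se_n * (n_m / b.n_density if b.n_density > 0 else 0.0)
            ce_t, ce_half = product_ci(n_m, se_n, b.ce, b.se_ce, z=z)
            decay = max(0.0, 1.0 - horizon_t * b.d)
            csp_t, csp_half = ce_t * decay, ce_half * decay
            row[f"N_{sp.value}"] = n_m
            row[f"CE_{sp.value}"] = ce_t
            row[f"CE_{sp.value}_ci"] = ce_half
            row[f"CSP_{sp.value}"] = csp_t
            row[f"CSP_{sp.value}_ci"] = csp_half
            tot_ce += ce_t
            tot_csp += csp_t
            ce_halves.append(ce_half)
            csp_halves.append(csp_half)
        row["CE_forest"] = tot_ce
        row["CE_forest_ci"] = variance_sum_se(ce_halves)
        row["CSP_forest"] = tot_csp
        row["CSP_forest_ci"] = variance_sum_se(csp_halves)
        rows.append(row)
    return pd.DataFrame(rows)


def decline_rate(
    projection: pd.DataFrame,
    start_year: int,
    end_year: int,
    column: str = "CSP_forest",
) -> float:
    """Average annual percentage decline of a forest series (% year^-1).

    Geometric-mean rate over the window: 100 * (1 - (end/start)^(1/yrs));
    positive = decline, negative = increase.
    """
    window = projection[(projection["year"] >= start_year) & (projection["year"] <= end_year)]
    if len(window) < 2:
        raise ValueError("window must contain at least two projected years")
    first, last = window.iloc[0], window.iloc[-1]
    years = last["year"] - first["year"]
    if first[column] <= 0:
        raise ValueError("zero or negative baseline; rate undefined")
    return 100.0 * (1.0 - (last[column] / first[column]) ** (1.0 / years))
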