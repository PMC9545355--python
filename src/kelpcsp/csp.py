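"""Carbon sequestration potential (CSP) model and its uncertainty.

CSP is defined as the carbon exported from the forest that remains
unremineralized at detrital age ``t`` (days), under linear decay:

    CSP(t) = N * CE * max(0, 1 - t * D)

where ``N`` is sporophyte density (plants m^-2, already weighted by the
vertical zone the species occupies), ``CE`` is carbon export
(g C plant^-1 period^-1) and ``D`` is the decomposition rate (day^-1).

Uncertainty follows two rules used throughout the pipeline:

* the variance sum law for sums of independent means,
  SE = sqrt(sum SE_i^2);
* Goodman's exact variance for the product of two independent means,
  Var(AB) = SE_A^2 SE_B^2 + SE_A^2 B^2 + SE_B^2 A^2,
  which yields the 95% CI half-width z * sqrt(Var) with z the 97.5
  percentile point of the standard normal (1.959964).

The decay factor (1 - t*D) carries no error into the CI: the interval
reflects density and export uncertainty only.  D's uncertainty surfaces
through the delta-method SE on the time to zero, SE(1/D) = SE_D / D^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .species import Species

#: 97.5 percentile point of the standard normal distribution.
Z_975 = 1.959964


@dataclass(frozen=True)
class CarbonBudget:
    """Per-species budget feeding the CSP model.

    ``n_density`` is the areal sporophyte density after zone weighting
    (plants m^-2), ``ce`` the carbon export per plant over ``period``
    and ``d`` the decomposition rate (day^-1).
    """

    species: Species
    n_density: float
    se_n: float
    ce: float
    se_ce: float
    d: float
    se_d: float
    period: str = "annual"
    be: float | None = None  # dry biomass export (g plant^-1 period^-1)
    se_be: float | None = None

    def __post_init__(self) -> None:
        if self.n_density < 0:
            raise ValueError("density must be non-negative")
        if self.ce < 0:
            raise ValueError("carbon export must be non-negative")
        for se in (self.se_n, self.se_ce, self.se_d):
            if se < 0:
                raise ValueError("standard errors must be non-negative")


@dataclass
class CspCurve:
    species: Species
    ages: np.ndarray
    csp: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    t_zero: float = field(default=math.inf)


def csp(budget: CarbonBudget, t: "float | np.ndarray") -> "float | np.ndarray":
    """CSP (g C m^-2 period^-1) at detrital age ``t`` days.

    Clamped at zero once the pool is fully remineralized (t >= 1/D).
    """
    decay = np.maximum(0.0, 1.0 - np.asarray(t, dtype=float) * budget.d)
    out = budget.n_density * budget.ce * decay
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def time_to_zero(d: float, se_d: float = 0.0) -> tuple[float, float]:
    """Detrital age (days) at which CSP reaches zero, with delta-method SE.

    Returns ``(inf, inf)`` flagged when D <= 0 (detritus growing rather
    than decomposing); report with ``round()`` for whole days.
    """
    if d <= 0:
        return math.inf, math.inf
    return 1.0 / d, se_d / d**2


def variance_sum_se(ses) -> float:
    """SE of a sum of independent means: sqrt(sum SE_i^2)."""
    arr = np.asarray(ses, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one standard error")
    if np.any(arr < 0):
        raise ValueError("standard errors must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


def product_ci(
    mean_a: float, se_a: float, mean_b: float, se_b: float, z: float = Z_975
) -> tuple[float, float]:
    """Mean and CI half-width of the product of two independent means.

    Uses Goodman's exact variance of a product of independent random
    variables, so the half-width matches a Monte-Carlo product of
    normals at large sample size.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    var = se_a**2 * se_b**2 + se_a**2 * mean_b**2 + se_b**2 * mean_a**2
    return mean_a * mean_b, z * math.sqrt(var)


def csp_curve(budget: CarbonBudget, ages) -> CspCurve:
    """Evaluate CSP and its 95% CI over a sorted grid of detrital ages.

    The CI applies the product-of-means rule to (N, CE) and scales with
    the (error-free) decay factor, matching how the pointwise interval
    behaves when D is treated as fixed.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or np.any(np.diff(ages) < 0):
        raise ValueError("ages must be a 1-d ascending array")
    mean0, half0 = product_ci(budget.n_density, budget.se_n, budget.ce, budget.se_ce)
    decay = np.maximum(0.0, 1.0 - ages * budget.d)
    values = mean0 * decay
    half = half0 * decay
    tz, _ = time_to_zero(budget.d, budget.se_d)
    return CspCurve(
        species=budget.species,
        ages=ages,
        csp=values,
        ci_low=values - half,
        ci_high=values + half,
        t_zero=tz,
    )
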