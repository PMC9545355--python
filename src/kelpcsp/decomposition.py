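"""Litterbag decomposition, grazing scars, phenolics and biochemistry trends.

Decomposition is proportional wet-mass loss per day in litterbags,

    D = (M_0 - M_1) / (M_0 * delta_t)        (day^-1),

negative when the detritus grew (observed in the shallow-forest
experiment).  Soluble polyphenolics are quantified against a
phloroglucinol (PG) standard curve from a Folin-Ciocalteu microplate
assay; detrital-age trends in phenolics, carbon content and C:N are
ordinary least-squares fits (linear, or log-linear for exponential
rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .species import Species


@dataclass(frozen=True)
class DecompositionEstimate:
    species: Species
    mean_d: float  # day^-1; negative = detrital growth
    se_d: float
    n: int


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # absorbance per (mg ml^-1)
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class TrendFit:
    """OLS slope of a response (possibly log-transformed) on detrital age."""

    slope: float
    se: float
    intercept: float
    model: str  # "linear" | "log-linear"
    n: int


def decomposition_rate(m_0: float, m_1: float, delta_t: float) -> float:
    """D = (M_0 - M_1) / (M_0 * delta_t), in day^-1 (wet-mass based)."""
    if m_0 <= 0:
        raise ValueError("initial mass must be positive")
    if m_1 < 0:
        raise ValueError("retrieved mass cannot be negative")
    if delta_t <= 0:
        raise ValueError("deployment time must be positive")
    return (m_0 - m_1) / (m_0 * delta_t)


def pool_rates(records: pd.DataFrame) -> list[DecompositionEstimate]:
    """Species mean, SE and n of D across all bags and both experiments.

    ``records`` needs columns species, M0_g, M1_g, delta_t_d.  Negative
    rates (growth) are retained in the pool.
    """
    out = []
    for sp, grp in records.groupby("species", sort=True):
        d = np.array(
            [
                decomposition_rate(r.M0_g, r.M1_g, r.delta_t_d)
                for r in grp.itertuples()
            ]
        )
        if len(d) < 2:
            raise ValueError(f"{sp}: need >= 2 litterbag records for an SE")
        out.append(
            DecompositionEstimate(
                species=Species.parse(sp),
                mean_d=float(np.mean(d)),
                se_d=float(np.std(d, ddof=1) / np.sqrt(len(d))),
                n=len(d),
            )
        )
    return out


def grazing_proportions(a_e: float, a_p: float, a_t: float) -> tuple[float, float]:
    """Proportional excavated (E) and perforated (P) lamina area.

    E = A_E / (A_T - A_P) relates excavation to the non-perforated
    surface; P = A_P / A_T.
    """
    if a_t <= 0:
        raise ValueError("total area must be positive")
    if a_p < 0 or a_p >= a_t:
        raise ValueError("perforated area must satisfy 0 <= A_P < A_T")
    if a_e < 0 or a_e > a_t - a_p:
        raise ValueError("excavated area must satisfy 0 <= A_E <= A_T - A_P")
    return a_e / (a_t - a_p), a_p / a_t


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """OLS line absorbance = slope * concentration + intercept."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct standard concentrations")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return StandardCurve(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
    )


def pg_equivalents(
    sample_abs,
    curve: StandardCurve,
    extract_w_v: float = 0.1,
    dilution: float = 1.0,
) -> float:
    """Phenolic content as % dry mass in phloroglucinol equivalents.

    Triplicate absorbances are averaged before inverting the standard
    curve; the concentration (mg ml^-1) is scaled by the dilution factor
    and referenced to the extraction ratio (default 10% w/v, i.e.
    100 mg dry tissue per ml solvent).  Negative back-calculated
    concentrations clamp to zero with a warning.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope must be non-zero")
    if not 0 < extract_w_v <= 1:
        raise ValueError("extraction ratio must be in (0, 1]")
    mean_abs = float(np.mean(np.asarray(sample_abs, dtype=float)))
    conc = (mean_abs - curve.intercept) / curve.slope * dilution
    if conc < 0:
        warnings.warn("negative PG-equivalent concentration clamped to 0", stacklevel=2)
        conc = 0.0
    tissue_mg_ml = extract_w_v * 1000.0
    return conc / tissue_mg_ml * 100.0


def age_trend(ages, values, model: str = "linear") -> TrendFit:
    """OLS slope (+/- SE) of a response on detrital age (days).

    ``model="log-linear"`` regresses log(response) on age, so the slope
    is an exponential rate (day^-1); it requires positive responses.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct detrital ages")
    if model == "log-linear":
        if np.any(y <= 0):
            raise ValueError("log-linear trend requires positive responses")
        y = np.log(y)
    elif model != "linear":
        raise ValueError(f"unknown trend model {model!r}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        intercept=float(res.params[0]),
        model=model,
        n=len(x),
    )


def decomposition_vs_biochem(d_pct_day, predictor_pct) -> TrendFit:
    """OLS slope of decomposition (% day^-1) on a biochemical predictor (%)."""
    x = np.asarray(predictor_pct, dtype=float)
    y = np.asarray(d_pct_day, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        intercept=float(res.params[0]),
        model="linear",
        n=len(x),
    )
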