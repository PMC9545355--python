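"""Carbon export via distal lamina erosion (hole-punch method).

Each tagged plant carries three punched holes (two on the central digit,
one on an outer digit).  Hole displacement over a month separates
meristematic growth from distal erosion:

    G   = H_F - H_I                     (growth, cm month^-1)
    E_L = L_I + G - L_F                 (length eroded, cm plant^-1 month^-1)
    E_M = E_L * ML_R / delta_t          (dry mass eroded, g plant^-1 day^-1)
    CE  = E_M * carbon_fraction         (g C plant^-1 day^-1)

ML_R (g dry cm^-1) comes from three 5-cm distal segments whose dry mass
is estimated from the outermost segment's own dry:wet ratio (M_R).

Aggregation follows the study's bookkeeping: daily export x days in the
record's month -> mean and SE across plants per month -> seasonal and
annual totals as sums of monthly means, SEs via the variance sum law.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csp import product_ci, variance_sum_se
from .species import Species


SEGMENT_LENGTH_CM = 5.0

#: Meteorological seasons (the study never defines them explicitly).
SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


@dataclass(frozen=True)
class ExportEstimate:
    species: Species
    resolution: str  # monthly | seasonal | annual
    label: str  # month number, season name or year
    mean_ce: float  # g C plant^-1 period^-1
    se_ce: float
    mean_be: float  # g dry plant^-1 period^-1
    se_be: float
    n: int

    def __post_init__(self) -> None:
        if self.mean_ce < 0 or self.se_ce < 0:
            raise ValueError("carbon export and its SE must be non-negative")
        if self.mean_ce > self.mean_be + 1e-9:
            raise ValueError("carbon export cannot exceed biomass export")


def growth(h_i: float, h_f: float, plant_id: str | None = None) -> float:
    """Digit growth G = H_F - H_I (cm month^-1).

    Holes move distally with growth, so H_F < H_I is a measurement
    inconsistency and raises, naming the plant when known.
    """
    if h_f < h_i:
        who = f" (plant {plant_id})" if plant_id else ""
        raise ValueError(f"hole moved proximally: H_F={h_f} < H_I={h_i}{who}")
    return h_f - h_i


def lamina_loss(l_i: float, g: float, l_f: float, plant_id: str | None = None) -> float:
    """Digit length lost to distal erosion, E_L = L_I + G - L_F >= 0."""
    e_l = l_i + g - l_f
    if e_l < 0:
        who = f" (plant {plant_id})" if plant_id else ""
        raise ValueError(
            f"L_F={l_f} exceeds L_I+G={l_i + g}: inconsistent measurement{who}"
        )
    return e_l


def mass_per_length(segment_wet_masses, segment_dry_mass: float) -> tuple[float, float]:
    """(ML_R, M_R) from three 5-cm distal segments, listed outermost first.

    The outermost (first) segment's dry:wet ratio M_R is applied to all
    three segments; ML_R is the mean estimated dry mass per cm of lamina.
    """
    wet = np.asarray(segment_wet_masses, dtype=float)
    if wet.shape != (3,) or np.any(wet <= 0):
        raise ValueError("expected three positive 5-cm segment wet masses")
    if segment_dry_mass <= 0:
        raise ValueError("segment dry mass must be positive")
    if segment_dry_mass > wet[0]:
        raise ValueError("dry mass exceeds wet mass of the outermost segment")
    m_r = segment_dry_mass / wet[0]
    ml_r = float(np.mean(wet * m_r) / SEGMENT_LENGTH_CM)
    return ml_r, m_r


def daily_erosion(e_l: float, ml_r: float, delta_t: float) -> float:
    """Dry-mass erosion rate E_M = E_L * ML_R / delta_t (g plant^-1 day^-1)."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return e_l * ml_r / delta_t


def carbon_export_daily(e_m: float, fraction: float) -> float:
    """Carbon export CE = E_M * carbon fraction (g C plant^-1 day^-1)."""
    if not 0 < fraction <= 1:
        raise ValueError("carbon fraction must be in (0, 1]")
    return e_m * fraction


def match_carbon_fraction(
    fractions: pd.DataFrame,
    species: Species,
    date: pd.Timestamp,
    window_days: float = 45.0,
) -> float:
    """Nearest-dated tissue carbon fraction (proportion) for a species.

    Carbon content is sampled roughly bimonthly; records more than
    ``window_days`` from ``date`` do not count as a match.
    """
    sub = fractions[fractions["species"] == species.value]
    if sub.empty:
        raise ValueError(f"no carbon fractions for {species.value}")
    gaps = (pd.to_datetime(sub["date"]) - date).abs()
    idx = gaps.idxmin()
    if gaps.loc[idx] > pd.Timedelta(days=window_days):
        raise ValueError(
            f"no carbon fraction within {window_days} days of {date.date()} "
            f"for {species.value}"
        )
    return float(sub.loc[idx, "carbon_pct"]) / 100.0


def per_plant_daily_export(
    erosion: pd.DataFrame,
    fractions: pd.DataFrame,
    window_days: float = 45.0,
    min_digits: int = 2,
) -> pd.DataFrame:
    """Per-plant daily biomass and carbon export from raw hole-punch rows.

    ``erosion`` has one row per punched digit (columns per the
    ``erosion.csv`` contract); E_L is averaged over the central and
    outer digit means with equal weight.  Plants with fewer than
    ``min_digits`` surviving digits are dropped with a warning.
    """
    df = erosion.copy()
    df["species"] = df["species"].map(lambda s: Species.parse(s).value)
    df["date_tagged"] = pd.to_datetime(df["date_tagged"])
    df["date_retrieved"] = pd.to_datetime(df["date_retrieved"])

    rows = []
    for (sp, plant), grp in df.groupby(["species", "plant_id"], sort=True):
        if len(grp) < min_digits:
            warnings.warn(
                f"plant {plant} ({sp}): only {len(grp)} punched digit(s) "
                "survived; dropped",
                stacklevel=2,
            )
            continue
        species = Species(sp)
        digit_means = []
        for _, dgrp in grp.groupby("digit"):
            e_ls = [
                lamina_loss(
                    r.L_I_cm,
                    growth(r.H_I_cm, r.H_F_cm, str(plant)),
                    r.L_F_cm,
                    str(plant),
                )
                for r in dgrp.itertuples()
            ]
            digit_means.append(float(np.mean(e_ls)))
        e_l = float(np.mean(digit_means))

        first = grp.iloc[0]
        delta_t = (first["date_retrieved"] - first["date_tagged"]).days
        ml_r, m_r = mass_per_length(
            [first["seg1_wet_g"], first["seg2_wet_g"], first["seg3_wet_g"]],
            first["seg1_dry_g"],
        )
        e_m = daily_erosion(e_l, ml_r, delta_t)
        frac = match_carbon_fraction(
            fractions, species, first["date_retrieved"], window_days
        )
        rows.append(
            {
                "species": sp,
                "plant_id": plant,
                "year": first["date_retrieved"].year,
                "month": first["date_retrieved"].month,
                "E_L_cm": e_l,
                "ML_R_g_cm": ml_r,
                "M_R": m_r,
                "E_M_g_day": e_m,
                "CE_g_C_day": carbon_export_daily(e_m, frac),
            }
        )
    if not rows:
        raise ValueError("no plants with enough surviving digits")
    return pd.DataFrame(rows)


def _days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(int(year), int(month))[1]


def aggregate_export(daily: pd.DataFrame) -> list[ExportEstimate]:
    """Monthly, seasonal and annual export per species, with SEs.

    ``daily`` is the per-plant table from :func:`per_plant_daily_export`.
    Monthly totals are the mean across plants of daily export scaled by
    the actual calendar length of the record's month; seasonal/annual
    totals sum monthly means with variance-sum SEs.  A species must
    cover all 12 months; gaps raise (no imputation).
    """
    out: list[ExportEstimate] = []
    for sp, grp in daily.groupby("species", sort=True):
        species = Species(sp)
        months_present = sorted(grp["month"].unique())
        missing = sorted(set(range(1, 13)) - set(months_present))
        if missing:
            raise ValueError(
                f"{sp}: missing erosion records for months {missing}"
            )
        monthly: dict[int, ExportEstimate] = {}
        for month, mgrp in grp.groupby("month"):
            ndays = _days_in_month(mgrp["year"].iloc[0], month)
            ce = mgrp["CE_g_C_day"].to_numpy() * ndays
            be = mgrp["E_M_g_day"].to_numpy() * ndays
            n = len(ce)
            est = ExportEstimate(
                species=species,
                resolution="monthly",
                label=str(int(month)),
                mean_ce=float(np.mean(ce)),
                se_ce=float(np.std(ce, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                mean_be=float(np.mean(be)),
                se_be=float(np.std(be, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                n=n,
            )
            monthly[int(month)] = est
            out.append(est)
        for season in ("winter", "spring", "summer", "autumn"):
            members = [m for m, s in SEASON_OF_MONTH.items() if s == season]
            ests = [monthly[m] for m in members]
            out.append(
                ExportEstimate(
                    species=species,
                    resolution="seasonal",
                    label=season,
                    mean_ce=float(sum(e.mean_ce for e in ests)),
                    se_ce=variance_sum_se([e.se_ce for e in ests]),
                    mean_be=float(sum(e.mean_be for e in ests)),
                    se_be=variance_sum_se([e.se_be for e in ests]),
                    n=int(sum(e.n for e in ests)),
                )
            )
        ests = list(monthly.values())
        out.append(
            ExportEstimate(
                species=species,
                resolution="annual",
                label="annual",
                mean_ce=float(sum(e.mean_ce for e in ests)),
                se_ce=variance_sum_se([e.se_ce for e in ests]),
                mean_be=float(sum(e.mean_be for e in ests)),
                se_be=variance_sum_se([e.se_be for e in ests]),
                n=int(sum(e.n for e in ests)),
            )
        )
    return out


def estimates_frame(estimates: list[ExportEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [e.species.value for e in estimates],
            "resolution": [e.resolution for e in estimates],
            "label": [e.label for e in estimates],
            "mean_CE": [e.mean_ce for e in estimates],
            "se_CE": [e.se_ce for e in estimates],
            "mean_BE": [e.mean_be for e in estimates],
            "se_BE": [e.se_be for e in estimates],
            "n": [e.n for e in estimates],
        }
    )


def areal_export(
    density: float,
    se_density: float,
    zone_weight: float,
    export: ExportEstimate,
) -> tuple[float, float]:
    """Areal carbon export (g C m^-2 period^-1) and its 95% CI half-width.

    Density is scaled by the proportion of the vertical forest band the
    species occupies; the CI uses the product-of-means rule.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if not 0 < zone_weight <= 1:
        raise ValueError("zone weight must be in (0, 1]")
    return product_ci(
        density * zone_weight, se_density * zone_weight, export.mean_ce, export.se_ce
    )
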