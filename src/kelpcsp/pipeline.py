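"""Stage orchestration: synthetic inputs -> budgets -> CSP -> projections.

Each stage is a pure function of its input tables; ``run_all`` wires
them in dependency order and emits the headline per-species numbers
(annual export, decomposition, time to zero CSP, projected decline
rates, cumulative detrital assimilation) plus every intermediate table.
"""

from __future__ import annotations

import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import assimilation as asm
from . import decomposition as dec
from . import erosion as ero
from . import respirometry as resp
from .csp import CarbonBudget, csp_curve, time_to_zero
from .projection import ThermalThresholds, decline_rate, project_forest, smooth_temperature
from .species import ALL_SPECIES, Species
from .synthetic import GeneratorConfig, gen_all, gen_temperature

log = logging.getLogger(__name__)

SCHEMAS = {
    "erosion": [
        "species", "plant_id", "date_tagged", "date_retrieved", "digit",
        "L_I_cm", "H_I_cm", "L_F_cm", "H_F_cm",
        "seg1_wet_g", "seg2_wet_g", "seg3_wet_g", "seg1_dry_g",
    ],
    "carbon_fraction": ["species", "date", "carbon_pct", "nitrogen_pct"],
    "litterbags": ["species", "experiment", "bag_id", "M0_g", "M1_g", "delta_t_d"],
    "incubations": [
        "species", "detrital_age_d", "mode", "c_S0", "c_S10", "c_S30",
        "c_B0", "c_B10", "c_B30", "V_S_L", "V_B_L", "mass_g", "ambient_par",
    ],
    "biochem": [
        "species", "detrital_age_d", "carbon_pct", "nitrogen_pct",
        "phenolic_pct", "water_pct",
    ],
    "scars": ["species", "sample_id", "A_E_cm2", "A_P_cm2", "A_T_cm2"],
    "density": ["species", "month", "quadrat", "count_m2"],
}

_POSITIVE = {
    "erosion": ["L_I_cm", "L_F_cm", "seg1_wet_g", "seg2_wet_g", "seg3_wet_g", "seg1_dry_g"],
    "litterbags": ["M0_g", "delta_t_d"],
    "incubations": ["V_S_L", "V_B_L", "mass_g"],
    "scars": ["A_T_cm2"],
}


def validate(table: pd.DataFrame, schema_name: str) -> list[str]:
    """Schema report for an input table; empty list means valid."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    report: list[str] = []
    missing = [c for c in SCHEMAS[schema_name] if c not in table.columns]
    if missing:
        report.append(f"missing columns: {missing}")
        return report
    if table.empty:
        report.append("table has no rows")
        return report
    for col in _POSITIVE.get(schema_name, []):
        bad = table.index[table[col] <= 0].tolist()
        for i in bad:
            report.append(f"row {i}: {col}={table.loc[i, col]} must be positive")
    if "species" in table.columns:
        for i, v in table["species"].items():
            try:
                Species.parse(v)
            except ValueError:
                report.append(f"row {i}: unknown species {v!r}")
    return report


def load_config(path: "str | Path") -> dict:
    """Read the plain-text TOML run configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


# ---------------------------------------------------------------------------
# stages


def stage_export(erosion_csv: pd.DataFrame, fractions: pd.DataFrame):
    daily = ero.per_plant_daily_export(erosion_csv, fractions)
    estimates = ero.aggregate_export(daily)
    return daily, ero.estimates_frame(estimates)


def stage_decompose(litterbags: pd.DataFrame) -> pd.DataFrame:
    ests = dec.pool_rates(litterbags)
    return pd.DataFrame(
        {
            "species": [e.species.value for e in ests],
            "mean_D_day": [e.mean_d for e in ests],
            "se_D_day": [e.se_d for e in ests],
            "n": [e.n for e in ests],
        }
    )


def stage_biochem(biochem: pd.DataFrame) -> pd.DataFrame:
    """Detrital-age trends per species plus the pooled C:N rate."""
    rows = []
    for sp, grp in biochem.groupby("species", sort=True):
        phen = dec.age_trend(grp["detrital_age_d"], grp["phenolic_pct"], "linear")
        carb = dec.age_trend(grp["detrital_age_d"], grp["carbon_pct"], "linear")
        rows.append(
            {
                "species": sp,
                "phenolic_slope_pct_day": phen.slope,
                "phenolic_slope_se": phen.se,
                "carbon_slope_pct_day": carb.slope,
                "carbon_slope_se": carb.se,
            }
        )
    cn = dec.age_trend(
        biochem["detrital_age_d"],
        biochem["carbon_pct"] / biochem["nitrogen_pct"],
        "log-linear",
    )
    out = pd.DataFrame(rows)
    out["cn_rate_day_pooled"] = cn.slope
    out["cn_rate_se_pooled"] = cn.se
    return out


def stage_respire(
    incubations: pd.DataFrame, m_r_by_species: dict[str, float]
) -> pd.DataFrame:
    return resp.process_incubations(incubations, m_r_by_species)


def gpp_trends(production: pd.DataFrame, alpha_z: float = 1.959964) -> pd.DataFrame:
    """Per-species gross-assimilation level/decline for the detrital phase.

    A species keeps its fitted linear decline only when the slope is
    distinguishable from zero at the 95% level; otherwise its detrital
    GPP is treated as constant at the grand mean.
    """
    rows = []
    for sp, grp in production.groupby("species", sort=True):
        fit = dec.age_trend(grp["detrital_age_d"], grp["CA_gross_gC_g_h"], "linear")
        if abs(fit.slope) > alpha_z * fit.se:
            rows.append({"species": sp, "gpp_intercept": fit.intercept, "gpp_slope": fit.slope})
        else:
            rows.append(
                {
                    "species": sp,
                    "gpp_intercept": float(grp["CA_gross_gC_g_h"].mean()),
                    "gpp_slope": 0.0,
                }
            )
    return pd.DataFrame(rows)


def build_budgets(
    density: pd.DataFrame,
    export_estimates: pd.DataFrame,
    decomposition_estimates: pd.DataFrame,
) -> dict[Species, CarbonBudget]:
    """Zone-weighted annual carbon budgets per species."""
    budgets = {}
    annual = export_estimates[export_estimates["resolution"] == "annual"]
    for sp in ALL_SPECIES:
        counts = density.loc[density["species"] == sp.value, "count_m2"].to_numpy(float)
        n_mean = counts.mean() * sp.zone_weight
        n_se = counts.std(ddof=1) / np.sqrt(len(counts)) * sp.zone_weight
        exp_row = annual[annual["species"] == sp.value].iloc[0]
        dec_row = decomposition_estimates[
            decomposition_estimates["species"] == sp.value
        ].iloc[0]
        budgets[sp] = CarbonBudget(
            species=sp,
            n_density=float(n_mean),
            se_n=float(n_se),
            ce=float(exp_row["mean_CE"]),
            se_ce=float(exp_row["se_CE"]),
            d=float(dec_row["mean_D_day"]),
            se_d=float(dec_row["se_D_day"]),
            period="annual",
            be=float(exp_row["mean_BE"]),
            se_be=float(exp_row["se_BE"]),
        )
    return budgets


def stage_csp(budgets: dict[Species, CarbonBudget], max_age: int = 180) -> pd.DataFrame:
    ages = np.arange(0, max_age + 1, dtype=float)
    frames = []
    for sp, b in budgets.items():
        curve = csp_curve(b, ages)
        frames.append(
            pd.DataFrame(
                {
                    "species": sp.value,
                    "age_d": curve.ages,
                    "CSP_gC_m2_yr": curve.csp,
                    "ci_low": curve.ci_low,
                    "ci_high": curve.ci_high,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_all(
    cfg: GeneratorConfig | None = None,
    seed: int = 1,
    out_dir: "str | Path | None" = None,
    sink_depth: float = 30.0,
    sink_distance: float = 4000.0,
    horizon_days: float = 50.0,
    scenarios: tuple = ("RCP2.6", "RCP6.0", "RCP8.5"),
) -> dict:
    """Full synthetic pipeline run; returns all tables and a summary.

    ``sink_depth``/``sink_distance`` give the local carbon-sink geometry
    for the assimilation stage; ``horizon_days`` the sequestration
    horizon for projected CSP.
    """
    cfg = cfg or GeneratorConfig(seed=seed)
    data = gen_all(cfg)
    for name, table in data.items():
        problems = validate(table, name)
        if problems:
            raise ValueError(f"{name}: schema violations: {problems[:5]}")

    daily, export_est = stage_export(data["erosion"], data["carbon_fraction"])
    decomp = stage_decompose(data["litterbags"])
    biochem_trends = stage_biochem(data["biochem"])
    m_r = {sp.value: cfg.species[sp].m_r for sp in ALL_SPECIES}
    production = stage_respire(data["incubations"], m_r)
    budgets = build_budgets(data["density"], export_est, decomp)
    curves = stage_csp(budgets)

    # temperature-driven projection
    hist = smooth_temperature(gen_temperature(cfg, "historical"))
    i2016 = int(np.where(hist.years == cfg.year)[0][0])
    thresholds = ThermalThresholds(
        t_upper=cfg.t_upper,
        t_min2016=float(hist.t_min[i2016]),
        t_max2016=float(hist.t_max[i2016]),
    )
    projections = {}
    for scen in scenarios:
        temps = smooth_temperature(gen_temperature(cfg, scen))
        projections[scen] = project_forest(
            budgets, temps, thresholds, horizon_t=horizon_days
        )
    projection = pd.concat(projections.values(), ignore_index=True)

    # detrital assimilation along the sinking trajectory
    env = asm.LightEnvironment()
    traj = asm.DetritalTrajectory(sink_depth=sink_depth, sink_distance=sink_distance)
    trends = gpp_trends(production)
    ca_rows = []
    for sp, b in budgets.items():
        tr = trends[trends["species"] == sp.value].iloc[0]
        ca = asm.cumulative_assimilation(
            b, env, traj, tr["gpp_intercept"], tr["gpp_slope"],
            t=int(traj.travel_time),
        )
        ca_rows.append(
            pd.DataFrame(
                {
                    "species": sp.value,
                    "age_d": np.arange(1, len(ca) + 1),
                    "CA_cum_gC_m2": ca,
                }
            )
        )
    ca_table = pd.concat(ca_rows, ignore_index=True)

    summary_rows = []
    for sp, b in budgets.items():
        tz, tz_se = time_to_zero(b.d, b.se_d)
        summary_rows.append(
            {
                "species": sp.value,
                "density_m2": b.n_density,
                "CE_annual_gC_plant": b.ce,
                "areal_CE_gC_m2_yr": b.n_density * b.ce,
                "D_pct_day": b.d * 100,
                "D_se_pct_day": b.se_d * 100,
                "t_zero_d": round(tz) if np.isfinite(tz) else np.inf,
                "t_zero_se_d": tz_se,
                "CA_50d_gC_m2": float(
                    ca_table.loc[ca_table["species"] == sp.value, "CA_cum_gC_m2"].iloc[-1]
                ),
            }
        )
    summary = pd.DataFrame(summary_rows)

    rcp85 = projections.get("RCP8.5")
    rates = {}
    if rcp85 is not None:
        rates["past_decline_pct_yr"] = decline_rate(rcp85, 1900, int(cfg.year))
        rates["rcp85_decline_pct_yr"] = decline_rate(rcp85, 2020, 2100)

    results = {
        "inputs": data,
        "daily_export": daily,
        "export_estimates": export_est,
        "decomposition": decomp,
        "biochem_trends": biochem_trends,
        "production": production,
        "budgets": budgets,
        "csp_curves": curves,
        "projection": projection,
        "assimilation": ca_table,
        "summary": summary,
        "decline_rates": rates,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in data.items():
            table.to_csv(out / f"{name}.csv", index=False)
        export_est.to_csv(out / "export_estimates.csv", index=False)
        decomp.to_csv(out / "decomposition.csv", index=False)
        biochem_trends.to_csv(out / "biochem_trends.csv", index=False)
        production.to_csv(out / "production.csv", index=False)
        curves.to_csv(out / "csp_curves.csv", index=False)
        projection.to_csv(out / "projection.csv", index=False)
        ca_table.to_csv(out / "assimilation.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    return results
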