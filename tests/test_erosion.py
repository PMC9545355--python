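"""Hole-punch erosion: per-digit arithmetic through areal export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelpcsp import erosion as ero
from kelpcsp.species import Species
from kelpcsp.synthetic import GeneratorConfig, gen_carbon_fractions, gen_erosion


@pytest.mark.parametrize(
    "h_i,h_f,expected",
    [(5, 5, 0), (5, 17, 12), (2.5, 15, 12.5)],
)
def test_growth_is_hole_displacement(h_i, h_f, expected):
    assert ero.growth(h_i, h_f) == pytest.approx(expected)


def test_growth_rejects_proximal_hole_movement():
    with pytest.raises(ValueError, match="plant-7"):
        ero.growth(10, 5, plant_id="plant-7")


@pytest.mark.parametrize(
    "l_i,g,l_f,expected",
    [(100, 10, 110, 0), (100, 10, 105, 5)],
)
def test_lamina_loss(l_i, g, l_f, expected):
    assert ero.lamina_loss(l_i, g, l_f) == pytest.approx(expected)


def test_lamina_loss_rejects_impossible_final_length():
    with pytest.raises(ValueError, match="inconsistent"):
        ero.lamina_loss(100, 5, 110)


@pytest.mark.parametrize(
    "wet,dry,ml_r,m_r",
    [
        ((2.0, 2.0, 2.0), 0.3, 0.06, 0.15),
        ((1.0, 2.0, 3.0), 0.3, 0.12, 0.3),  # outermost segment listed first
        ((5.0, 5.0, 5.0), 5.0, 1.0, 1.0),
    ],
)
def test_mass_per_length_applies_outermost_dry_wet_ratio(wet, dry, ml_r, m_r):
    got_ml_r, got_m_r = ero.mass_per_length(wet, dry)
    assert got_ml_r == pytest.approx(ml_r)
    assert got_m_r == pytest.approx(m_r)


def test_mass_per_length_rejects_dry_above_wet():
    with pytest.raises(ValueError, match="dry mass exceeds"):
        ero.mass_per_length((2.0, 2.0, 2.0), 2.5)


@pytest.mark.parametrize(
    "e_l,ml_r,dt,expected",
    [(5, 0.2, 30, 1 / 30), (0, 0.2, 30, 0), (30, 0.1, 30, 0.1)],
)
def test_daily_erosion(e_l, ml_r, dt, expected):
    assert ero.daily_erosion(e_l, ml_r, dt) == pytest.approx(expected)


@pytest.mark.parametrize(
    "e_m,frac,expected", [(0.1, 0.30, 0.03), (0.25, 1.0, 0.25), (0.0, 0.3, 0.0)]
)
def test_carbon_export_is_fraction_of_dry_erosion(e_m, frac, expected):
    assert ero.carbon_export_daily(e_m, frac) == pytest.approx(expected)


@given(
    e_l=st.floats(0, 50), ml_r=st.floats(0.01, 2), frac=st.floats(0.05, 0.5),
    scale=st.floats(0.1, 10),
)
@settings(max_examples=50, deadline=None)
def test_export_scales_linearly_in_mass_ratio_and_fraction(e_l, ml_r, frac, scale):
    base = ero.carbon_export_daily(ero.daily_erosion(e_l, ml_r, 30), frac)
    assert base >= 0
    scaled = ero.carbon_export_daily(ero.daily_erosion(e_l, ml_r * scale, 30), frac)
    assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)


def _daily_frame(per_plant_ce, year=2016):
    rows = []
    for month, values in per_plant_ce.items():
        for i, ce in enumerate(values):
            rows.append(
                {
                    "species": "digitata",
                    "plant_id": f"p{month}-{i}",
                    "year": year,
                    "month": month,
                    "E_L_cm": 1.0,
                    "ML_R_g_cm": 1.0,
                    "M_R": 0.15,
                    "E_M_g_day": ce * 4,  # biomass export >= carbon export
                    "CE_g_C_day": ce,
                }
            )
    return pd.DataFrame(rows)


def test_monthly_aggregate_scales_by_calendar_days():
    daily = _daily_frame({m: [0.1, 0.1, 0.1] for m in range(1, 13)})
    ests = {
        (e.resolution, e.label): e for e in ero.aggregate_export(daily)
    }
    april = ests[("monthly", "4")]
    assert april.mean_ce == pytest.approx(3.0)  # 0.1 * 30 days
    assert april.se_ce == 0.0
    june = ests[("monthly", "6")]
    assert june.mean_ce == pytest.approx(3.0)


def test_seasonal_se_follows_variance_sum_law():
    # two spring months with distinct plant spreads; third month zero
    daily = _daily_frame(
        {
            **{m: [0.1, 0.1] for m in range(1, 13)},
            3: [0.2, 0.0968],  # mean 3.0 +- known SE over 31 days
            4: [0.2, 0.0667],
        }
    )
    ests = {(e.resolution, e.label): e for e in ero.aggregate_export(daily)}
    spring = ests[("seasonal", "spring")]
    m3, m4, m5 = ests[("monthly", "3")], ests[("monthly", "4")], ests[("monthly", "5")]
    assert spring.mean_ce == pytest.approx(m3.mean_ce + m4.mean_ce + m5.mean_ce)
    assert spring.se_ce == pytest.approx(
        np.sqrt(m3.se_ce**2 + m4.se_ce**2 + m5.se_ce**2)
    )


def test_annual_equals_sum_of_seasons():
    rng = np.random.default_rng(7)
    daily = _daily_frame({m: rng.uniform(0.02, 0.3, size=5) for m in range(1, 13)})
    ests = ero.aggregate_export(daily)
    annual = next(e for e in ests if e.resolution == "annual")
    seasons = [e for e in ests if e.resolution == "seasonal"]
    assert annual.mean_ce == pytest.approx(sum(e.mean_ce for e in seasons))
    assert annual.se_ce == pytest.approx(
        np.sqrt(sum(e.se_ce**2 for e in seasons))
    )


def test_missing_months_raise_listing_gaps():
    daily = _daily_frame({m: [0.1] * 3 for m in (1, 2, 3)})
    with pytest.raises(ValueError, match=r"\[4, 5, 6"):
        ero.aggregate_export(daily)


def test_areal_export_zero_error_case():
    est = ero.ExportEstimate(
        Species.DIGITATA, "annual", "annual", 90.0, 0.0, 300.0, 0.0, 10
    )
    mean, half = ero.areal_export(1.0, 0.0, 1.0, est)
    assert mean == pytest.approx(90.0)
    assert half == 0.0


def test_areal_export_matches_goodman_monte_carlo():
    est = ero.ExportEstimate(
        Species.DIGITATA, "annual", "annual", 100.0, 10.0, 300.0, 0.0, 10
    )
    mean, half = ero.areal_export(2.0, 0.1, 0.5, est)
    assert mean == pytest.approx(100.0)
    rng = np.random.default_rng(0)
    prod = rng.normal(1.0, 0.05, 10**6) * rng.normal(100.0, 10.0, 10**6)
    assert half / 1.959964 == pytest.approx(prod.std(), rel=0.01)


def test_pipeline_recovers_configured_export_within_2_se(cfg):
    truth = {sp: cfg.species[sp].export_daily * 365.0 for sp in cfg.species}
    daily = ero.per_plant_daily_export(
        gen_erosion(cfg, n_plants_per_month=10), gen_carbon_fractions(cfg)
    )
    for est in ero.aggregate_export(daily):
        if est.resolution != "annual":
            continue
        t = truth[est.species]
        # carbon-fraction sampling noise adds a little extra spread
        assert abs(est.mean_ce - t) < max(2 * est.se_ce, 0.1 * t)


def test_plants_with_single_digit_are_dropped(cfg):
    df = gen_erosion(cfg, n_plants_per_month=2)
    victim = df["plant_id"].iloc[0]
    df = df[~((df["plant_id"] == victim) & (df["digit"] == "central"))]
    with pytest.warns(UserWarning, match="dropped"):
        daily = ero.per_plant_daily_export(df, gen_carbon_fractions(cfg))
    assert victim not in set(daily["plant_id"])
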