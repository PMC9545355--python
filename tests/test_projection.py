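"""LOESS smoothing, thermal density scaling and forest projection."""

import numpy as np
import pytest

from kelpcsp.csp import CarbonBudget
from kelpcsp.projection import (
    TemperatureSeries,
    ThermalThresholds,
    decline_rate,
    density_cold,
    density_warm,
    loess,
    project_forest,
    smooth_temperature,
)
from kelpcsp.species import Species
from kelpcsp.synthetic import GeneratorConfig, gen_temperature

TH = ThermalThresholds(t_upper=19.0, t_min2016=9.9, t_max2016=17.3)


def test_loess_reproduces_line_exactly():
    x = np.arange(20, dtype=float)
    y = 2.0 + 0.3 * x
    assert loess(x, y) == pytest.approx(y, rel=1e-9)


def test_loess_reproduces_quadratic_exactly():
    x = np.linspace(0, 10, 25)
    y = 1.0 - 0.5 * x + 0.07 * x**2
    assert np.max(np.abs(loess(x, y) - y) / np.abs(y).max()) < 1e-6


def test_loess_reduces_roughness_of_noisy_signal():
    rng = np.random.default_rng(11)
    x = np.arange(60, dtype=float)
    y = 0.05 * x + np.sin(x / 6) + rng.normal(0, 0.4, 60)
    smooth = loess(x, y)
    rough = lambda v: np.sum(np.diff(v) ** 2)  # noqa: E731
    assert rough(smooth) < rough(y)


def test_smooth_temperature_needs_history():
    ts = TemperatureSeries(
        "historical",
        np.arange(2000, 2005),
        np.full(5, 9.0),
        np.full(5, 12.0),
        np.full(5, 16.0),
    )
    with pytest.raises(ValueError, match=">= 10 years"):
        smooth_temperature(ts)


def test_temperature_series_validates_ordering():
    with pytest.raises(ValueError, match="t_min <= t_mean"):
        TemperatureSeries(
            "x", np.array([2000, 2001]), np.array([10.0, 10.0]),
            np.array([9.0, 12.0]), np.array([16.0, 16.0]),
        )


@pytest.mark.parametrize(
    "t_max,expected",
    [(17.3, 8.0), (19.0, 0.0), (18.15, 4.0), (21.0, 0.0)],
)
def test_density_cold_anchors_and_floor(t_max, expected):
    assert density_cold(8.0, TH, t_max) == pytest.approx(expected)


@pytest.mark.parametrize(
    "t_min,expected",
    [(9.9, 4.0), (9.53, 0.0), (9.0, 0.0), (12.0, 12.0)],  # last one hits the cap
)
def test_density_warm_anchors_floor_and_cap(t_min, expected):
    assert density_warm(4.0, TH, t_min, cap=12.0) == pytest.approx(expected)


def test_density_functions_are_linear_between_floor_and_cap():
    t = np.linspace(17.3, 19.0, 9)
    n = density_cold(8.0, TH, t)
    assert np.allclose(np.diff(n, 2), 0, atol=1e-9)


def _budgets(d_warm=0.0154):
    return {
        Species.DIGITATA: CarbonBudget(Species.DIGITATA, 0.9, 0.05, 23.0, 1.0, 0.0093, 0.001),
        Species.HYPERBOREA: CarbonBudget(Species.HYPERBOREA, 6.7, 0.3, 39.0, 1.5, 0.006, 0.001),
        Species.OCHROLEUCA: CarbonBudget(Species.OCHROLEUCA, 3.0, 0.2, 40.0, 1.8, d_warm, 0.002),
    }


def test_constant_reference_temperatures_give_flat_projection():
    years = np.arange(2000, 2021)
    temps = TemperatureSeries(
        "flat", years, np.full(21, TH.t_min2016), np.full(21, 13.0),
        np.full(21, TH.t_max2016),
    )
    proj = project_forest(_budgets(), temps, TH)
    b = _budgets()
    expected = sum(
        bb.n_density * bb.ce * (1 - 50 * bb.d) for bb in b.values()
    )
    assert np.allclose(proj["CSP_forest"], expected)
    assert np.allclose(np.diff(proj["CSP_forest"]), 0)


def test_cold_species_csp_hits_zero_when_ramp_reaches_upper_limit():
    years = np.arange(2000, 2051)
    t_max = np.linspace(TH.t_max2016, 19.0, len(years))
    temps = TemperatureSeries(
        "ramp", years, np.full(len(years), 9.9), t_max - 2, t_max
    )
    proj = project_forest(_budgets(), temps, TH)
    assert proj["CSP_digitata"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
    assert proj["CSP_hyperborea"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
    assert proj["CSP_ochroleuca"].iloc[-1] > 0


def test_forest_csp_never_exceeds_forest_export():
    cfg = GeneratorConfig(seed=3)
    temps = smooth_temperature(gen_temperature(cfg, "RCP8.5"))
    proj = project_forest(_budgets(), temps, TH)
    assert (proj["CSP_forest"] <= proj["CE_forest"] + 1e-9).all()


def test_warm_replacement_with_faster_decay_reduces_forest_csp():
    """Replacing cold density 1:1 by a faster-decomposing warm species
    at equal export strictly lowers forest CSP — the compositional
    mechanism behind projected CSP decline."""
    th = TH
    years = np.arange(2016, 2101)
    # warm at same CE as cold, but faster D
    cold = CarbonBudget(Species.HYPERBOREA, 6.0, 0.0, 40.0, 0.0, 0.006, 0.0)
    warm = CarbonBudget(Species.OCHROLEUCA, 6.0, 0.0, 40.0, 0.0, 0.0154, 0.0)
    dig = CarbonBudget(Species.DIGITATA, 0.0, 0.0, 1.0, 0.0, 0.0093, 0.0)
    t_max = np.linspace(th.t_max2016, 19.0, len(years))
    t_min = np.linspace(th.t_min2016, 11.0, len(years))
    temps = TemperatureSeries("ramp", years, t_min, (t_min + t_max) / 2, t_max)
    proj = project_forest({Species.DIGITATA: dig, Species.HYPERBOREA: cold,
                           Species.OCHROLEUCA: warm}, temps, th, warm_cap=6.0)
    # export replaced nearly 1:1 late in the ramp, CSP strictly down
    assert proj["CSP_forest"].iloc[-1] < proj["CSP_forest"].iloc[0]
    drop_ce = 1 - proj["CE_forest"].iloc[-1] / proj["CE_forest"].iloc[0]
    drop_csp = 1 - proj["CSP_forest"].iloc[-1] / proj["CSP_forest"].iloc[0]
    assert drop_csp > drop_ce


def test_decline_rate_flat_halving_and_ratio():
    years = np.arange(2000, 2101)
    flat = {"year": years, "CSP_forest": np.full(101, 5.0)}
    import pandas as pd

    assert decline_rate(pd.DataFrame(flat), 2000, 2100) == pytest.approx(0.0)
    halving = pd.DataFrame(
        {"year": years, "CSP_forest": 5.0 * 0.5 ** ((years - 2000) / 100)}
    )
    assert decline_rate(halving, 2000, 2100) == pytest.approx(0.691, abs=1e-3)
    with pytest.raises(ValueError):
        decline_rate(pd.DataFrame({"year": [2000], "CSP_forest": [1.0]}), 1999, 2001)
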