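"""Litterbag decomposition, grazing scars, phenolics, age trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelpcsp import decomposition as dec
from kelpcsp.species import Species
from kelpcsp.synthetic import GeneratorConfig, gen_biochem, gen_litterbags


@pytest.mark.parametrize(
    "m0,m1,dt,expected",
    [
        (20, 20, 32, 0.0),
        (20, 10.144, 32, 0.0154),
        (20, 22, 25, -0.004),  # detrital growth
    ],
)
def test_decomposition_rate(m0, m1, dt, expected):
    assert dec.decomposition_rate(m0, m1, dt) == pytest.approx(expected)


@given(
    m0=st.floats(1, 200),
    frac=st.floats(0, 1.5),
    dt=st.floats(1, 60),
    scale=st.floats(0.01, 100),
)
@settings(max_examples=50, deadline=None)
def test_rate_invariant_to_mass_units(m0, frac, dt, scale):
    d1 = dec.decomposition_rate(m0, m0 * frac, dt)
    d2 = dec.decomposition_rate(m0 * scale, m0 * frac * scale, dt)
    assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)


def test_pool_rates_mean_se_and_pooling_consistency():
    import pandas as pd

    recs = pd.DataFrame(
        {
            "species": ["digitata"] * 4,
            "experiment": ["a", "a", "b", "b"],
            "bag_id": list("wxyz"),
            "M0_g": [20.0] * 4,
            "M1_g": [14.0, 15.0, 16.0, 17.0],
            "delta_t_d": [30.0] * 4,
        }
    )
    (est,) = dec.pool_rates(recs)
    d = (20 - np.array([14, 15, 16, 17])) / (20 * 30)
    assert est.mean_d == pytest.approx(d.mean())
    assert est.se_d == pytest.approx(d.std(ddof=1) / 2)
    assert est.n == 4
    # pooled mean equals the n-weighted mean of per-experiment pools
    per_exp = [
        dec.pool_rates(recs[recs["experiment"] == e])[0] for e in ("a", "b")
    ]
    weighted = sum(p.mean_d * p.n for p in per_exp) / sum(p.n for p in per_exp)
    assert est.mean_d == pytest.approx(weighted)


def test_pool_rates_single_record_has_no_se():
    import pandas as pd

    rec = pd.DataFrame(
        {
            "species": ["digitata"],
            "experiment": ["a"],
            "bag_id": ["x"],
            "M0_g": [20.0],
            "M1_g": [15.0],
            "delta_t_d": [30.0],
        }
    )
    with pytest.raises(ValueError, match=">= 2"):
        dec.pool_rates(rec)


def test_litterbag_estimator_recovers_truth(cfg):
    bags = gen_litterbags(cfg)
    for est in dec.pool_rates(bags):
        truth = cfg.species[est.species].d_true
        assert abs(est.mean_d - truth) < 2 * est.se_d


@pytest.mark.parametrize(
    "a_e,a_p,a_t,e,p",
    [
        (0, 0, 10, 0.0, 0.0),
        (2, 1, 10, 2 / 9, 0.1),
        (9, 1, 10, 1.0, 0.1),
    ],
)
def test_grazing_proportions(a_e, a_p, a_t, e, p):
    got_e, got_p = dec.grazing_proportions(a_e, a_p, a_t)
    assert got_e == pytest.approx(e)
    assert got_p == pytest.approx(p)


@given(
    a_t=st.floats(1, 1000),
    pf=st.floats(0, 0.95),
    ef=st.floats(0, 0.95),
    scale=st.floats(0.01, 100),
)
@settings(max_examples=50, deadline=None)
def test_grazing_invariant_to_area_units(a_t, pf, ef, scale):
    a_p = a_t * pf
    a_e = (a_t - a_p) * ef
    base = dec.grazing_proportions(a_e, a_p, a_t)
    scaled = dec.grazing_proportions(a_e * scale, a_p * scale, a_t * scale)
    assert base == pytest.approx(scaled, rel=1e-9, abs=1e-12)


def test_grazing_rejects_full_perforation():
    with pytest.raises(ValueError):
        dec.grazing_proportions(0, 10, 10)


def test_standard_curve_exact_and_noisy_fit(rng):
    curve = dec.fit_standard_curve([1, 2, 3], [1, 2, 3])
    assert (curve.slope, curve.intercept, curve.r_squared) == pytest.approx((1, 0, 1))

    conc = np.array([0.05, 0.1, 0.25, 0.5, 0.75, 1.0])
    curve = dec.fit_standard_curve(conc, 2 * conc + 0.01)
    assert curve.slope == pytest.approx(2.0)
    assert curve.intercept == pytest.approx(0.01)

    noisy = dec.fit_standard_curve(conc, 2 * conc + 0.01 + rng.normal(0, 0.01, 6))
    # OLS slope SE for this design, sigma=0.01
    se = 0.01 / (conc.std(ddof=0) * np.sqrt(6))
    assert abs(noisy.slope - 2.0) < 3 * se


def test_standard_curve_rejects_degenerate_concentrations():
    with pytest.raises(ValueError):
        dec.fit_standard_curve([0.5, 0.5, 0.5], [1, 2, 3])


def test_pg_equivalents_unit_chain():
    curve = dec.StandardCurve(slope=2.0, intercept=0.0, r_squared=1.0)
    # 0.2 AU -> 0.1 mg/ml against 100 mg/ml of tissue -> 0.1%
    assert dec.pg_equivalents(0.2, curve) == pytest.approx(0.1)
    assert dec.pg_equivalents([0.2, 0.2, 0.2], curve) == pytest.approx(0.1)
    assert dec.pg_equivalents(0.4, curve, dilution=2.0) == pytest.approx(0.4)
    curve2 = dec.StandardCurve(slope=2.0, intercept=0.05, r_squared=1.0)
    assert dec.pg_equivalents(0.05, curve2) == 0.0  # at the intercept
    with pytest.warns(UserWarning, match="clamped"):
        assert dec.pg_equivalents(0.0, curve2) == 0.0


def test_age_trend_flat_and_oracle():
    ages = [0, 10, 20, 30]
    flat = dec.age_trend(ages, [1.0, 1.0, 1.0, 1.0])
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    # exact line reproduced
    fit = dec.age_trend([0, 15, 30], [1.0, 2.5, 4.0])
    assert fit.slope == pytest.approx(0.1)
    # brute-force normal equations on a random small instance
    rng = np.random.default_rng(3)
    x, y = rng.uniform(0, 32, 9), rng.normal(0, 1, 9)
    X = np.column_stack([np.ones(9), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    fit = dec.age_trend(x, y)
    assert fit.slope == pytest.approx(beta[1])
    assert fit.intercept == pytest.approx(beta[0])


def test_age_trend_log_linear_requires_positive():
    with pytest.raises(ValueError, match="positive"):
        dec.age_trend([0, 10, 20], [1.0, -1.0, 2.0], "log-linear")


def test_phenolic_and_cn_trends_recovered(cfg):
    bio = gen_biochem(cfg, species=Species.HYPERBOREA, n=27)
    fit = dec.age_trend(bio["detrital_age_d"], bio["phenolic_pct"])
    assert abs(fit.slope - 0.03) < 2 * fit.se

    pooled = gen_biochem(cfg, n=27)
    cn = dec.age_trend(
        pooled["detrital_age_d"],
        pooled["carbon_pct"] / pooled["nitrogen_pct"],
        "log-linear",
    )
    assert abs(cn.slope + 0.005) < 2 * cn.se


def test_decomposition_vs_biochem_slope_recovery(rng):
    # known linear dependence of decomposition on phenolic content
    phen = rng.uniform(0.1, 1.2, 40)
    d = 1.8 - 1.05 * phen + rng.normal(0, 0.1, 40)
    fit = dec.decomposition_vs_biochem(d, phen)
    assert abs(fit.slope + 1.05) < 2 * fit.se

    carbon = rng.uniform(20, 31, 40)
    d = 3.0 - 0.08 * carbon + rng.normal(0, 0.05, 40)
    fit = dec.decomposition_vs_biochem(d, carbon)
    assert abs(fit.slope + 0.08) < 2 * fit.se
    with pytest.raises(ValueError):
        dec.decomposition_vs_biochem([1.0, 2.0], [1.0, 2.0])
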