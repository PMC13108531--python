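"""Scaling, bootstrap OLS, VIF, spatial weights, SAR, beta regression,
crowding indices, neighborhood designs and mixed-model fitting."""

import numpy as np
import pandas as pd
import pytest

from foreststab import regression as rg
from foreststab.layout import QuadratLayout


def test_zscale_and_log():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 10.0, 100.0]})
    out, rec = rg.zscale_and_log(df, log_columns=["b"], scale_columns=["a"])
    assert np.allclose(out["a"], [-1, 0, 1])
    assert np.allclose(out["b"], np.log([1, 10, 100]))
    assert rec["scale"]["a"] == (2.0, 1.0)
    with pytest.raises(ValueError, match="zero-variance"):
        rg.zscale_and_log(pd.DataFrame({"c": [1.0, 1.0]}), scale_columns=["c"])
    with pytest.raises(ValueError, match="non-positive"):
        rg.zscale_and_log(pd.DataFrame({"c": [0.0, 1.0]}), log_columns=["c"])


def test_bootstrap_degenerate_exact_fit(rng):
    x = rng.normal(0, 1, 50)
    X = np.column_stack([np.ones(50), x])
    y = 2.0 * x
    res = rg.ols_bootstrap(X, y, n_boot=200, seed=0, names=["int", "slope"])
    row = res.set_index("term").loc["slope"]
    assert row.lo95 == pytest.approx(2.0, abs=1e-10)
    assert row.hi95 == pytest.approx(2.0, abs=1e-10)
    assert row.significant


def test_bootstrap_covers_known_slope():
    hits = 0
    for s in range(20):
        r = np.random.default_rng(s)
        x = r.normal(0, 1, 200)
        y = 0.5 * x + r.normal(0, 1, 200)
        res = rg.ols_bootstrap(np.column_stack([np.ones(200), x]), y,
                               n_boot=500, seed=s, names=["int", "slope"])
        row = res.set_index("term").loc["slope"]
        hits += row.lo95 <= 0.5 <= row.hi95
    assert hits >= 18


def test_vif_closed_forms(rng):
    n = 2000
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n)
    v = rg.vif(np.column_stack([a, b]))
    assert np.allclose(v, 1.0, atol=0.05)       # orthogonal columns
    c = 0.9 * a + np.sqrt(1 - 0.81) * b          # corr(a, c) = 0.9
    v2 = rg.vif(np.column_stack([a, c]), names=["a", "c"])
    assert v2["a"] == pytest.approx(1 / (1 - 0.81), rel=0.1)
    v3 = rg.vif(np.column_stack([a, a]))         # duplicated column
    assert np.isinf(v3).all()


@pytest.mark.parametrize("cell,expected", [
    ((5, 5), 8),   # interior: 4 edge + 4 corner neighbours
    ((0, 0), 3),   # corner
    ((0, 5), 5),   # edge, non-corner
])
def test_queen_neighbour_counts(cell, expected):
    w = rg.queen_weights((10, 10), row_standardize=False)
    i = cell[0] * 10 + cell[1]
    assert w.adjacency[i].sum() == expected


def test_row_standardized_rows_sum_to_one():
    w = rg.queen_weights((6, 7))
    rows = np.asarray(w.W.sum(axis=1)).ravel()
    assert np.allclose(rows, 1.0)
    A = w.adjacency.toarray()
    assert np.allclose(A, A.T) and np.allclose(np.diag(A), 0)


def test_sar_reduces_to_ols_with_lambda_fixed_zero(rng):
    w = rg.queen_weights((8, 8))
    X = np.column_stack([np.ones(64), rng.normal(size=64)])
    y = X @ np.array([1.0, 2.0]) + rng.normal(size=64)
    fit = rg.sar_error_fit(X, y, w, fix_lam=0.0)
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.abs(fit.beta - ols).max() < 1e-6
    assert fit.aic == pytest.approx(2 * (X.shape[1] + 2) - 2 * fit.loglik)


def test_sar_beats_ols_under_strong_spatial_error(rng):
    w = rg.queen_weights((12, 12))
    n = 144
    W = w.W.toarray()
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    u = np.linalg.solve(np.eye(n) - 0.85 * W, rng.normal(0, 0.5, n))
    y = X @ np.array([1.0, 0.5]) + u
    sar = rg.sar_error_fit(X, y, w)
    ols = rg.sar_error_fit(X, y, w, fix_lam=0.0)
    assert sar.lam > 0.4
    assert sar.aic < ols.aic


def test_beta_regression_recovery_and_validation(rng):
    n = 500
    x = rng.normal(0, 1, n)
    from scipy.special import expit
    mu = expit(0.2 + 1.0 * x)
    phi = 30.0
    y = rng.beta(mu * phi, (1 - mu) * phi)
    X = np.column_stack([np.ones(n), x])
    out, _ = rg.beta_regression_fit(X, y, names=["int", "slope"])
    slope = out.set_index("term").loc["slope", "estimate"]
    assert slope == pytest.approx(1.0, abs=0.2)
    with pytest.raises(ValueError):
        rg.beta_regression_fit(X, np.append(y[:-1], 1.2))


def test_crowding_index_cases():
    adults = pd.DataFrame({
        "stem_id": ["f", "n1", "far"],
        "species_id": ["a", "b", "b"],
        "x": [0.0, 5.0, 0.0], "y": [0.0, 0.0, 10.5],
        "dbh": [np.sqrt(8 / np.pi), np.sqrt(40 / np.pi), 5.0],  # BA 2 and 10
    })
    ci = rg.crowding_index(adults).set_index("stem_id")
    # one heterospecific neighbour BA 10 at 5 m, focal BA 2 -> HAD = 10/(5*2) = 1
    assert ci.loc["f", "HAD"] == pytest.approx(1.0, rel=1e-9)
    assert ci.loc["f", "CAD"] == 0.0                     # no conspecifics in range
    assert ci.loc["far", "HAD"] == 0.0                   # 10.5 m > 10 m radius
    # additive over neighbour sets and invariant to relabeling
    ci_abs = rg.crowding_index(adults, formula="absolute").set_index("stem_id")
    assert ci_abs.loc["f", "HAD"] == pytest.approx(2.0, rel=1e-9)  # 10/5


def test_crowding_distance_floor():
    adults = pd.DataFrame({
        "stem_id": ["a", "b"], "species_id": ["s", "s"],
        "x": [0.0, 0.0], "y": [0.0, 0.0], "dbh": [2.0, 2.0],
    })
    ci = rg.crowding_index(adults).set_index("stem_id")
    assert np.isfinite(ci.CAD).all() and (ci.CAD > 0).all()


def test_seedling_design_counts_and_scaling():
    # one quadrat: focal newborn with 3 conspecifics and 2 heterospecifics
    rows = []
    for i, sp in enumerate(["a"] * 4 + ["b"] * 2):
        rows.append({"stem_id": f"s{i}", "species_id": sp, "quadrat_id": "q1",
                     "subplot_id": "sub1", "census": 2008, "height": 10.0,
                     "dbh": np.nan, "status": "recruited"})
    # a second quadrat so covariates have variance
    for i, sp in enumerate(["a", "b"]):
        rows.append({"stem_id": f"t{i}", "species_id": sp, "quadrat_id": "q2",
                     "subplot_id": "sub2", "census": 2008, "height": 12.0,
                     "dbh": np.nan, "status": "recruited"})
    rows.append({"stem_id": "s0", "species_id": "a", "quadrat_id": "q1",
                 "subplot_id": "sub1", "census": 2009, "height": 15.0,
                 "dbh": np.nan, "status": "alive"})
    seedlings = pd.DataFrame(rows)
    surface = pd.DataFrame({"quadrat_id": ["q1", "q2"], "nut": [3.0, 4.0]})
    design = rg.build_seedling_design(seedlings, surface, "nut")
    df = design.data
    # raw CSD 3 / HSD 2 for the q1 focal of species a, on the log1p scale
    # before z-scoring; invert the stored transform to check
    mu, sd = design.transform_record["scale"]["CSD"]
    raw_csd = np.expm1(df["CSD"] * sd + mu)
    s0 = df[df.stem_id == "s0"]
    assert raw_csd[s0.index[0]] == pytest.approx(3.0, abs=1e-9)
    assert s0.survival.item() == 1
    # z-scored columns have mean 0, SD 1
    for c in ("CSD", "HSD", "nutrient"):
        assert df[c].mean() == pytest.approx(0.0, abs=1e-9)
        assert df[c].std(ddof=1) == pytest.approx(1.0, rel=1e-9)


def test_mixed_model_reduces_without_random_structure(rng):
    # Gaussian design with a single non-informative grouping: estimates match OLS
    n = 300
    x = rng.normal(0, 1, n)
    y = 1.0 + 0.5 * x + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"y": y, "x": x, "g": np.repeat(np.arange(30), 10)})
    design = rg.NeighborhoodDesign(
        stage="adult", nutrient="none", data=df, response="y",
        fixed_terms=["x"], group_terms=["g"], family="gaussian")
    res = rg.fit_mixed_model(design).set_index("term")
    ols = np.linalg.lstsq(np.column_stack([np.ones(n), x]), y, rcond=None)[0]
    assert res.loc["x", "estimate"] == pytest.approx(ols[1], abs=0.02)
    assert 0 <= res.attrs["marginal_r2"] <= 1


def test_subset_weights_alignment():
    w = rg.queen_weights((4, 4))
    keep = np.ones(16, bool)
    keep[[0, 5]] = False
    sub = rg.subset_weights(w, keep)
    assert sub.n == 14
    rows = np.asarray(sub.W.sum(axis=1)).ravel()
    assert np.allclose(rows[rows > 0], 1.0)
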