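"""Variogram estimation, ordinary kriging, and Monte-Carlo propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from foreststab import geostat as gs


def _dense_ok_oracle(xy, z, model, target):
    """Independent brute-force solve of the ordinary-kriging system."""
    n = len(z)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model(cdist(xy, xy))
    A[n, :n] = A[:n, n] = 1.0
    g0 = model(cdist(xy, target[None, :])).ravel()
    sol = np.linalg.solve(A, np.r_[g0, 1.0])
    w, mu = sol[:n], sol[n]
    return w @ z, w @ g0 + mu, w


def test_empirical_variogram_basics(rng):
    pts = pd.DataFrame({"x": rng.uniform(0, 50, 60), "y": rng.uniform(0, 50, 60)})
    # constant field -> zero semivariance everywhere
    emp = gs.empirical_variogram(pts, np.full(60, 3.0), np.linspace(0, 60, 8))
    assert np.allclose(emp.dropna().gamma, 0.0)
    # two points distance 1, values 0 and 2 -> gamma = 2 in that bin
    two = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 0.0]})
    emp2 = gs.empirical_variogram(two, [0.0, 2.0], [0.5, 1.5])
    assert emp2.gamma.item() == pytest.approx(2.0)
    assert emp2.n_pairs.item() == 1


def test_iid_noise_variogram_flat_at_variance():
    # white noise: semivariance ~ s^2 at every lag (10-replicate average)
    gammas = []
    for s in range(10):
        r = np.random.default_rng(s)
        pts = pd.DataFrame({"x": r.uniform(0, 50, 80), "y": r.uniform(0, 50, 80)})
        z = r.normal(0, 2.0, 80)
        emp = gs.empirical_variogram(pts, z, np.linspace(1, 50, 6))
        gammas.append(emp.gamma.to_numpy())
    mean_gamma = np.nanmean(gammas, axis=0)
    assert np.allclose(mean_gamma, 4.0, rtol=0.25)


def test_variogram_fit_recovers_family_params():
    true = gs.VariogramModel("exponential", 0.2, 1.0, 15.0)
    h = np.linspace(1, 60, 15)
    emp = pd.DataFrame({"lag": h, "gamma": true(h), "n_pairs": 50})
    fit = gs.fit_variogram(emp, family="exponential")
    assert fit.nugget == pytest.approx(0.2, abs=0.05)
    assert fit.psill == pytest.approx(1.0, abs=0.1)
    assert fit.range_ == pytest.approx(15.0, rel=0.15)
    auto = gs.fit_variogram(emp)   # family selection by SSE
    assert auto.family == "exponential"


def test_kriging_matches_dense_oracle(rng):
    model = gs.VariogramModel("spherical", 0.1, 2.0, 40.0)
    pts = pd.DataFrame({"x": rng.uniform(0, 100, 25), "y": rng.uniform(0, 100, 25)})
    z = rng.normal(10, 2, 25)
    targets = rng.uniform(0, 100, (8, 2))
    surf = gs.ordinary_kriging(pts, z, model, targets)
    xy = pts[["x", "y"]].to_numpy()
    for k in range(8):
        pred, var, w = _dense_ok_oracle(xy, z, model, targets[k])
        assert surf.pred[k] == pytest.approx(pred, abs=1e-8)
        assert surf["var"][k] == pytest.approx(var, abs=1e-8)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)   # unbiasedness


def test_kriging_exact_interpolation_no_nugget(rng):
    model = gs.VariogramModel("exponential", 0.0, 1.0, 20.0)
    pts = pd.DataFrame({"x": rng.uniform(0, 50, 12), "y": rng.uniform(0, 50, 12)})
    z = rng.normal(5, 1, 12)
    surf = gs.ordinary_kriging(pts, z, model, pts[["x", "y"]].to_numpy())
    assert np.allclose(surf.pred, z, atol=1e-8)
    assert np.allclose(surf["var"], 0.0, atol=1e-8)


def test_kriging_symmetric_pair_average():
    model = gs.VariogramModel("exponential", 0.0, 1.0, 30.0)
    pts = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0]})
    surf = gs.ordinary_kriging(pts, np.array([2.0, 6.0]), model,
                               np.array([[5.0, 0.0]]))
    assert surf.pred.item() == pytest.approx(4.0, abs=1e-10)


def test_prediction_variance_shrinks_with_added_sample(rng):
    model = gs.VariogramModel("exponential", 0.0, 1.0, 25.0)
    pts = pd.DataFrame({"x": rng.uniform(0, 50, 8), "y": rng.uniform(0, 50, 8)})
    z = rng.normal(0, 1, 9)
    target = np.array([[25.0, 25.0]])
    v8 = gs.ordinary_kriging(pts, z[:8], model, target)["var"].item()
    pts9 = pd.concat([pts, pd.DataFrame({"x": [20.0], "y": [25.0]})],
                     ignore_index=True)
    v9 = gs.ordinary_kriging(pts9, z, model, target)["var"].item()
    assert v9 <= v8 + 1e-10


def test_duplicate_points_averaged():
    model = gs.VariogramModel("exponential", 0.0, 1.0, 30.0)
    pts = pd.DataFrame({"x": [0.0, 0.0, 10.0], "y": [0.0, 0.0, 0.0]})
    surf = gs.ordinary_kriging(pts, np.array([2.0, 4.0, 5.0]), model,
                               np.array([[0.0, 0.0]]))
    assert surf.pred.item() == pytest.approx(3.0, abs=1e-9)


def test_mc_propagation_zero_variance_and_mean(rng):
    surface = pd.DataFrame({"pred": rng.normal(0, 1, 30), "var": np.zeros(30)})
    out = gs.mc_propagate(surface, lambda x: {"mean": float(x.mean())},
                          n_draws=50, seed=1)
    assert out.lo95.item() == pytest.approx(out.hi95.item())   # zero-width interval
    surface2 = pd.DataFrame({"pred": np.full(30, 2.0), "var": np.full(30, 0.25)})
    out2 = gs.mc_propagate(surface2, lambda x: {"mean": float(x.mean())},
                           n_draws=500, seed=2)
    assert out2["median"].item() == pytest.approx(2.0, abs=0.05)


def test_mc_interval_covers_known_slope():
    # regression through kriged-with-uncertainty predictor: the 95% MC interval
    # should usually cover the true slope
    covered = 0
    n = 60
    beta = 0.8
    for s in range(10):
        r = np.random.default_rng(s)
        x_true = r.normal(0, 1, n)
        y = beta * x_true + r.normal(0, 0.3, n)
        surface = pd.DataFrame({"pred": x_true, "var": np.full(n, 0.05)})

        def refit(x, y=y):
            X = np.column_stack([np.ones(n), x])
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            return {"slope": float(b[1])}

        out = gs.mc_propagate(surface, refit, n_draws=200, seed=s)
        if out.lo95.item() - 0.15 <= beta <= out.hi95.item() + 0.15:
            covered += 1
    assert covered >= 8
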