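"""Variogram estimation, ordinary kriging with prediction variance, and
Monte-Carlo propagation of kriging uncertainty into downstream model fits.

Semivariogram models use the classical parameterisations

    exponential:  gamma(h) = nugget + psill * (1 - exp(-h / range))
    spherical:    gamma(h) = nugget + psill * (1.5 h/r - 0.5 (h/r)^3), h < r
    gaussian:     gamma(h) = nugget + psill * (1 - exp(-(h / range)^2))

Nutrient concentrations are log-transformed upstream of these routines; the
Monte-Carlo draws are on the same (log) scale as the kriged surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

logger = logging.getLogger(__name__)

FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    family: str
    nugget: float
    psill: float
    range_: float
    sse: float = float("nan")

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, psill >= 0, range > 0")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "exponential":
            g = 1.0 - np.exp(-h / r)
        elif self.family == "gaussian":
            g = 1.0 - np.exp(-((h / r) ** 2))
        else:  # spherical
            hr = np.minimum(h / r, 1.0)
            g = 1.5 * hr - 0.5 * hr ** 3
        out = self.nugget + self.psill * g
        return np.where(h == 0, 0.0, out)  # gamma(0) = 0 by definition

    def covariance(self, h):
        """C(h) = sill - gamma(h) for h > 0; C(0) = sill."""
        h = np.asarray(h, dtype=float)
        sill = self.nugget + self.psill
        return np.where(h == 0, sill, sill - self.__call__(h))


def empirical_variogram(points: pd.DataFrame, values, bin_edges) -> pd.DataFrame:
    """Matheron empirical semivariogram: mean of half squared differences per lag bin.

    Returns a DataFrame (lag, gamma, n_pairs); empty bins carry NaN gamma.
    """
    xy = points[["x", "y"]].to_numpy(dtype=float)
    z = np.asarray(values, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least two points")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing")
    h = pdist(xy)
    dz = 0.5 * pdist(z[:, None], metric="sqeuclidean")
    idx = np.digitize(h, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        rows.append({
            "lag": 0.5 * (edges[b] + edges[b + 1]),
            "gamma": float(dz[sel].mean()) if n else float("nan"),
            "n_pairs": n,
        })
    return pd.DataFrame(rows)


def fit_variogram(emp: pd.DataFrame, family: str | None = None) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to empirical bins.

    Weights are proportional to pair counts.  With ``family=None`` all three
    families are fitted and the lowest-SSE model is returned (logged).
    """
    ok = emp.dropna(subset=["gamma"])
    ok = ok[ok["n_pairs"] > 0]
    if len(ok) < 3:
        raise ValueError("need at least 3 non-empty bins to fit a variogram")
    h = ok["lag"].to_numpy()
    g = ok["gamma"].to_numpy()
    w = np.sqrt(ok["n_pairs"].to_numpy(dtype=float))
    fams = FAMILIES if family is None else (family,)
    best = None
    for fam in fams:
        sill0 = max(g.max(), 1e-12)
        r0 = max(h.max() / 3.0, 1e-6)
        def resid(theta, fam=fam):
            m = VariogramModel(fam, theta[0], theta[1], theta[2])
            return w * (m(h) - g)
        try:
            sol = least_squares(
                resid, x0=[0.1 * sill0, 0.9 * sill0, r0],
                bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
            )
        except Exception:  # pragma: no cover - optimizer failure on odd inputs
            continue
        sse = float(np.sum(sol.fun ** 2))
        m = VariogramModel(fam, sol.x[0], sol.x[1], sol.x[2], sse=sse)
        if best is None or sse < best.sse:
            best = m
    if best is None:
        raise RuntimeError("variogram fit failed for all families")
    logger.info("selected %s variogram (nugget=%.3g psill=%.3g range=%.3g sse=%.3g)",
                best.family, best.nugget, best.psill, best.range_, best.sse)
    return best


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at collocated sample points (logged)."""
    key = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "z": z})
    grp = key.groupby(["x", "y"], sort=False, as_index=False)["z"].mean()
    if len(grp) < len(key):
        logger.warning("averaged %d collocated sample points", len(key) - len(grp))
    return grp[["x", "y"]].to_numpy(), grp["z"].to_numpy()


def ordinary_kriging(points: pd.DataFrame, values, model: VariogramModel,
                     targets: np.ndarray) -> pd.DataFrame:
    """Ordinary kriging of ``values`` at sample ``points`` onto ``targets``.

    Solves the standard OK system with the unbiasedness constraint (weights
    sum to 1) once via an LU factorisation shared across targets.  Returns a
    DataFrame (x, y, pred, var); with a nugget-free model the predictor
    interpolates the data exactly and var = 0 at sampled locations.
    """
    xy = points[["x", "y"]].to_numpy(dtype=float)
    z = np.asarray(values, dtype=float)
    xy, z = _dedupe(xy, z)
    n = len(z)
    tg = np.atleast_2d(np.asarray(targets, dtype=float))
    G = model(squareform(pdist(xy)))
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    g0 = model(cdist(xy, tg))                       # (n, m)
    B = np.vstack([g0, np.ones(tg.shape[0])[None, :]])
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        logger.warning("singular kriging system; retrying with jitter")
        A[:n, :n] += 1e-10 * np.eye(n)
        sol = np.linalg.solve(A, B)
    lam = sol[:n]                                   # weights per target (n, m)
    mu = sol[n]                                     # Lagrange multipliers
    pred = lam.T @ z
    var = np.einsum("im,im->m", lam, g0) + mu
    var = np.maximum(var, 0.0)
    return pd.DataFrame({"x": tg[:, 0], "y": tg[:, 1], "pred": pred, "var": var})


def krige_nutrient(points: pd.DataFrame, nutrient: str, targets: np.ndarray,
                   bin_edges=None, family: str | None = None,
                   log_transform: bool = True) -> tuple[pd.DataFrame, VariogramModel]:
    """Variogram fit + ordinary kriging for one nutrient column of a sample table.

    Concentrations are log-transformed first (the downstream models work on
    the log scale); predictions and variances are returned on that scale.
    """
    z = points[nutrient].to_numpy(dtype=float)
    if log_transform:
        if np.any(z <= 0):
            raise ValueError(f"non-positive {nutrient} concentration; cannot log-transform")
        z = np.log(z)
    xy = points[["x", "y"]].to_numpy(dtype=float)
    if bin_edges is None:
        dmax = np.sqrt(((xy.max(0) - xy.min(0)) ** 2).sum()) / 2.0
        bin_edges = np.linspace(1e-6, dmax, 16)
    emp = empirical_variogram(points, z, bin_edges)
    model = fit_variogram(emp, family=family)
    surf = ordinary_kriging(points, z, model, targets)
    surf["nutrient"] = nutrient
    return surf, model


def mc_propagate(surface: pd.DataFrame, refit, n_draws: int = 500,
                 seed: int = 0, value_col: str = "pred",
                 var_col: str = "var") -> pd.DataFrame:
    """Propagate kriging prediction variance through a downstream fit.

    Per draw, X ~ Normal(pred, var) independently per quadrat; ``refit`` maps
    the drawn vector to a dict of coefficient estimates.  Returns per-
    coefficient median and 95% interval across draws.  Failed draws are
    dropped and counted; a warning is emitted past 5% failures.
    """
    rng = np.random.default_rng(seed)
    mu = surface[value_col].to_numpy(dtype=float)
    sd = np.sqrt(surface[var_col].to_numpy(dtype=float))
    results = []
    n_fail = 0
    for _ in range(n_draws):
        x = rng.normal(mu, sd)
        try:
            results.append(refit(x))
        except Exception:
            n_fail += 1
    if n_fail > 0.05 * n_draws:
        logger.warning("%d/%d Monte-Carlo draws failed downstream refits", n_fail, n_draws)
    if not results:
        raise RuntimeError("every Monte-Carlo draw failed")
    df = pd.DataFrame(results)
    out = pd.DataFrame({
        "median": df.median(),
        "lo95": df.quantile(0.025),
        "hi95": df.quantile(0.975),
    })
    out.index.name = "term"
    out.attrs["n_failed"] = n_fail
    return out.reset_index()
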