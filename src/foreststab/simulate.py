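"""Synthetic forest generator with known ground truth.

Produces (a) spatially autocorrelated soil-nutrient fields (stationary
Gaussian random fields with an exponential/spherical/gaussian variogram),
(b) a many-rare-species / few-abundant-species pool (log-series or
geometric), and (c) stage-structured demographic time series: annual
seedling censuses with logit-linear first-year survival including
nutrient x density interactions, and 5-yearly adult censuses with linear
DBH growth including nutrient x crowding interactions.

Density covariates are computed from the simulated state with the same
counting rules the analysis modules use (conspecific / heterospecific counts
per quadrat on the log(x+1) scale; crowding indices via
:func:`foreststab.regression.crowding_index`), so generator and estimator
share definitions.  None of the demographic magnitudes are estimates of any
real forest; they are free scenario parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .geostat import VariogramModel
from .layout import QuadratLayout


@dataclass(frozen=True)
class NutrientFieldParams:
    mean: float = 5.0           # mean of the (log-scale) concentration field
    sill: float = 1.0           # total variance
    range_: float = 50.0        # correlation range (m)
    nugget: float = 0.0         # micro-scale + measurement variance
    family: str = "exponential"

    def __post_init__(self):
        if not (self.sill >= self.nugget >= 0):
            raise ValueError("require sill >= nugget >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be positive")


def gaussian_random_field(coords: np.ndarray, params: NutrientFieldParams,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample a stationary GRF at ``coords`` by Cholesky factorisation.

    The spatially structured variance is ``sill - nugget``; nugget noise is
    added independently per location.
    """
    from scipy.spatial.distance import pdist, squareform

    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    psill = params.sill - params.nugget
    if psill > 0:
        model = VariogramModel(params.family, 0.0, psill, params.range_)
        C = model.covariance(squareform(pdist(coords)))
        np.fill_diagonal(C, psill)
        try:
            L = np.linalg.cholesky(C + 1e-10 * psill * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"covariance not positive definite for family={params.family}, "
                f"sill={params.sill}, nugget={params.nugget}, range={params.range_}"
            ) from exc
        z = params.mean + L @ rng.standard_normal(n)
    else:
        z = np.full(n, params.mean)
    if params.nugget > 0:
        z = z + rng.normal(0.0, np.sqrt(params.nugget), n)
    return z


def simulate_nutrient_field(layout: QuadratLayout, params: NutrientFieldParams,
                            seed: int,
                            sample_points: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """True nutrient surface on quadrat centres plus noisy design observations.

    The field is simulated jointly on quadrat centres and sampling-design
    points from the nugget-free covariance, so truth and observations share
    the same realisation; nugget noise is then added to the observations
    only.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    centers = layout.quadrat_centers()
    if sample_points is not None:
        pts = sample_points[["x", "y"]].to_numpy(dtype=float)
        coords = np.vstack([centers, pts])
    else:
        coords = centers
    smooth = replace(params, nugget=0.0)
    z = gaussian_random_field(coords, smooth, rng)
    truth = pd.DataFrame({
        "quadrat_id": [f"q{i}" for i in range(len(centers))],
        "x": centers[:, 0], "y": centers[:, 1], "value": z[: len(centers)],
    })
    obs = None
    if sample_points is not None:
        noise = rng.normal(0.0, np.sqrt(params.nugget), len(pts)) if params.nugget > 0 else 0.0
        obs = sample_points.copy()
        obs["value"] = z[len(centers):] + noise
    return truth, obs


def simulate_species_pool(S: int, model: str = "logseries", shape: float = 0.9,
                          seed: int = 0) -> np.ndarray:
    """Relative-abundance vector with a many-rare / few-abundant structure.

    log-series: p_k proportional to shape^k / k, 0 < shape < 1 (larger shape
    -> longer rare tail); geometric: p_k proportional to shape (1-shape)^(k-1),
    0 < shape < 1.  Returned sorted in decreasing order, summing to 1.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    k = np.arange(1, S + 1, dtype=float)
    if model == "logseries":
        if not 0 < shape < 1:
            raise ValueError("log-series shape must be in (0, 1)")
        p = shape ** k / k
    elif model == "geometric":
        if not 0 < shape < 1:
            raise ValueError("geometric shape must be in (0, 1)")
        p = shape * (1 - shape) ** (k - 1)
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    p = np.sort(p / p.sum())[::-1]
    return p


@dataclass(frozen=True)
class DemographyParams:
    """Ground-truth demographic coefficients for both stages.

    Survival coefficients act on the logit scale over log(x+1) density
    covariates and the z-scored nutrient; growth coefficients act on the cm
    scale.  ``synchrony`` in [0, 1] mixes a common year shock (1) against
    species-specific year shocks (0); lower synchrony generates the
    asynchronous, more stable communities.
    """

    # seedling survival (logit scale)
    surv_intercept: float = 1.2
    b_csd: float = -0.4
    b_hsd: float = 0.1
    b_nut: float = 0.0
    b_csd_nut: float = 0.0
    b_hsd_nut: float = 0.0
    b_height: float = 0.3
    sd_species: float = 0.3
    sd_subplot: float = 0.2
    sd_year: float = 0.2
    recruit_rate: float = 3.0            # expected new germinants per m^2 per year
    height_meanlog: float = np.log(15.0)  # initial seedling height ~ LogNormal (cm)
    height_sdlog: float = 0.4
    growth_mean: float = 6.0             # annual height increment (cm)
    growth_sd: float = 3.0
    trend_slope: float = 0.1             # linear productivity trend per year
    synchrony: float = 0.5
    # adult growth (cm DBH per 5-year interval)
    g_intercept: float = 1.2
    g_cad: float = -0.15
    g_had: float = -0.1
    g_nut: float = 0.0
    g_cad_nut: float = 0.0
    g_had_nut: float = 0.0
    g_dbh: float = -0.01
    g_sd_species: float = 0.2
    g_sd_individual: float = 0.2
    g_noise_sd: float = 0.5
    adult_mortality: float = 0.05        # per 5-year interval
    adult_recruit_rate: float = 0.02     # recruits per interval per standing adult
    dbh_powerlaw: float = 1.8            # truncated power-law exponent for initial DBH


def scenario_params(name: str) -> dict[str, DemographyParams]:
    """Preset per-nutrient demographies: 'null' or 'paper-like'.

    Keys are the four nutrient forms.  In the null scenario no nutrient
    coefficient is non-zero; in the paper-like scenario inorganic P
    facilitates heterospecific seedling neighbourhoods (positive HSD x
    nutrient) while organic P strengthens interspecific competition
    (negative HSD x nutrient), with analogous adult-stage signs.
    """
    base = DemographyParams()
    if name == "null":
        return {n: base for n in ("organicP", "inorganicP", "organicN", "inorganicN")}
    if name == "paper-like":
        return {
            "inorganicP": replace(base, b_nut=0.15, b_hsd_nut=0.2, g_had_nut=0.15),
            "organicP": replace(base, b_nut=-0.1, b_hsd_nut=-0.2, g_had_nut=-0.15),
            "organicN": replace(base, b_hsd_nut=-0.1, b_csd_nut=0.07, g_had_nut=-0.1),
            "inorganicN": replace(base, b_hsd_nut=-0.1, b_csd_nut=0.07, g_had_nut=-0.1),
        }
    raise ValueError(f"unknown scenario {name!r}")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def simulate_seedling_dynamics(quadrats: pd.DataFrame, nutrient: pd.Series,
                               pool: np.ndarray, params: DemographyParams,
                               years=range(2008, 2024), seed: int = 0) -> pd.DataFrame:
    """Annual seedling census table over ``years``.

    ``quadrats`` is the seedling-layout frame (quadrat_id, subplot_id);
    ``nutrient`` maps quadrat_id to the true (log-scale) nutrient value.
    Survival is Bernoulli with the logit-linear predictor over conspecific /
    heterospecific counts, the z-scored nutrient, their products, and log
    initial height, plus species / subplot / year random intercepts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    years = list(years)
    qids = quadrats["quadrat_id"].to_numpy()
    sub_of = dict(zip(quadrats["quadrat_id"], quadrats["subplot_id"]))
    nut_z = pd.Series(_zscore(nutrient.loc[qids].to_numpy(dtype=float)), index=qids)
    S = len(pool)
    re_sp = rng.normal(0, params.sd_species, S)
    subs = sorted(set(sub_of.values()))
    re_sub = dict(zip(subs, rng.normal(0, params.sd_subplot, len(subs))))
    re_year = dict(zip(years, rng.normal(0, params.sd_year, len(years))))
    w = np.sqrt(np.clip(params.synchrony, 0, 1))
    common_shock = rng.normal(0, 1, len(years))
    sp_shock = rng.normal(0, 1, (len(years), S))

    live = pd.DataFrame(columns=["stem_id", "species", "quadrat_id", "height", "born"])
    records = []
    next_id = 0
    for ti, t in enumerate(years):
        n_new = rng.poisson(params.recruit_rate, len(qids))
        total_new = int(n_new.sum())
        if total_new:
            new = pd.DataFrame({
                "stem_id": [f"s{next_id + i}" for i in range(total_new)],
                "species": rng.choice(S, total_new, p=pool),
                "quadrat_id": np.repeat(qids, n_new),
                "height": np.exp(rng.normal(params.height_meanlog,
                                            params.height_sdlog, total_new)),
                "born": t,
            })
            next_id += total_new
            live = pd.concat([live, new], ignore_index=True) if len(live) else new
        if live.empty:
            continue
        live["species"] = live["species"].astype(int)
        records.append(pd.DataFrame({
            "stem_id": live["stem_id"].to_numpy(),
            "species_id": ["sp" + str(s) for s in live["species"]],
            "quadrat_id": live["quadrat_id"].to_numpy(),
            "subplot_id": [sub_of[q] for q in live["quadrat_id"]],
            "census": t, "dbh": np.nan,
            "height": live["height"].to_numpy(dtype=float),
            "status": np.where(live["born"].to_numpy() == t, "recruited", "alive"),
        }))
        # survival to the next census
        counts = live.groupby(["quadrat_id", "species"]).size()
        qtot = live.groupby("quadrat_id").size()
        csd = counts.loc[list(zip(live["quadrat_id"], live["species"]))].to_numpy() - 1
        tot = qtot.loc[live["quadrat_id"]].to_numpy()
        hsd = tot - 1 - csd
        nz = nut_z.loc[live["quadrat_id"]].to_numpy()
        lcsd, lhsd = np.log1p(csd), np.log1p(hsd)
        eta = (params.surv_intercept + params.b_csd * lcsd + params.b_hsd * lhsd
               + params.b_nut * nz + params.b_csd_nut * lcsd * nz
               + params.b_hsd_nut * lhsd * nz
               + params.b_height * (np.log(live["height"].to_numpy(dtype=float))
                                    - params.height_meanlog)
               + re_sp[live["species"].to_numpy(dtype=int)]
               + np.array([re_sub[sub_of[q]] for q in live["quadrat_id"]])
               + re_year[t])
        surv = rng.random(len(live)) < expit(eta)
        live = live[surv].copy()
        # height growth with trended, partially synchronous year shocks
        shock = (w * common_shock[ti]
                 + np.sqrt(1 - w ** 2) * sp_shock[ti, live["species"].to_numpy(dtype=int)])
        inc = (params.growth_mean + params.trend_slope * ti
               + params.growth_sd * shock
               + rng.normal(0, params.growth_sd / 2, len(live)))
        live["height"] = live["height"].to_numpy(dtype=float) + np.maximum(inc, 0.5)
    return (pd.concat(records, ignore_index=True) if records
            else pd.DataFrame(columns=["stem_id", "species_id", "quadrat_id",
                                       "subplot_id", "census", "dbh", "height",
                                       "status"]))


def simulate_adult_dynamics(layout: QuadratLayout, nutrient: pd.Series,
                            pool: np.ndarray, params: DemographyParams,
                            n_initial: int = 2000,
                            censuses=(2011, 2016, 2021, 2026, 2031),
                            seed: int = 0) -> pd.DataFrame:
    """5-yearly adult census table on the 20-m quadrat grid.

    DBH growth per interval follows the linear crowding model with
    nutrient x crowding interactions; mortality and recruitment are constant
    rates.  ``nutrient`` maps quadrat index order of ``layout`` (q0..qN) to
    the true log-scale value.
    """
    from .regression import crowding_index

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    censuses = list(censuses)
    S = len(pool)
    re_sp = rng.normal(0, params.g_sd_species, S)
    nut_vals = nutrient.to_numpy(dtype=float)
    nut_z = pd.Series(_zscore(nut_vals), index=nutrient.index)

    def draw_dbh(n):
        u = rng.random(n)
        dbh = 1.0 * (1 - u) ** (-1.0 / params.dbh_powerlaw)
        return np.minimum(dbh, 80.0)

    x = rng.uniform(0, layout.width, n_initial)
    y = rng.uniform(0, layout.height, n_initial)
    live = pd.DataFrame({
        "stem_id": [f"a{i}" for i in range(n_initial)],
        "species": rng.choice(S, n_initial, p=pool),
        "x": x, "y": y, "dbh": draw_dbh(n_initial),
        "re_ind": rng.normal(0, params.g_sd_individual, n_initial),
        "born": censuses[0],
    })
    next_id = n_initial
    records = []
    for ti, t in enumerate(censuses):
        qidx = layout.quadrat_index(live["x"], live["y"])
        live = live[qidx >= 0].copy()
        live["quadrat_id"] = [f"q{i}" for i in layout.quadrat_index(live["x"], live["y"])]
        live["species"] = live["species"].astype(int)
        records.append(pd.DataFrame({
            "stem_id": live["stem_id"].to_numpy(),
            "species_id": ["sp" + str(s) for s in live["species"]],
            "x": live["x"].to_numpy(dtype=float),
            "y": live["y"].to_numpy(dtype=float),
            "quadrat_id": live["quadrat_id"].to_numpy(),
            "census": t, "dbh": live["dbh"].to_numpy(dtype=float),
            "height": np.nan,
            "status": np.where(live["born"].to_numpy() == t, "recruited", "alive"),
        }))
        if t == censuses[-1]:
            break
        snap = live.rename(columns={"species": "species_id"})[
            ["stem_id", "species_id", "x", "y", "dbh"]]
        ci = crowding_index(snap).set_index("stem_id")
        lcad = np.log1p(ci.loc[live["stem_id"], "CAD"].to_numpy())
        lhad = np.log1p(ci.loc[live["stem_id"], "HAD"].to_numpy())
        nz = nut_z.loc[live["quadrat_id"]].to_numpy()
        growth = (params.g_intercept + params.g_cad * lcad + params.g_had * lhad
                  + params.g_nut * nz + params.g_cad_nut * lcad * nz
                  + params.g_had_nut * lhad * nz
                  + params.g_dbh * (live["dbh"].to_numpy() - 5.0)
                  + re_sp[live["species"].to_numpy(dtype=int)]
                  + live["re_ind"].to_numpy()
                  + rng.normal(0, params.g_noise_sd, len(live)))
        live["dbh"] = np.maximum(live["dbh"].to_numpy() + np.maximum(growth, 0.0), 1.0)
        surv = rng.random(len(live)) >= params.adult_mortality
        live = live[surv].copy()
        n_rec = rng.poisson(params.adult_recruit_rate * len(live))
        if n_rec:
            new = pd.DataFrame({
                "stem_id": [f"a{next_id + i}" for i in range(n_rec)],
                "species": rng.choice(S, n_rec, p=pool),
                "x": rng.uniform(0, layout.width, n_rec),
                "y": rng.uniform(0, layout.height, n_rec),
                "dbh": rng.uniform(1.0, 2.0, n_rec),
                "re_ind": rng.normal(0, params.g_sd_individual, n_rec),
                "born": censuses[ti + 1],
            })
            next_id += n_rec
            live = pd.concat([live, new], ignore_index=True)
    return pd.concat(records, ignore_index=True)


def simulate_forest_dynamics(seedling_quadrats: pd.DataFrame,
                             adult_layout: QuadratLayout,
                             seedling_nutrient: pd.Series,
                             adult_nutrient: pd.Series,
                             pool: np.ndarray, params: DemographyParams,
                             seedling_years=range(2008, 2024),
                             adult_censuses=(2011, 2016, 2021, 2026, 2031),
                             n_adults: int = 2000,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seedling (annual) and adult (5-yearly) census-table pair, one master seed."""
    sub = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=2)
    seedlings = simulate_seedling_dynamics(
        seedling_quadrats, seedling_nutrient, pool, params,
        years=seedling_years, seed=int(sub[0]))
    adults = simulate_adult_dynamics(
        adult_layout, adult_nutrient, pool, params, n_initial=n_adults,
        censuses=adult_censuses, seed=int(sub[1]))
    return seedlings, adults
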