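"""Regression machinery: scaled multiple regression with bootstrap CIs, VIF,
beta regression, queen-contiguity spatial weights, the SAR error model, adult
crowding indices, and construction/fitting of the stage-specific neighborhood
designs (seedling survival GLMM, adult growth LMM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .diversity import basal_area
from .layout import QuadratLayout

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms

def zscale_and_log(table: pd.DataFrame, log_columns=(), scale_columns=(),
                   log_offset: float = 0.0) -> tuple[pd.DataFrame, dict]:
    """Log-transform then centre-and-scale columns; returns table + transform record.

    ``log_offset`` is added before the log (use 1.0 for the log1p count rule).
    The record stores offsets, means and SDs so the transform is reversible.
    """
    out = table.copy()
    record = {"log": {}, "scale": {}}
    for c in log_columns:
        v = out[c].to_numpy(dtype=float) + log_offset
        if np.any(v <= 0):
            raise ValueError(f"column {c!r} non-positive after offset {log_offset}")
        out[c] = np.log(v)
        record["log"][c] = log_offset
    for c in scale_columns:
        v = out[c].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column {c!r} cannot be scaled")
        out[c] = (v - mu) / sd
        record["scale"][c] = (mu, sd)
    return out, record


# ---------------------------------------------------------------------------
# OLS with nonparametric bootstrap

def ols_bootstrap(X: np.ndarray, y: np.ndarray, n_boot: int = 10000,
                  seed: int = 0, names=None) -> pd.DataFrame:
    """Case-resampling bootstrap of OLS coefficients with percentile 95% CIs.

    Returns a tidy frame (term, estimate, median, lo95, hi95, significant)
    where ``significant`` flags CIs excluding zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > p")
    beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
    rng = np.random.default_rng(seed)
    betas = np.empty((n_boot, p))
    for b in range(n_boot):
        for _ in range(10):
            idx = rng.integers(0, n, n)
            Xb = X[idx]
            XtX = Xb.T @ Xb
            if np.linalg.cond(XtX) < 1e12:
                betas[b] = np.linalg.solve(XtX, Xb.T @ y[idx])
                break
        else:
            raise RuntimeError("persistent singular bootstrap resamples")
    lo = np.percentile(betas, 2.5, axis=0)
    hi = np.percentile(betas, 97.5, axis=0)
    names = names if names is not None else [f"x{j}" for j in range(p)]
    return pd.DataFrame({
        "term": names, "estimate": beta_hat,
        "median": np.median(betas, axis=0), "lo95": lo, "hi95": hi,
        "significant": (lo > 0) | (hi < 0),
    })


def vif(X: np.ndarray, names=None) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) per predictor column.

    Perfect collinearity yields ``inf``.  An intercept column is added to the
    auxiliary regressions automatically.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    names = names if names is not None else [f"x{j}" for j in range(p)]
    out = {}
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Xj = np.hstack([ones, np.delete(X, j, axis=1)])
        resid = yj - Xj @ np.linalg.lstsq(Xj, yj, rcond=None)[0]
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        out[names[j]] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# spatial weights and the SAR error model

@dataclass
class SpatialWeights:
    """Queen-contiguity weights on a regular quadrat grid."""

    labels: list
    adjacency: sp.csr_matrix          # symmetric 0/1, zero diagonal
    row_standardized: bool = True
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def W(self) -> sp.csr_matrix:
        if not self.row_standardized:
            return self.adjacency
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        islands = deg == 0
        if islands.any():
            logger.warning("%d island units with no neighbours", int(islands.sum()))
        inv = np.where(islands, 0.0, 1.0 / np.maximum(deg, 1))
        return sp.diags(inv) @ self.adjacency

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (via the similar symmetric matrix)."""
        if self._eigs is None:
            deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
            if not self.row_standardized:
                M = self.adjacency.toarray()
            else:
                d = np.where(deg == 0, 1.0, deg)
                Dh = sp.diags(1.0 / np.sqrt(d))
                M = (Dh @ self.adjacency @ Dh).toarray()
            self._eigs = np.linalg.eigvalsh(M)
        return self._eigs


def queen_weights(layout: QuadratLayout | tuple[int, int],
                  row_standardize: bool = True) -> SpatialWeights:
    """8-neighbour (edge- and corner-adjacent) contiguity on a quadrat grid."""
    if isinstance(layout, QuadratLayout):
        nrow, ncol = layout.grid_shape()
    else:
        nrow, ncol = layout
    if nrow < 1 or ncol < 1:
        raise ValueError("grid must be at least 1x1")
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    rows, cols = [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(nrow, nrow - dr)
            c0, c1 = max(0, -dc), min(ncol, ncol - dc)
            src = idx[r0:r1, c0:c1].ravel()
            dst = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
            rows.append(src)
            cols.append(dst)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sp.csr_matrix((np.ones_like(rows, dtype=float), (rows, cols)),
                      shape=(nrow * ncol, nrow * ncol))
    labels = [f"q{r}_{c}" for r in range(nrow) for c in range(ncol)]
    return SpatialWeights(labels=labels, adjacency=A, row_standardized=row_standardize)


def subset_weights(weights: SpatialWeights, keep: np.ndarray) -> SpatialWeights:
    """Restrict a weights object to the units flagged in boolean mask ``keep``.

    Used when degenerate quadrats are dropped listwise before a SAR fit.
    """
    keep = np.asarray(keep, dtype=bool)
    A = weights.adjacency[keep][:, keep]
    labels = [l for l, k in zip(weights.labels, keep) if k]
    return SpatialWeights(labels=labels, adjacency=A.tocsr(),
                          row_standardized=weights.row_standardized)


@dataclass
class SarFit:
    beta: np.ndarray
    beta_se: np.ndarray
    lam: float
    lam_se: float
    sigma2: float
    loglik: float
    aic: float
    names: list

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.beta_se
        from scipy.stats import norm
        return pd.DataFrame({
            "term": self.names, "estimate": self.beta, "se": self.beta_se,
            "z": z, "p": 2 * norm.sf(np.abs(z)),
        })


def sar_error_fit(X: np.ndarray, y: np.ndarray, weights: SpatialWeights,
                  names=None, fix_lam: float | None = None) -> SarFit:
    """Maximum-likelihood SAR error model y = X b + u, u = lambda W u + e.

    The likelihood is concentrated over lambda using the eigenvalues of the
    row-standardized weights; beta standard errors come from the GLS
    information matrix and the lambda SE from the numerical curvature of the
    concentrated log-likelihood.  AIC = 2k - 2 logLik with k = p + 2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if weights.n != n:
        raise ValueError("weights dimension does not match data")
    W = weights.W.toarray()
    eigs = weights.eigenvalues()
    lo = 1.0 / eigs.min() + 1e-6 if eigs.min() < 0 else -0.999999
    hi = 1.0 / eigs.max() - 1e-6 if eigs.max() > 0 else 0.999999
    I = np.eye(n)

    def neg_conc_ll(lam):
        B = I - lam * W
        Xs, ys = B @ X, B @ y
        beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        resid = ys - Xs @ beta
        sigma2 = float(resid @ resid) / n
        logdet = float(np.sum(np.log(1.0 - lam * eigs)))
        ll = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(sigma2)) + logdet
        return -ll

    if fix_lam is not None:
        lam = float(fix_lam)
    else:
        res = minimize_scalar(neg_conc_ll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"SAR concentrated likelihood failed: {res.message}")
        lam = float(res.x)
    B = I - lam * W
    Xs, ys = B @ X, B @ y
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / n
    beta_se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    h = 1e-5 * max(1.0, abs(lam))
    lam_m = max(lam - h, lo)
    lam_p = min(lam + h, hi)
    d2 = (neg_conc_ll(lam_p) - 2 * neg_conc_ll(lam) + neg_conc_ll(lam_m)) / ((lam_p - lam) * (lam - lam_m))
    lam_se = float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")
    ll = -neg_conc_ll(lam)
    k = p + 2
    return SarFit(beta=beta, beta_se=beta_se, lam=lam, lam_se=lam_se,
                  sigma2=sigma2, loglik=ll, aic=2 * k - 2 * ll,
                  names=list(names) if names is not None else [f"x{j}" for j in range(p)])


# ---------------------------------------------------------------------------
# beta regression

def beta_regression_fit(X: np.ndarray, y: np.ndarray, names=None):
    """Beta regression with a logit mean link (ML via statsmodels BetaModel).

    Responses exactly at 0 or 1 are shrunk by the standard
    (y (n-1) + 0.5) / n rule (logged); values outside [0, 1] raise.
    Returns a tidy coefficient frame on the link scale plus the precision.
    """
    from statsmodels.othermod.betareg import BetaModel

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("beta regression requires responses in [0, 1]")
    n = len(y)
    if np.any((y <= 0) | (y >= 1)):
        logger.info("shrinking %d boundary responses into (0,1)",
                    int(((y <= 0) | (y >= 1)).sum()))
        y = (y * (n - 1) + 0.5) / n
    fit = BetaModel(y, X).fit(disp=False)
    p = X.shape[1]
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    out = pd.DataFrame({
        "term": names + ["precision"],
        "estimate": fit.params,
        "se": fit.bse,
        "p": fit.pvalues,
    })
    return out, fit


# ---------------------------------------------------------------------------
# neighborhood covariates

def crowding_index(adults: pd.DataFrame, radius: float = 10.0,
                   min_distance: float = 0.1,
                   formula: str = "relative") -> pd.DataFrame:
    """Conspecific (CAD) and heterospecific (HAD) crowding per focal adult.

    Neighbours are all adults within ``radius`` metres.  The default index is
    NCI = sum_j BA_j / (d_ij * BA_focal) (larger, closer neighbours crowd a
    small focal tree more); ``formula='absolute'`` drops the focal term,
    NCI = sum_j BA_j / d_ij.  Coincident stems receive a minimum-distance
    floor (logged).  Stems with no neighbours score zero.
    """
    if formula not in ("relative", "absolute"):
        raise ValueError("formula must be 'relative' or 'absolute'")
    xy = adults[["x", "y"]].to_numpy(dtype=float)
    ba = basal_area(adults["dbh"].to_numpy(dtype=float))
    sp_codes = pd.factorize(adults["species_id"])[0]
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    cad = np.zeros(len(adults))
    had = np.zeros(len(adults))
    if len(pairs):
        d = np.sqrt(((xy[pairs[:, 0]] - xy[pairs[:, 1]]) ** 2).sum(axis=1))
        n_floor = int((d < min_distance).sum())
        if n_floor:
            logger.info("applied %.2g m distance floor to %d coincident pairs",
                        min_distance, n_floor)
        d = np.maximum(d, min_distance)
        same = sp_codes[pairs[:, 0]] == sp_codes[pairs[:, 1]]
        for a, b in ((0, 1), (1, 0)):
            contrib = ba[pairs[:, b]] / d
            np.add.at(cad, pairs[same, a], contrib[same])
            np.add.at(had, pairs[~same, a], contrib[~same])
    if formula == "relative":
        cad = cad / ba
        had = had / ba
    out = adults[["stem_id"]].copy()
    out["CAD"] = cad
    out["HAD"] = had
    return out


# ---------------------------------------------------------------------------
# neighborhood designs (one soil nutrient at a time)

@dataclass
class NeighborhoodDesign:
    """Model-ready design for one life stage and one nutrient."""

    stage: str
    nutrient: str
    data: pd.DataFrame
    response: str
    fixed_terms: list
    group_terms: list
    family: str
    transform_record: dict = field(default_factory=dict)
    n_dropped: int = 0


def build_seedling_design(seedlings: pd.DataFrame, surface: pd.DataFrame,
                          nutrient: str) -> NeighborhoodDesign:
    """First-year survival design for newly germinated seedlings.

    CSD / HSD are conspecific / heterospecific seedling counts in the same
    1 m^2 quadrat at the recruitment census (focal excluded); survival is
    presence alive at the next census.  Counts are log(x+1)-transformed, all
    covariates z-scored; random-effect keys are species, subplot and cohort
    year.  ``surface`` maps quadrat_id -> nutrient value (kriged, log scale).
    """
    years = np.sort(seedlings["census"].unique())
    nut = surface.set_index("quadrat_id")[nutrient]
    first = seedlings.groupby("stem_id")["census"].min()
    rows = []
    n_dropped = 0
    by_year = {y: g for y, g in seedlings.groupby("census")}
    for t, t_next in zip(years[:-1], years[1:]):
        cohort = seedlings[(seedlings["census"] == t)
                           & (seedlings["stem_id"].map(first) == t)
                           & (seedlings["status"].ne("dead"))]
        if cohort.empty:
            continue
        snap = by_year[t]
        alive_next = set(by_year.get(t_next, pd.DataFrame(columns=["stem_id", "status"]))
                         .query("status != 'dead'")["stem_id"])
        counts = snap.groupby(["quadrat_id", "species_id"]).size()
        qtot = snap.groupby("quadrat_id").size()
        for rec in cohort.itertuples():
            q = rec.quadrat_id
            if q not in nut.index:
                n_dropped += 1
                continue
            csd = counts.get((q, rec.species_id), 0) - 1
            hsd = qtot.get(q, 1) - 1 - csd
            rows.append({
                "stem_id": rec.stem_id, "survival": int(rec.stem_id in alive_next),
                "CSD": max(csd, 0), "HSD": max(hsd, 0),
                "nutrient": float(nut.loc[q]), "IniHeight": float(rec.height),
                "species_id": rec.species_id, "subplot_id": rec.subplot_id,
                "cohort": int(t), "quadrat_id": q,
            })
    if n_dropped:
        logger.info("dropped %d seedlings without a nutrient surface value", n_dropped)
    df = pd.DataFrame(rows)
    df, record = zscale_and_log(df, log_columns=["CSD", "HSD"], log_offset=1.0)
    df["IniHeight"] = np.log(df["IniHeight"])
    df, rec2 = zscale_and_log(df, scale_columns=["CSD", "HSD", "nutrient", "IniHeight"])
    record["scale"] = rec2["scale"]
    df["CSDxNut"] = df["CSD"] * df["nutrient"]
    df["HSDxNut"] = df["HSD"] * df["nutrient"]
    return NeighborhoodDesign(
        stage="seedling", nutrient=nutrient, data=df, response="survival",
        fixed_terms=["CSD", "HSD", "nutrient", "CSDxNut", "HSDxNut", "IniHeight"],
        group_terms=["species_id", "subplot_id", "cohort"],
        family="binomial", transform_record=record, n_dropped=n_dropped)


def build_adult_design(adults: pd.DataFrame, surface: pd.DataFrame, nutrient: str,
                       layout: QuadratLayout, radius: float = 10.0,
                       crowding_formula: str = "relative") -> NeighborhoodDesign:
    """DBH-growth design for focal adults (edge-filtered), one nutrient.

    Response is the DBH increment between consecutive censuses; CAD / HAD are
    crowding indices at the interval start; year enters as a fixed effect;
    random-effect keys are individual, species and quadrat.  Crowding indices
    are log(x + smallest positive value)-transformed, all covariates z-scored.
    """
    years = np.sort(adults["census"].unique())
    nut = surface.set_index("quadrat_id")[nutrient]
    frames = []
    n_dropped = 0
    for t, t_next in zip(years[:-1], years[1:]):
        snap = adults[(adults["census"] == t) & adults["status"].ne("dead")].copy()
        nxt = adults[(adults["census"] == t_next) & adults["status"].ne("dead")]
        nxt = nxt.set_index("stem_id")["dbh"]
        snap = snap[snap["stem_id"].isin(nxt.index)]
        if snap.empty:
            continue
        ci = crowding_index(snap, radius=radius, formula=crowding_formula)
        snap = snap.merge(ci, on="stem_id")
        snap["dDBH"] = nxt.loc[snap["stem_id"]].to_numpy() - snap["dbh"].to_numpy()
        snap["year"] = int(t)
        frames.append(snap)
    df = pd.concat(frames, ignore_index=True)
    if "focal" in df.columns:
        df = df[df["focal"]]
    else:
        x0, y0 = layout.origin
        df = df[(df["x"] >= x0 + radius) & (df["x"] <= x0 + layout.width - radius)
                & (df["y"] >= y0 + radius) & (df["y"] <= y0 + layout.height - radius)]
    miss = ~df["quadrat_id"].isin(nut.index)
    n_dropped = int(miss.sum())
    if n_dropped:
        logger.info("dropped %d adult records without a nutrient surface value", n_dropped)
    df = df[~miss].copy()
    df["nutrient"] = df["quadrat_id"].map(nut).astype(float)
    df["IniDBH"] = df["dbh"]
    for c in ("CAD", "HAD"):
        v = df[c].to_numpy()
        eps = v[v > 0].min() if (v > 0).any() else 1.0
        df[c] = np.log(v + eps)
    df, record = zscale_and_log(
        df, scale_columns=["CAD", "HAD", "nutrient", "IniDBH"])
    df["CADxNut"] = df["CAD"] * df["nutrient"]
    df["HADxNut"] = df["HAD"] * df["nutrient"]
    return NeighborhoodDesign(
        stage="adult", nutrient=nutrient, data=df.reset_index(drop=True),
        response="dDBH",
        fixed_terms=["CAD", "HAD", "nutrient", "CADxNut", "HADxNut", "IniDBH", "year"],
        group_terms=["species_id", "quadrat_id", "stem_id"],
        family="gaussian", transform_record=record, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# mixed-model fitting (delegated numerics)

def fit_mixed_model(design: NeighborhoodDesign) -> pd.DataFrame:
    """Fit the stage-appropriate mixed model of a neighborhood design.

    Seedling survival: binomial-logit GLMM with crossed random intercepts,
    fitted by the variational Bayes routine of statsmodels (posterior means
    reported as estimates).  Adult growth: Gaussian LMM via statsmodels
    MixedLM with the first grouping key as the grouping factor and remaining
    keys as variance components (within-group approximation to fully crossed
    intercepts).  Returns a tidy frame with a marginal-R2 attribute
    (variance of fixed-effect predictions over total modelled variance).
    """
    df = design.data
    terms = design.fixed_terms
    fixed = " + ".join(terms) if terms else "1"
    if design.family == "binomial":
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        formula = f"{design.response} ~ {fixed}"
        vc = {g: f"0 + C({g})" for g in design.group_terms}
        model = BinomialBayesMixedGLM.from_formula(formula, vc, df)
        fit = model.fit_vb()
        fe = pd.Series(fit.fe_mean, index=model.exog_names)
        se = pd.Series(fit.fe_sd, index=model.exog_names)
        from scipy.stats import norm
        out = pd.DataFrame({
            "term": fe.index, "estimate": fe.to_numpy(), "se": se.to_numpy(),
            "z": (fe / se).to_numpy(),
            "p": 2 * norm.sf(np.abs((fe / se).to_numpy())),
        })
        X = model.exog
        var_fixed = float(np.var(X @ fe.to_numpy()))
        var_rand = float(np.sum(np.exp(2 * fit.vcp_mean)))
        resid = np.pi ** 2 / 3  # logit-link distribution variance
        out.attrs["marginal_r2"] = var_fixed / (var_fixed + var_rand + resid)
        out.attrs["fit"] = fit
        return out
    # Gaussian LMM
    import statsmodels.formula.api as smf

    groups = design.group_terms[0] if design.group_terms else None
    vc = {g: f"0 + C({g})" for g in design.group_terms[1:]}
    kwargs = {}
    if vc:
        kwargs["vc_formula"] = vc
    if groups is None:
        import statsmodels.api as sm
        fit = smf.ols(f"{design.response} ~ {fixed}", df).fit()
        out = pd.DataFrame({"term": fit.params.index, "estimate": fit.params.to_numpy(),
                            "se": fit.bse.to_numpy(), "z": fit.tvalues.to_numpy(),
                            "p": fit.pvalues.to_numpy()})
        out.attrs["marginal_r2"] = fit.rsquared
        out.attrs["fit"] = fit
        return out
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    model = smf.mixedlm(f"{design.response} ~ {fixed}", df, groups=df[groups], **kwargs)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            fit = model.fit(reml=True)
        except Exception:
            logger.warning("singular mixed fit; refitting without variance components")
            model = smf.mixedlm(f"{design.response} ~ {fixed}", df, groups=df[groups])
            fit = model.fit(reml=True)
    fe_names = list(model.exog_names)
    out = pd.DataFrame({
        "term": fe_names,
        "estimate": fit.params[fe_names].to_numpy(),
        "se": fit.bse[fe_names].to_numpy(),
        "z": fit.tvalues[fe_names].to_numpy(),
        "p": fit.pvalues[fe_names].to_numpy(),
    })
    X = model.exog
    var_fixed = float(np.var(X @ fit.params[fe_names].to_numpy()))
    var_rand = float(np.sum(fit.vcomp)) if len(fit.vcomp) else 0.0
    var_group = float(fit.cov_re.to_numpy().sum()) if fit.cov_re.size else 0.0
    out.attrs["marginal_r2"] = var_fixed / (var_fixed + var_rand + var_group + float(fit.scale))
    out.attrs["fit"] = fit
    return out
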