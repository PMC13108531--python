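"""Productivity construction and the temporal-stability / asynchrony partition.

Community temporal stability is the inverse coefficient of variation of
community productivity through time, mu_comm / sigma_comm; population
stability is mu_comm / sum_i sigma_i over species-level SDs; species
asynchrony is 1 - sigma_comm^2 / (sum_i sigma_i)^2, in [0, 1].  All SDs are
of the residuals of an ordinary least-squares regression of productivity on
census year (linear detrending), with the n-1 sample denominator.

The three quantities satisfy, identically,

    ln(community stability) = ln(population stability) - 0.5 ln(1 - asynchrony)

because sigma_comm = (sum_i sigma_i) * sqrt(1 - asynchrony).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default adult AGB allometry AGB = a * DBH^b (configurable; increments only
#: ever enter stability ratios, which are invariant to the scale a)
DEFAULT_ALLOMETRY = (0.25, 2.5)


def agb_from_dbh(dbh, allometry: tuple[float, float] = DEFAULT_ALLOMETRY):
    """Aboveground biomass from DBH via a power-law allometry AGB = a * DBH^b."""
    a, b = allometry
    return a * np.asarray(dbh, dtype=float) ** b


def species_productivity(census: pd.DataFrame, stage: str,
                         quadrat_col: str = "quadrat_id",
                         allometry: tuple[float, float] = DEFAULT_ALLOMETRY,
                         negative_increments: str = "keep") -> pd.DataFrame:
    """Quadrat x species x interval productivity from a longitudinal census table.

    Per surviving individual the contribution to the interval ending at census
    ``t`` is the increment of AGB (adults) or height (seedlings) between the
    two consecutive censuses; newly recruited individuals contribute their
    first recorded AGB/height in the interval of first record (size assumed
    zero at the interval start).  Dead stems contribute nothing after their
    last living census.

    Returns a long DataFrame (quadrat_id, species_id, interval, year, productivity)
    where ``year`` is the calendar year ending the interval.
    """
    if stage not in ("seedling", "adult"):
        raise ValueError("stage must be 'seedling' or 'adult'")
    years = np.sort(census["census"].unique())
    if len(years) < 2:
        raise ValueError("need at least two censuses to form increments")
    size = (agb_from_dbh(census["dbh"], allometry) if stage == "adult"
            else census["height"].to_numpy(dtype=float))
    df = census[[quadrat_col, "species_id", "stem_id", "census"]].copy()
    df["size"] = size
    df["alive"] = census["status"].ne("dead") if "status" in census else True
    df = df[df["alive"]]

    wide = df.pivot_table(index="stem_id", columns="census", values="size", aggfunc="first")
    wide = wide.reindex(columns=years)
    meta = df.drop_duplicates("stem_id").set_index("stem_id")[[quadrat_col, "species_id"]]

    vals = wide.to_numpy()
    prev = vals[:, :-1]
    curr = vals[:, 1:]
    inc = curr - prev
    recruit = np.isnan(prev) & ~np.isnan(curr)
    inc = np.where(recruit, curr, inc)          # recruit rule: zero at interval start
    inc = np.where(np.isnan(curr), np.nan, inc)  # gone by census end -> no contribution
    n_neg = int(np.nansum(inc < 0))
    if n_neg:
        if negative_increments == "truncate":
            inc = np.where(inc < 0, 0.0, inc)
            logger.info("truncated %d negative increments at zero", n_neg)
        else:
            logger.info("kept %d negative productivity increments", n_neg)

    long = pd.DataFrame(inc, index=wide.index, columns=years[1:]).stack().rename("productivity")
    long = long.reset_index().rename(columns={"level_1": "census", "census": "year"})
    long.columns = ["stem_id", "year", "productivity"]
    long = long.join(meta, on="stem_id")
    out = (long.groupby([quadrat_col, "species_id", "year"], sort=True)["productivity"]
           .sum().reset_index())
    year_to_interval = {y: i for i, y in enumerate(years[1:])}
    out["interval"] = out["year"].map(year_to_interval)
    return out[[quadrat_col, "species_id", "interval", "year", "productivity"]]


def community_productivity(matrix: pd.DataFrame,
                           quadrat_col: str = "quadrat_id") -> pd.DataFrame:
    """Community marginal: sum over species per quadrat-interval."""
    return (matrix.groupby([quadrat_col, "interval", "year"], sort=True)["productivity"]
            .sum().reset_index())


def detrended_sd(values, years) -> float:
    """Sample SD (n-1) of residuals from an OLS fit of values on calendar year.

    Returns NaN (flagged missing) with fewer than 3 intervals.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(years, dtype=float)
    if v.size < 3:
        return float("nan")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    return float(np.std(resid, ddof=1))


def _dense_series(grp: pd.DataFrame, years: np.ndarray) -> np.ndarray:
    """Species series over all intervals of the quadrat, absent intervals = 0."""
    s = pd.Series(0.0, index=years)
    s.loc[grp["year"].to_numpy()] = grp["productivity"].to_numpy()
    return s.to_numpy()


def stability_profile(matrix: pd.DataFrame, quadrat_col: str = "quadrat_id",
                      min_intervals: int = 3) -> pd.DataFrame:
    """Per-quadrat community stability, population stability, and asynchrony.

    Quadrats with sigma_comm = 0 or fewer than ``min_intervals`` intervals are
    flagged ``degenerate`` and carry NaN metrics; downstream regressions drop
    them listwise.
    """
    rows = []
    n_degenerate = 0
    for qid, grp in matrix.groupby(quadrat_col, sort=True):
        years = np.sort(grp["year"].unique())
        comm = grp.groupby("year")["productivity"].sum().reindex(years, fill_value=0.0)
        mu = float(comm.mean())
        if len(years) < min_intervals:
            rows.append(_degenerate_row(quadrat_col, qid, mu))
            n_degenerate += 1
            continue
        sigma_comm = detrended_sd(comm.to_numpy(), years)
        sig_sum = 0.0
        for _, sp in grp.groupby("species_id"):
            sigma_i = detrended_sd(_dense_series(sp, years), years)
            sig_sum += sigma_i
        tol = 1e-10 * max(abs(mu), 1.0)   # float-noise residuals count as zero
        if sigma_comm <= tol or sig_sum <= tol or not np.isfinite(sigma_comm):
            rows.append(_degenerate_row(quadrat_col, qid, mu))
            n_degenerate += 1
            continue
        asyn = 1.0 - sigma_comm ** 2 / sig_sum ** 2
        rows.append({
            quadrat_col: qid, "mu_comm": mu, "sigma_comm": sigma_comm,
            "sigma_sum": sig_sum,
            "community_stability": mu / sigma_comm,
            "population_stability": mu / sig_sum,
            "asynchrony": float(np.clip(asyn, 0.0, 1.0)),
            "degenerate": False,
        })
    if n_degenerate:
        logger.info("flagged %d degenerate quadrats (sigma=0 or <%d intervals)",
                    n_degenerate, min_intervals)
    return pd.DataFrame(rows)


def _degenerate_row(quadrat_col, qid, mu):
    return {quadrat_col: qid, "mu_comm": mu, "sigma_comm": np.nan, "sigma_sum": np.nan,
            "community_stability": np.nan, "population_stability": np.nan,
            "asynchrony": np.nan, "degenerate": True}


def species_asynchrony(series: dict[str, np.ndarray], years) -> float:
    """Asynchrony of a single quadrat from per-species productivity series.

    ``series`` maps species to productivity vectors over the same intervals.
    Returns 0 for a single-species quadrat; NaN when every SD is zero.
    """
    years = np.asarray(years, dtype=float)
    mats = np.array([np.asarray(v, dtype=float) for v in series.values()])
    comm = mats.sum(axis=0)
    sigma_comm = detrended_sd(comm, years)
    sigs = np.array([detrended_sd(v, years) for v in mats])
    tot = sigs.sum()
    if tot == 0 or not np.isfinite(tot):
        return float("nan")
    if len(series) < 2:
        return 0.0
    return float(np.clip(1.0 - sigma_comm ** 2 / tot ** 2, 0.0, 1.0))


def interval_coarsen(matrix: pd.DataFrame, window: int,
                     quadrat_col: str = "quadrat_id") -> pd.DataFrame:
    """Aggregate annual productivity into non-overlapping multi-year windows.

    Productivity is summed within each window of ``window`` consecutive
    intervals; a trailing partial window is dropped (logged).  The window is
    labelled by its last calendar year.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    years = np.sort(matrix["year"].unique())
    n_full = len(years) // window
    if n_full == 0:
        raise ValueError("window longer than the available span")
    if len(years) % window:
        logger.info("dropping trailing partial window of %d intervals", len(years) % window)
    kept = years[: n_full * window]
    lab = {y: kept[(i // window) * window + window - 1] for i, y in enumerate(kept)}
    df = matrix[matrix["year"].isin(kept)].copy()
    df["year"] = df["year"].map(lab)
    out = (df.groupby([quadrat_col, "species_id", "year"], sort=True)["productivity"]
           .sum().reset_index())
    y2i = {y: i for i, y in enumerate(np.sort(out["year"].unique()))}
    out["interval"] = out["year"].map(y2i)
    return out[[quadrat_col, "species_id", "interval", "year", "productivity"]]
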