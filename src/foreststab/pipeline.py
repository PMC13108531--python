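"""End-to-end orchestration: simulate -> krige -> diversity -> stability ->
regressions -> neighborhood models -> piecewise SEM, with a manifest of
seeds and exclusion counts, plus the temporal-alignment and interval-
coarsening sensitivity reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, geostat, layout as layout_mod, psem, regression, simulate, stability

logger = logging.getLogger(__name__)

NUTRIENTS = ("organicP", "inorganicP", "organicN", "inorganicN")


@dataclass
class PipelineConfig:
    """Scenario + scale parameters of a synthetic end-to-end run."""

    scenario: str = "paper-like"
    seed: int = 0
    n_plots: int = 2                    # seedling 1-ha plots
    subplot_grid: int = 10
    quadrats_per_subplot: int = 4
    adult_width: float = 200.0
    adult_height: float = 200.0
    adult_quadrat: float = 20.0
    n_species: int = 40
    n_adults: int = 1500
    seedling_years: tuple = (2008, 2023)   # inclusive span, annual cadence
    adult_censuses: tuple = (2011, 2016, 2021, 2026, 2031)
    nutrient_range: float = 40.0
    nutrient_sill: float = 0.4
    nutrient_nugget: float = 0.05
    mc_draws: int = 0                   # kriging Monte-Carlo propagation draws
    n_boot: int = 2000
    out_dir: str | None = None

    def to_yaml(self) -> str:
        import yaml
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        import yaml
        d = yaml.safe_load(text) or {}
        cfg = cls(**d)
        for k in ("seedling_years", "adult_censuses"):
            setattr(cfg, k, tuple(getattr(cfg, k)))
        return cfg


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(master).integers(0, 2 ** 31 - 1, n)]


def simulate_scenario(cfg: PipelineConfig) -> dict:
    """Generate layouts, nutrient truths/observations and both census tables."""
    s = _seeds(cfg.seed, 8)
    quads = layout_mod.build_seedling_layout(
        cfg.n_plots, cfg.subplot_grid, cfg.quadrats_per_subplot)
    adult_layout = layout_mod.QuadratLayout(
        "adult", (0.0, 0.0), cfg.adult_width, cfg.adult_height, cfg.adult_quadrat)
    demos = simulate.scenario_params(cfg.scenario)
    pool = simulate.simulate_species_pool(cfg.n_species, "logseries", 0.95, seed=s[0])

    # adult-plot nutrient fields: truth on 20-m quadrat centres + sampled designs
    design = layout_mod.build_soil_sampling_design(adult_layout, seed=s[1])
    adult_truth, adult_obs = {}, {}
    for i, nut in enumerate(NUTRIENTS):
        params = simulate.NutrientFieldParams(
            mean=3.0 + 0.3 * i, sill=cfg.nutrient_sill, range_=cfg.nutrient_range,
            nugget=cfg.nutrient_nugget)
        truth, obs = simulate.simulate_nutrient_field(
            adult_layout, params, seed=s[2] + i, sample_points=design)
        adult_truth[nut] = truth.set_index("quadrat_id")["value"]
        obs = obs.rename(columns={"value": nut})
        adult_obs[nut] = obs[["point_id", "x", "y", "design_class", nut]]

    # seedling plots share one synthetic nutrient realisation per plot
    seed_truth = {nut: {} for nut in NUTRIENTS}
    plot_layouts = {}
    for pi, (p, grp) in enumerate(quads.groupby("plot_id", sort=True)):
        side = cfg.subplot_grid * 10.0
        plot_layouts[p] = layout_mod.QuadratLayout(p, (0.0, 0.0), side, side, 10.0)
        centers = grp[["x0", "y0"]].to_numpy() + 0.5
        for i, nut in enumerate(NUTRIENTS):
            params = simulate.NutrientFieldParams(
                mean=3.0 + 0.3 * i, sill=cfg.nutrient_sill,
                range_=cfg.nutrient_range / 4, nugget=cfg.nutrient_nugget)
            rng = np.random.default_rng(s[3] + 101 * i + 7919 * pi)
            vals = simulate.gaussian_random_field(centers, params, rng)
            seed_truth[nut][p] = pd.Series(vals, index=grp["quadrat_id"].to_numpy())

    # demographic series use the first scenario nutrient with non-null effects
    active = cfg.scenario != "null"
    drive_nut = "inorganicP" if active else NUTRIENTS[0]
    seed_nut_all = {nut: pd.concat(seed_truth[nut].values()) for nut in NUTRIENTS}
    seedlings = simulate.simulate_seedling_dynamics(
        quads, seed_nut_all[drive_nut], pool, demos[drive_nut],
        years=range(cfg.seedling_years[0], cfg.seedling_years[1] + 1), seed=s[4])
    adults = simulate.simulate_adult_dynamics(
        adult_layout, adult_truth[drive_nut], pool, demos[drive_nut],
        n_initial=cfg.n_adults, censuses=cfg.adult_censuses, seed=s[5])
    return {
        "quadrats": quads, "adult_layout": adult_layout, "pool": pool,
        "demographies": demos, "design": design,
        "adult_truth": adult_truth, "adult_obs": adult_obs,
        "seedling_truth": seed_nut_all, "seedlings": seedlings, "adults": adults,
        "seeds": s,
    }


def krige_adult_surfaces(sim: dict) -> tuple[pd.DataFrame, dict]:
    """Kriged X-hat and prediction variance per nutrient on the adult grid."""
    lay = sim["adult_layout"]
    targets = lay.quadrat_centers()
    qids = [f"q{i}" for i in range(len(targets))]
    out = pd.DataFrame({"quadrat_id": qids})
    models = {}
    for nut in NUTRIENTS:
        obs = sim["adult_obs"][nut]
        surf, model = geostat.krige_nutrient(obs, nut, targets, log_transform=False)
        out[nut] = surf["pred"].to_numpy()
        out[nut + "_var"] = surf["var"].to_numpy()
        models[nut] = model
    return out, models


def stage_metrics(census: pd.DataFrame, stage: str,
                  window: tuple[int, int] | None = None,
                  coarsen: int | None = None) -> pd.DataFrame:
    """Diversity + stability profile per quadrat for one stage."""
    df = census
    if window is not None:
        df = df[(df["census"] >= window[0]) & (df["census"] <= window[1])]
    pooled = df.sort_values("census").drop_duplicates("stem_id", keep="last")
    div = diversity.quadrat_diversity(pooled, stage)
    prod = stability.species_productivity(df, stage)
    if coarsen is not None:
        prod = stability.interval_coarsen(prod, coarsen)
    stab = stability.stability_profile(prod)
    out = div.merge(stab, on="quadrat_id", how="outer")
    return out


def nutrient_stability_models(metrics: pd.DataFrame, surface: pd.DataFrame,
                              stage: str, weights=None, n_boot: int = 2000,
                              seed: int = 0) -> dict[str, pd.DataFrame]:
    """Scaled multiple regressions of each stability/diversity response on the
    four nutrient forms (bootstrap CIs; SAR error model when weights given)."""
    df = metrics.merge(surface, on="quadrat_id", how="inner")
    responses = {
        "community_stability": np.log, "population_stability": np.log,
        "asynchrony": None, "diversity": None, "evenness": None, "S": None,
    }
    out = {}
    keep_base = ~df[list(NUTRIENTS)].isna().any(axis=1)
    for resp, tf in responses.items():
        y = df[resp].to_numpy(dtype=float)
        if tf is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                y = tf(y)
        keep = keep_base & np.isfinite(y)
        sub = df[keep]
        if len(sub) < 20:
            continue
        scaled, _ = regression.zscale_and_log(sub, scale_columns=list(NUTRIENTS))
        X = np.column_stack([np.ones(len(sub))]
                            + [scaled[n].to_numpy() for n in NUTRIENTS])
        names = ["Intercept"] + list(NUTRIENTS)
        if weights is not None:
            w = regression.subset_weights(weights, keep.to_numpy())
            fit = regression.sar_error_fit(X, y[keep.to_numpy()], w, names=names)
            out[resp] = fit.summary()
        else:
            out[resp] = regression.ols_bootstrap(
                X, y[keep.to_numpy()], n_boot=n_boot, seed=seed, names=names)
    return out


def psem_analysis(metrics: pd.DataFrame, surface: pd.DataFrame, stage: str,
                  subplot_of: pd.Series | None = None,
                  weights=None) -> dict:
    """AIC-selected piecewise SEM of nutrients -> diversity -> stability."""
    df = metrics.merge(surface, on="quadrat_id", how="inner")
    cols = {"S": "richness", "evenness": "evenness",
            "population_stability": "pop_stability", "asynchrony": "asynchrony",
            "community_stability": "comm_stability"}
    df = df.rename(columns=cols)
    for c in ("comm_stability", "pop_stability"):
        df[c] = np.log(df[c])
    use = ["richness", "evenness", "pop_stability", "asynchrony",
           "comm_stability", *NUTRIENTS]
    df = df.dropna(subset=use)
    keep_mask = metrics.merge(surface, on="quadrat_id", how="inner")[
        ["community_stability", "population_stability", "asynchrony", "S",
         "evenness"] + list(NUTRIENTS)].notna().all(axis=1).to_numpy()
    data = df[use].apply(lambda v: (v - v.mean()) / v.std(ddof=1))
    if subplot_of is not None:
        data = data.assign(subplot_id=df["quadrat_id"].map(subplot_of).to_numpy())
    candidates = {
        "richness": list(NUTRIENTS),
        "evenness": list(NUTRIENTS),
        "pop_stability": ["richness", "evenness", *NUTRIENTS],
        "asynchrony": ["richness", "evenness", *NUTRIENTS],
        "comm_stability": ["pop_stability", "asynchrony", "richness", "evenness"],
    }
    corr = {frozenset(p) for p in
            [(a, b) for i, a in enumerate(NUTRIENTS) for b in NUTRIENTS[i + 1:]]}
    specs = {}
    if subplot_of is not None:
        specs = {r: psem.ComponentSpec("lmm", group="subplot_id") for r in candidates}
    elif weights is not None:
        w = regression.subset_weights(weights, keep_mask)
        specs = {r: psem.ComponentSpec("sar", weights=w) for r in candidates}
    model = psem.select_component_models(candidates, data, specs, corr)
    dsep = psem.dsep_test(model, data, specs)
    effects = psem.standardized_effects(model)
    return {"model": model, "dsep": dsep, "effects": effects, "data": data}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Full synthetic reproduction workflow; returns the result bundle.

    When ``cfg.out_dir`` is set, per-stage CSV/JSON outputs and a manifest
    (seeds, record counts, exclusions) are written there.
    """
    sim = simulate_scenario(cfg)
    surface, vgmodels = krige_adult_surfaces(sim)
    seed_surface = pd.DataFrame({"quadrat_id": sim["seedling_truth"][NUTRIENTS[0]].index})
    for nut in NUTRIENTS:   # seedling plots: truth surface, zero kriging variance
        seed_surface[nut] = sim["seedling_truth"][nut].to_numpy()
        seed_surface[nut + "_var"] = 0.0

    seed_metrics = stage_metrics(sim["seedlings"], "seedling")
    adult_metrics = stage_metrics(sim["adults"], "adult")
    weights = regression.queen_weights(sim["adult_layout"])
    s = sim["seeds"]

    seed_models = nutrient_stability_models(
        seed_metrics, seed_surface, "seedling", n_boot=cfg.n_boot, seed=s[6])
    adult_models = nutrient_stability_models(
        adult_metrics, surface, "adult", weights=weights)

    subplot_of = (sim["quadrats"].set_index("quadrat_id")["subplot_id"])
    seed_sem = psem_analysis(seed_metrics, seed_surface, "seedling",
                             subplot_of=subplot_of)
    adult_sem = psem_analysis(adult_metrics, surface, "adult", weights=weights)

    neighborhood = {}
    drive = "inorganicP" if cfg.scenario != "null" else NUTRIENTS[0]
    design_s = regression.build_seedling_design(sim["seedlings"], seed_surface, drive)
    neighborhood["seedling"] = regression.fit_mixed_model(design_s)
    design_a = regression.build_adult_design(
        sim["adults"], surface, drive, sim["adult_layout"])
    neighborhood["adult"] = regression.fit_mixed_model(design_a)

    result = {
        "config": cfg, "sim": sim, "surface": surface, "variograms": vgmodels_dict(vgmodels),
        "seedling_metrics": seed_metrics, "adult_metrics": adult_metrics,
        "seedling_models": seed_models, "adult_models": adult_models,
        "seedling_sem": seed_sem, "adult_sem": adult_sem,
        "neighborhood": neighborhood,
    }
    if cfg.out_dir:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def vgmodels_dict(models: dict) -> dict:
    return {k: {"family": m.family, "nugget": m.nugget, "psill": m.psill,
                "range": m.range_} for k, m in models.items()}


def _write_outputs(result: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result["config"]
    result["seedling_metrics"].to_csv(out / "seedling_metrics.csv", index=False)
    result["adult_metrics"].to_csv(out / "adult_metrics.csv", index=False)
    result["surface"].to_csv(out / "adult_surface.csv", index=False)
    for stage in ("seedling", "adult"):
        for resp, tab in result[f"{stage}_models"].items():
            tab.to_csv(out / f"{stage}_reg_{resp}.csv", index=False)
        sem = result[f"{stage}_sem"]
        sem["effects"].to_csv(out / f"{stage}_sem_effects.csv", index=False)
        with open(out / f"{stage}_sem_fit.json", "w") as fh:
            json.dump({"C": sem["dsep"].C, "df": sem["dsep"].df, "p": sem["dsep"].p,
                       "r2": sem["model"].r2}, fh, indent=2)
        result["neighborhood"][stage].to_csv(out / f"{stage}_neighborhood.csv",
                                             index=False)
    manifest = {
        "config": asdict(cfg),
        "seeds": result["sim"]["seeds"],
        "n_seedling_records": int(len(result["sim"]["seedlings"])),
        "n_adult_records": int(len(result["sim"]["adults"])),
        "variograms": result["variograms"],
        "n_degenerate_seedling": int(result["seedling_metrics"]["degenerate"].sum()
                                     if "degenerate" in result["seedling_metrics"] else 0),
        "n_degenerate_adult": int(result["adult_metrics"]["degenerate"].sum()
                                  if "degenerate" in result["adult_metrics"] else 0),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def temporal_alignment_run(cfg: PipelineConfig, window: tuple[int, int]) -> dict:
    """Recompute seedling metrics inside a truncated window and compare models.

    Mirrors the alignment sensitivity check: identical definitions, shorter
    span.  Errors when the window holds fewer than 3 censuses.
    """
    if window[1] - window[0] + 1 < 3:
        raise ValueError("alignment window must contain at least 3 censuses")
    if not (cfg.seedling_years[0] <= window[0] <= window[1] <= cfg.seedling_years[1]):
        raise ValueError("window must lie inside the simulated span")
    sim = simulate_scenario(cfg)
    seed_surface = pd.DataFrame({"quadrat_id": sim["seedling_truth"][NUTRIENTS[0]].index})
    for nut in NUTRIENTS:
        seed_surface[nut] = sim["seedling_truth"][nut].to_numpy()
        seed_surface[nut + "_var"] = 0.0
    full = stage_metrics(sim["seedlings"], "seedling")
    trunc = stage_metrics(sim["seedlings"], "seedling", window=window)
    m_full = nutrient_stability_models(full, seed_surface, "seedling",
                                       n_boot=cfg.n_boot, seed=cfg.seed)
    m_trunc = nutrient_stability_models(trunc, seed_surface, "seedling",
                                        n_boot=cfg.n_boot, seed=cfg.seed)
    report = []
    for resp in m_full:
        if resp not in m_trunc:
            continue
        a = m_full[resp].set_index("term")["estimate"]
        b = m_trunc[resp].set_index("term")["estimate"]
        for term in a.index:
            report.append({"response": resp, "term": term,
                           "full": float(a[term]), "aligned": float(b.get(term, np.nan))})
    return {"full": m_full, "aligned": m_trunc, "report": pd.DataFrame(report)}
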