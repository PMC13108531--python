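"""Productivity construction, detrending, and the stability partition."""

import numpy as np
import pandas as pd
import pytest

from foreststab import stability as sb


def test_recruit_contributes_first_recorded_size(two_census_adults):
    prod = sb.species_productivity(two_census_adults, "adult", allometry=(1.0, 1.0))
    # with AGB = DBH, increments: t1 grows 2, t2 grows 0, t4 recruits at 2
    spA = prod[(prod.species_id == "spA")].productivity.sum()
    spB = prod[(prod.species_id == "spB")].productivity.sum()
    assert spA == pytest.approx(2.0)
    assert spB == pytest.approx(0.0 + 2.0)
    # dead stem t3 contributes nothing
    assert len(prod[prod.interval == 0]) == 2  # one row per species


def test_seedling_recruit_height_rule():
    df = pd.DataFrame({
        "stem_id": ["s1", "s1", "s2"],
        "species_id": ["a", "a", "a"],
        "quadrat_id": ["q"] * 3,
        "census": [2008, 2009, 2009],
        "height": [10.0, 16.0, 30.0],
        "dbh": np.nan,
        "status": ["alive", "alive", "recruited"],
    })
    prod = sb.species_productivity(df, "seedling")
    # survivor grows 6, recruit contributes its first recorded 30
    assert prod.productivity.sum() == pytest.approx(36.0)


def test_species_sums_conspecifics():
    df = pd.DataFrame({
        "stem_id": ["a", "a", "b", "b"],
        "species_id": ["s", "s", "s", "s"],
        "quadrat_id": ["q"] * 4,
        "census": [1, 2, 1, 2],
        "height": [10.0, 12.0, 20.0, 23.0],
        "dbh": np.nan, "status": "alive",
    })
    prod = sb.species_productivity(df, "seedling")
    assert prod.productivity.item() == pytest.approx(5.0)


@pytest.mark.parametrize("vals,years,expected", [
    ((1, 2, 3, 4), (1, 2, 3, 4), 0.0),        # exactly linear
    ((5, 5, 5, 5), (1, 2, 3, 4), 0.0),        # constant
    ((2, 4, 2, 4), (1, 2, 3, 4), np.sqrt(3.2 / 3)),  # slope 0.4, SS_res = 3.2
])
def test_detrended_sd_closed_form(vals, years, expected):
    assert sb.detrended_sd(vals, years) == pytest.approx(expected, abs=1e-12)


def test_detrended_sd_needs_three_points():
    assert np.isnan(sb.detrended_sd([1, 2], [1, 2]))


def _matrix_from_series(series: dict, years):
    rows = []
    for spid, v in series.items():
        for y, p in zip(years, v):
            rows.append({"quadrat_id": "q", "species_id": spid,
                         "interval": y - years[0], "year": y, "productivity": p})
    return pd.DataFrame(rows)


def test_asynchrony_mirror_and_proportional():
    years = np.arange(2008, 2014)
    mirror = {"a": [3, 5, 3, 5, 3, 5], "b": [5, 3, 5, 3, 5, 3]}
    assert sb.species_asynchrony(mirror, years) == pytest.approx(1.0)
    prop = {"a": [3, 5, 3, 5, 3, 5], "b": [6, 10, 6, 10, 6, 10]}
    assert sb.species_asynchrony(prop, years) == pytest.approx(0.0, abs=1e-12)
    single = {"a": [3, 5, 3, 5, 3, 5]}
    assert sb.species_asynchrony(single, years) == 0.0


def test_stability_ratios_and_scale_invariance(rng):
    years = np.arange(10)
    series = {f"s{i}": rng.normal(100, 10, 10) for i in range(3)}
    m1 = _matrix_from_series(series, years)
    m2 = m1.copy()
    m2["productivity"] *= 7.0    # uniform unit rescaling
    p1 = sb.stability_profile(m1).iloc[0]
    p2 = sb.stability_profile(m2).iloc[0]
    for k in ("community_stability", "population_stability", "asynchrony"):
        assert p1[k] == pytest.approx(p2[k], rel=1e-9)
    # single-species quadrat: population stability equals community stability
    ps = sb.stability_profile(_matrix_from_series({"only": series["s0"]}, years)).iloc[0]
    assert ps.community_stability == pytest.approx(ps.population_stability)


def test_community_stability_simulation_oracle(rng):
    # iid N(100, 10) community productivity -> stability ~ mu/sigma = 10
    vals = []
    for _ in range(40):
        series = {"a": rng.normal(100, 10, 12)}
        prof = sb.stability_profile(_matrix_from_series({"a": series["a"]}, np.arange(12)))
        vals.append(prof.iloc[0].community_stability)
    assert np.median(vals) == pytest.approx(10.0, rel=0.35)


def test_population_vs_community_scaling_in_species_number(rng):
    # k identical independent species: community stability grows ~ sqrt(k),
    # population stability stays flat
    def metrics(k, seed):
        r = np.random.default_rng(seed)
        series = {f"s{i}": r.normal(50, 5, 12) for i in range(k)}
        p = sb.stability_profile(_matrix_from_series(series, np.arange(12))).iloc[0]
        return p.community_stability, p.population_stability

    c1, p1 = np.mean([metrics(1, s) for s in range(30)], axis=0)
    c9, p9 = np.mean([metrics(9, s + 100) for s in range(30)], axis=0)
    assert c9 / c1 == pytest.approx(3.0, rel=0.35)   # sqrt(9)
    assert p9 / p1 == pytest.approx(1.0, rel=0.25)


def test_degenerate_quadrats_flagged():
    years = np.arange(5)
    m = _matrix_from_series({"a": [3.0, 4.0, 5.0, 6.0, 7.0]}, years)  # perfect trend
    prof = sb.stability_profile(m)
    assert prof.iloc[0].degenerate
    short = _matrix_from_series({"a": [1.0, 2.0]}, np.arange(2))
    assert sb.stability_profile(short).iloc[0].degenerate


def test_interval_coarsening_counts():
    years = np.arange(2008, 2023)   # 15 intervals
    m = _matrix_from_series({"a": np.arange(15.0)}, years)
    c = sb.interval_coarsen(m, 5)
    assert c.year.nunique() == 3
    # sums preserved over kept span
    assert c.productivity.sum() == pytest.approx(m.productivity.sum())
    c3 = sb.interval_coarsen(m, 4)   # 15 -> 3 full windows, partial dropped
    assert c3.year.nunique() == 3
    with pytest.raises(ValueError):
        sb.interval_coarsen(m, 1)
    with pytest.raises(ValueError):
        sb.interval_coarsen(m, 30)


def test_coarsening_to_full_span_degenerates():
    years = np.arange(2008, 2012)
    m = _matrix_from_series({"a": [1.0, 2.0, 1.5, 2.5]}, years)
    c = sb.interval_coarsen(m, 4)
    assert c.year.nunique() == 1
    assert sb.stability_profile(c).iloc[0].degenerate
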