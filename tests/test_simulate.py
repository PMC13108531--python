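"""Synthetic nutrient fields, species pools, and demographic dynamics."""

import numpy as np
import pandas as pd
import pytest

from foreststab import diversity as dv
from foreststab import layout as lm
from foreststab import simulate as sim
from foreststab import stability as sb


def _grid_coords(nx, ny, step):
    xx, yy = np.meshgrid(np.arange(nx) * step, np.arange(ny) * step)
    return np.column_stack([xx.ravel(), yy.ravel()])


def test_field_deterministic_under_seed():
    lay = lm.QuadratLayout("p", (0, 0), 100.0, 100.0, 20.0)
    params = sim.NutrientFieldParams(sill=1.0, range_=30.0, nugget=0.1)
    t1, _ = sim.simulate_nutrient_field(lay, params, seed=9)
    t2, _ = sim.simulate_nutrient_field(lay, params, seed=9)
    pd.testing.assert_frame_equal(t1, t2)


def test_pure_nugget_field_has_flat_variogram():
    from foreststab import geostat as gs
    params = sim.NutrientFieldParams(mean=0.0, sill=1.0, range_=10.0, nugget=1.0)
    coords = _grid_coords(15, 15, 5.0)
    gammas = []
    for s in range(10):
        rng = np.random.default_rng(s)
        z = sim.gaussian_random_field(coords, params, rng)
        pts = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
        emp = gs.empirical_variogram(pts, z, np.linspace(1, 60, 7))
        gammas.append(emp.gamma.to_numpy())
    mean_gamma = np.nanmean(gammas, axis=0)
    assert np.allclose(mean_gamma, 1.0, rtol=0.2)   # flat at the sill


def test_field_variance_near_sill():
    params = sim.NutrientFieldParams(mean=5.0, sill=2.0, range_=8.0, nugget=0.0)
    coords = _grid_coords(50, 25, 10.0)   # large grid, short range
    var = []
    for s in range(5):
        z = sim.gaussian_random_field(coords, params, np.random.default_rng(s))
        var.append(z.var())
    assert np.mean(var) == pytest.approx(2.0, rel=0.2)


def test_non_positive_definite_covariance_raises():
    with pytest.raises(ValueError):
        sim.NutrientFieldParams(sill=0.5, nugget=1.0)   # nugget above sill


@pytest.mark.parametrize("model", ["logseries", "geometric"])
def test_species_pool_normalised_and_monotone(model):
    p = sim.simulate_species_pool(25, model, 0.9, seed=0)
    assert p.sum() == pytest.approx(1.0)
    assert (np.diff(p) <= 1e-15).all()
    assert len(sim.simulate_species_pool(1, model, 0.5)) == 1
    assert sim.simulate_species_pool(1, model, 0.5)[0] == pytest.approx(1.0)


def test_logseries_pool_less_even_than_uniform():
    p = sim.simulate_species_pool(20, "logseries", 0.98, seed=1)
    H = dv.shannon_entropy(p)
    assert dv.hill_evenness(H, 20) < 1.0 - 1e-6


def test_invalid_shape_rejected():
    with pytest.raises(ValueError):
        sim.simulate_species_pool(10, "logseries", 1.5)


def _tiny_setup(n_q=60, seed=0):
    quads = lm.build_seedling_layout(1, 10, 4).head(n_q)
    rng = np.random.default_rng(seed)
    nut = pd.Series(rng.normal(3, 0.5, n_q), index=quads["quadrat_id"].to_numpy())
    pool = sim.simulate_species_pool(15, "logseries", 0.9, seed=2)
    return quads, nut, pool


def test_saturating_intercept_means_all_survive():
    quads, nut, pool = _tiny_setup()
    params = sim.DemographyParams(surv_intercept=20.0, b_csd=0.0, b_hsd=0.0,
                                  b_height=0.0, sd_species=0.0, sd_subplot=0.0,
                                  sd_year=0.0)
    census = sim.simulate_seedling_dynamics(quads, nut, pool, params,
                                            years=range(2008, 2012), seed=3)
    # every stem present at one census must appear at the next
    for t, t1 in [(2008, 2009), (2009, 2010)]:
        now = set(census[census.census == t].stem_id)
        nxt = set(census[census.census == t1].stem_id)
        assert now <= nxt


def test_dynamics_deterministic_under_seed():
    quads, nut, pool = _tiny_setup()
    params = sim.DemographyParams()
    a = sim.simulate_seedling_dynamics(quads, nut, pool, params,
                                       years=range(2008, 2013), seed=11)
    b = sim.simulate_seedling_dynamics(quads, nut, pool, params,
                                       years=range(2008, 2013), seed=11)
    pd.testing.assert_frame_equal(a, b)


def test_census_records_satisfy_schema():
    quads, nut, pool = _tiny_setup()
    census = sim.simulate_seedling_dynamics(quads, nut, pool,
                                            sim.DemographyParams(),
                                            years=range(2008, 2013), seed=4)
    assert (census.height > 0).all()
    assert not census.duplicated(["stem_id", "census"]).any()
    assert set(census.status) <= {"alive", "recruited", "dead"}


def test_adult_dynamics_schema_and_determinism():
    lay = lm.QuadratLayout("a", (0, 0), 100.0, 100.0, 20.0)
    rng = np.random.default_rng(0)
    nut = pd.Series(rng.normal(3, 0.5, lay.n_quadrats),
                    index=[f"q{i}" for i in range(lay.n_quadrats)])
    pool = sim.simulate_species_pool(10, "logseries", 0.9, seed=1)
    a = sim.simulate_adult_dynamics(lay, nut, pool, sim.DemographyParams(),
                                    n_initial=150, seed=5)
    b = sim.simulate_adult_dynamics(lay, nut, pool, sim.DemographyParams(),
                                    n_initial=150, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert (a.dbh >= 1.0).all()
    assert not a.duplicated(["stem_id", "census"]).any()


def test_asynchrony_raises_community_stability_across_quadrats():
    # communities simulated with species-independent year responses (low
    # synchrony) should sit higher on the stability-vs-asynchrony gradient
    quads, nut, pool = _tiny_setup(n_q=80)
    profs = []
    for syn in (0.95, 0.05):
        params = sim.DemographyParams(synchrony=syn, recruit_rate=4.0)
        census = sim.simulate_seedling_dynamics(quads, nut, pool, params,
                                                years=range(2008, 2020), seed=21)
        prod = sb.species_productivity(census, "seedling")
        prof = sb.stability_profile(prod)
        profs.append(prof[~prof.degenerate])
    pooled = pd.concat(profs)
    from scipy.stats import spearmanr
    rho, _ = spearmanr(pooled.asynchrony, np.log(pooled.community_stability))
    assert rho > 0


def test_interaction_sign_recovery_single_replicate():
    # strong negative heterospecific x nutrient interaction recovered by the
    # survival GLMM from one mid-sized simulation
    from foreststab import regression as rg
    quads = lm.build_seedling_layout(2, 10, 4)
    rng = np.random.default_rng(7)
    nut = pd.Series(rng.normal(3, 0.7, len(quads)),
                    index=quads["quadrat_id"].to_numpy())
    pool = sim.simulate_species_pool(25, "logseries", 0.95, seed=8)
    params = sim.DemographyParams(b_hsd_nut=-0.3)
    census = sim.simulate_seedling_dynamics(quads, nut, pool, params,
                                            years=range(2008, 2015), seed=9)
    surface = pd.DataFrame({"quadrat_id": nut.index, "nut": nut.to_numpy()})
    design = rg.build_seedling_design(census, surface, "nut")
    res = rg.fit_mixed_model(design).set_index("term")
    assert res.loc["HSDxNut", "estimate"] < 0
    assert res.loc["HSDxNut", "estimate"] / res.loc["HSDxNut", "se"] < -2
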