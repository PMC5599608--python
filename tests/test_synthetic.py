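"""Synthetic world generators: masks, covariate fields, surveys, walks."""

import numpy as np
import pandas as pd
import pytest

import sealusage as su
from sealusage.grid import GridSpec
from sealusage.synthetic import (
    SyntheticWorld,
    _gaussian_field,
    gen_haulouts_and_counts,
    tidal_power,
)


class TestGenGrid:
    def test_land_fraction_near_target(self):
        g = su.gen_grid(50, 50, 0.3, seed=1)
        assert 0.2 <= g.land.mean() <= 0.4

    def test_zero_land_fraction_gives_all_sea(self):
        g = su.gen_grid(20, 20, 0.0, seed=1)
        assert g.land.sum() == 0

    def test_deterministic_under_seed(self):
        a = su.gen_grid(30, 30, 0.25, seed=42)
        b = su.gen_grid(30, 30, 0.25, seed=42)
        assert np.array_equal(a.land, b.land)

    def test_sea_is_connected(self):
        from scipy import ndimage

        g = su.gen_grid(50, 50, 0.35, seed=3)
        _, n = ndimage.label(g.sea, structure=np.ones((3, 3), int))
        assert n == 1


class TestCovariates:
    def test_tidal_power_formula(self):
        # half * 1027 kg/m3 * (1 m/s)^3
        assert tidal_power(1.0) == pytest.approx(513.5)
        assert tidal_power(2.0) == pytest.approx(0.5 * 1027 * 8.0)

    def test_compositional_closure_and_positivity(self, small_world):
        cov = small_world.covariates
        total = cov["sand"] + cov["gravel"] + cov["mud"]
        assert np.abs(total - 1).max() < 1e-9
        assert (cov["tidal_power"] >= 0).all()
        assert (cov["depth"] >= 0).all()
        assert (cov["peak_spring_flow"] > cov["peak_neap_flow"]).all()

    def test_variogram_range_increases_autocorrelation(self):
        grid = su.GridSpec(80, 80, np.zeros((80, 80), bool))
        short = su.gen_covariates(grid, variogram_range_m=1800.0, seed=5)["sand"]
        long_ = su.gen_covariates(grid, variogram_range_m=3600.0, seed=5)["sand"]

        def semivariance(f, lag):
            return 0.5 * np.mean((f[:, lag:] - f[:, :-lag]) ** 2)

        # with longer correlation range the field varies less over a fixed lag
        for lag in (2, 4, 6):
            assert semivariance(long_, lag) < semivariance(short, lag)


class TestHaulOutsAndCounts:
    def test_full_coverage_counts_everything(self):
        g = su.gen_grid(40, 40, 0.3, seed=2)
        sites, counts, survey = gen_haulouts_and_counts(
            g, n_sites=5, total_population=100, survey_coverage=1.0, seed=3, min_separation_m=3000
        )
        assert counts.sum() == 100
        assert survey["count"].sum() == 100
        assert not survey["count"].isna().any()

    def test_single_site_gets_all_mass(self):
        g = su.gen_grid(40, 40, 0.3, seed=2)
        sites, counts, survey = gen_haulouts_and_counts(
            g, n_sites=1, total_population=50, survey_coverage=1.0, seed=3
        )
        assert len(sites) == 1 and counts[0] == 50

    def test_unsurveyed_distinct_from_surveyed_zero(self):
        g = su.gen_grid(40, 40, 0.3, seed=2)
        _, _, survey = gen_haulouts_and_counts(
            g, n_sites=3, total_population=60, survey_coverage=0.5, seed=3, min_separation_m=3000
        )
        surveyed = survey.dropna(subset=["count"])
        unsurveyed = survey[survey["count"].isna()]
        assert len(unsurveyed) > 0 and len(surveyed) > 0
        assert (surveyed["count"] >= 0).all()
        assert unsurveyed["survey_year"].isna().all()
        assert surveyed["survey_year"].between(2008, 2015).all()

    def test_sites_are_coastal_land(self, small_world):
        g = small_world.grid
        for r, c in small_world.haulout_cells:
            assert g.land[r, c]
            assert len(g.adjacent_sea(r, c)) > 0


def _uniform_world(grid, beta, seed=0):
    """A world with flat covariates except those named in beta overrides."""
    cov = su.CovariateStack(grid)
    shape = (grid.nrows, grid.ncols)
    rng = np.random.default_rng(seed)
    cov["sand"] = 0.5 + 0.3 * np.tanh(_gaussian_field(shape, 5.0, rng))
    cov["gravel"] = (1 - cov["sand"]) / 2
    cov["mud"] = (1 - cov["sand"]) / 2
    cov["tidal_power"] = 500.0 + 200.0 * _gaussian_field(shape, 5.0, rng)
    cov["tidal_power"] = np.abs(cov["tidal_power"])
    cov["depth"] = np.full(shape, 30.0)
    coastal = grid.coastal_land_cells()
    site = tuple(coastal[len(coastal) // 2])
    sea = grid.sea
    std = {
        name: (float(cov[name][sea].mean()), float(cov[name][sea].std() + 1e-12))
        for name in ("sand", "tidal_power")
    }
    return SyntheticWorld(
        grid=grid,
        covariates=cov,
        haulout_cells=[site],
        true_counts=np.array([20]),
        survey=pd.DataFrame({"row": [site[0]], "col": [site[1]], "count": [20.0], "survey_year": [2012.0]}),
        true_beta=beta,
        seed=seed,
        standardisation=std,
    )


def _island_grid(n=31):
    land = np.zeros((n, n), bool)
    land[n // 2, n // 2] = True
    return GridSpec(n, n, land)


class TestSimulateTracks:
    def test_fix_spacing_and_lifespan(self, small_tracks):
        fixes, meta = small_tracks
        for aid, g in fixes.groupby("animal_id"):
            dt = g["timestamp"].diff().dropna().dt.total_seconds() / 3600.0
            assert (dt == 2.0).all()
            life = meta.loc[meta["animal_id"] == aid, "lifespan_h"].iloc[0]
            span = (g["timestamp"].iloc[-1] - g["timestamp"].iloc[0]).total_seconds() / 3600.0
            assert span <= life

    def test_deterministic_under_seed(self, small_world):
        a, _ = su.simulate_tracks(small_world, 3, seed=5)
        b, _ = su.simulate_tracks(small_world, 3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_distance_decay_confines_fixes(self):
        world = _uniform_world(_island_grid(), {"distance": -10.0, "sand": 0.0, "tidal_power": 0.0})
        fixes, _ = su.simulate_tracks(world, 4, mean_lifespan_h=1000.0, seed=9, tagged_site_fraction=1.0)
        at_sea = fixes[~fixes["at_haulout"]]
        hx, hy = world.grid.centre_of(*world.haulout_cells[0])
        d = np.hypot(at_sea["x_m"] - hx, at_sea["y_m"] - hy)
        assert (d <= 5 * world.grid.cell_size).mean() >= 0.95

    def test_no_preference_shows_no_selectivity(self):
        # with beta = 0 a distance-controlled count regression of occupancy
        # on (standardised) sand finds no habitat effect
        import statsmodels.api as sm

        world = _uniform_world(_island_grid(), {"distance": 0.0, "sand": 0.0, "tidal_power": 0.0}, seed=1)
        fixes, _ = su.simulate_tracks(
            world, 6, mean_lifespan_h=3000.0, seed=13, mean_trip_steps=60, tagged_site_fraction=1.0
        )
        at_sea = fixes[~fixes["at_haulout"]]
        r, c = world.grid.cell_of(at_sea["x_m"].to_numpy(), at_sea["y_m"].to_numpy())
        grid = world.grid
        counts = np.zeros((grid.nrows, grid.ncols))
        np.add.at(counts, (r, c), 1)
        dist = su.atsea_distance(grid, [world.haulout_cells[0]]).values
        near = grid.sea & np.isfinite(dist) & (dist < 6000.0)
        X = np.column_stack([np.ones(near.sum()), dist[near] / 1000.0, world.sea_zscore("sand")[near]])
        res = sm.GLM(counts[near], X, family=sm.families.Poisson()).fit()
        assert abs(res.params[2]) < 0.3

    def test_preference_recoverable_from_occupancy(self):
        from scipy.stats import spearmanr

        world = _uniform_world(_island_grid(), {"distance": -0.2, "sand": 2.0, "tidal_power": 0.0}, seed=2)
        fixes, _ = su.simulate_tracks(
            world, 8, mean_lifespan_h=4000.0, seed=17, mean_trip_steps=40, tagged_site_fraction=1.0
        )
        at_sea = fixes[~fixes["at_haulout"]]
        r, c = world.grid.cell_of(at_sea["x_m"].to_numpy(), at_sea["y_m"].to_numpy())
        grid = world.grid
        counts = np.zeros((grid.nrows, grid.ncols))
        np.add.at(counts, (r, c), 1)
        dist = su.atsea_distance(grid, [world.haulout_cells[0]]).values
        score = (
            world.true_beta["distance"] * dist / 1000.0
            + world.true_beta["sand"] * world.sea_zscore("sand")
        )
        near = grid.sea & np.isfinite(dist) & (dist < 6000.0)
        rho, _ = spearmanr(counts[near], np.exp(score[near]))
        assert rho > 0.5
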