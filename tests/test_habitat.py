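"""Habitat GEE: design assembly, splines, panel-robust fits and FPS CV."""

import numpy as np
import pandas as pd
import pytest

import sealusage as su
from sealusage.grid import GridSpec
from sealusage.habitat import (
    CVReport,
    bootstrap_response,
    build_design_matrix,
    fit_gee,
    fold_test,
    forward_select,
    fps_score,
    make_folds,
    sample_pseudo_absences,
    spline_basis,
    standardise,
    vif_screen,
)
from sealusage.seadist import DistanceSurface

from oracles import cluster_sandwich_oracle, deboor_oracle, logistic_newton_oracle


def _presences(n, cluster_id=0, year=2011, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "animal_id": [f"A{i % 4}" for i in range(n)],
            "cluster_id": cluster_id,
            "year": year,
            "row": rng.integers(0, 20, n),
            "col": rng.integers(0, 20, n),
        }
    )


class TestPseudoAbsences:
    def test_exact_ratio(self):
        cells = np.argwhere(np.ones((20, 20), bool))
        design = sample_pseudo_absences(_presences(100), {0: cells}, ratio=5, seed=1)
        assert (design["response"] == 0).sum() == 500
        assert len(design) == 600

    def test_deterministic_under_seed(self):
        cells = np.argwhere(np.ones((20, 20), bool))
        a = sample_pseudo_absences(_presences(50), {0: cells}, seed=3)
        b = sample_pseudo_absences(_presences(50), {0: cells}, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_pseudo_absence_panels_unique(self):
        cells = np.argwhere(np.ones((20, 20), bool))
        design = sample_pseudo_absences(_presences(40), {0: cells}, seed=2)
        pa = design[design["response"] == 0]
        assert pa["panel"].nunique() == len(pa)
        pres = design[design["response"] == 1]
        assert pres["panel"].nunique() == pres["animal_id"].nunique()

    def test_sampling_matches_availability_distribution(self):
        # empirical CDF of a covariate over drawn cells vs exact enumeration
        rng = np.random.default_rng(4)
        values = rng.random((30, 30))
        cells = np.argwhere(np.ones((30, 30), bool))
        design = sample_pseudo_absences(_presences(20000, seed=5), {0: cells}, ratio=5, seed=6)
        pa = design[design["response"] == 0]
        sample = np.sort(values[pa["row"], pa["col"]])
        pop = np.sort(values.ravel())
        grid_pts = np.linspace(0, 1, 201)
        F_s = np.searchsorted(sample, grid_pts) / len(sample)
        F_p = np.searchsorted(pop, grid_pts) / len(pop)
        assert np.abs(F_s - F_p).max() < 0.05

    def test_unreachable_cluster_raises(self):
        with pytest.raises(ValueError, match="cluster 0"):
            sample_pseudo_absences(_presences(5), {0: np.empty((0, 2), int)})


class TestVif:
    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.standard_normal(10000), "b": rng.standard_normal(10000)})
        vifs, pairs = vif_screen(df)
        assert (vifs < 1.1).all()
        assert pairs == []

    def test_near_collinear_matches_analytic(self):
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal(5000)
        x2 = x1 + 0.01 * rng.standard_normal(5000)
        df = pd.DataFrame({"x1": x1, "x2": x2, "z": rng.standard_normal(5000)})
        vifs, pairs = vif_screen(df)
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert vifs["x2"] > 100
        assert vifs["x2"] == pytest.approx(1 / (1 - r2), rel=0.05)
        assert ("x1", "x2") in pairs

    def test_exact_collinearity_infinite(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"x1": x, "x2": x.copy(), "z": rng.standard_normal(100)})
        vifs, pairs = vif_screen(df)
        assert np.isinf(vifs["x1"]) and np.isinf(vifs["x2"])
        assert ("x1", "x2") in pairs


class TestStandardise:
    def test_basic_example(self):
        z, (m, s) = standardise(np.array([1.0, 2.0, 3.0]))
        assert m == 2.0 and s == 1.0  # sample sd, denominator n-1
        assert np.allclose(z, [-1, 0, 1])

    def test_round_trip_properties(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 7, 1000)
        z, params = standardise(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12
        z2, _ = standardise(np.array([50.0]), params)  # prediction-time reuse
        assert z2[0] == pytest.approx((50.0 - params[0]) / params[1])


class TestSplineBasis:
    def test_four_columns_one_interior_knot_at_mean(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(200)
        B, knots = spline_basis(z)
        assert B.shape == (200, 4)
        assert knots["interior"] == [pytest.approx(z.mean())]
        assert knots["boundary"] == (pytest.approx(z.min()), pytest.approx(z.max()))

    def test_partition_of_unity_of_full_family(self):
        from sealusage.habitat import bspline_full_basis

        rng = np.random.default_rng(7)
        z = rng.uniform(-2, 2, 300)
        _, knots = spline_basis(z)
        full = bspline_full_basis(z, knots)
        assert np.abs(full.sum(axis=1) - 1).max() < 1e-12

    def test_matches_deboor_recursion(self):
        rng = np.random.default_rng(8)
        z = rng.uniform(-3, 3, 120)
        B, knots = spline_basis(z)
        a, b = knots["boundary"]
        t = [a] * 4 + knots["interior"] + [b] * 4
        for i, x in enumerate(rng.uniform(a, b, 100)):
            row, _ = spline_basis(np.array([x]), knots=knots)
            for j in range(4):
                assert row[0, j] == pytest.approx(deboor_oracle(float(x), t, 3, j + 1), abs=1e-12)

    def test_prediction_outside_boundary_clamped(self):
        z = np.linspace(-1, 1, 50)
        B, knots = spline_basis(z)
        with pytest.warns(UserWarning, match="clamp"):
            out, _ = spline_basis(np.array([5.0]), knots=knots)
        edge, _ = spline_basis(np.array([1.0]), knots=knots)
        assert np.allclose(out, edge)


def _logistic_design(n=200, seed=0, n_years=2):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "year": rng.integers(2010, 2010 + n_years, n),
            "distance": rng.normal(5000, 2000, n),
            "sand": rng.random(n),
            "cluster_id": rng.integers(0, 5, n),
        }
    )
    eta = 0.5 - 0.3 * standardise(df["distance"].to_numpy())[0] + 0.8 * standardise(df["sand"].to_numpy())[0]
    df["response"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df["panel"] = [f"p{i}" for i in range(n)]  # singleton panels
    return df


class TestFitGee:
    def test_matches_newton_raphson_oracle(self):
        df = _logistic_design(200, seed=1)
        model = fit_gee(df, [("year", "factor"), ("distance", "linear"), ("sand", "linear")])
        X, _ = build_design_matrix(df, model.terms, model.standardisation, model.splines, model.year_levels)
        beta_oracle = logistic_newton_oracle(X, df["response"].to_numpy(float))
        assert np.abs(model.beta - beta_oracle).max() < 1e-8

    def test_singleton_panels_give_hc0_sandwich(self):
        df = _logistic_design(300, seed=2)
        model = fit_gee(df, [("year", "factor"), ("distance", "linear")])
        X, _ = build_design_matrix(df, model.terms, model.standardisation, model.splines, model.year_levels)
        panels = np.arange(len(df))
        V_oracle = cluster_sandwich_oracle(X, df["response"].to_numpy(float), model.beta, panels)
        assert np.abs(model.cov - V_oracle).max() < 1e-10

    def test_animal_panels_match_cluster_sandwich_oracle(self):
        df = _logistic_design(400, seed=3)
        df["panel"] = [f"animal:{i % 7}" for i in range(len(df))]
        model = fit_gee(df, [("year", "factor"), ("distance", "linear"), ("sand", "linear")])
        X, _ = build_design_matrix(df, model.terms, model.standardisation, model.splines, model.year_levels)
        panels = pd.factorize(df["panel"])[0]
        V_oracle = cluster_sandwich_oracle(X, df["response"].to_numpy(float), model.beta, panels)
        assert np.abs(model.cov - V_oracle).max() < 1e-10

    def test_duplicating_panels_leaves_beta_unchanged(self):
        df = _logistic_design(150, seed=4)
        doubled = pd.concat([df, df.assign(panel=df["panel"] + "_copy")], ignore_index=True)
        m1 = fit_gee(df, [("year", "factor"), ("distance", "linear")])
        m2 = fit_gee(doubled, [("year", "factor"), ("distance", "linear")])
        # standardisation sds differ slightly (ddof=1 on 2n rows), so compare
        # on the raw covariate scale where the likelihood is identical
        b1 = m1.beta.copy()
        b1[-1] /= m1.standardisation["distance"][1]
        b2 = m2.beta.copy()
        b2[-1] /= m2.standardisation["distance"][1]
        assert np.abs(b1 - b2).max() < 1e-8

    def test_single_class_raises(self):
        df = _logistic_design(100, seed=5)
        df["response"] = 1
        with pytest.raises(ValueError, match="classes"):
            fit_gee(df, [("year", "factor"), ("distance", "linear")])

    def test_separation_raises(self):
        df = _logistic_design(100, seed=6)
        df["response"] = (df["distance"] > df["distance"].median()).astype(int)
        with pytest.raises(ValueError, match="converge"):
            fit_gee(df, [("year", "factor"), ("distance", "linear")])


class TestMakeFolds:
    def test_equal_clusters_balanced(self):
        counts = {i: 10 for i in range(10)}
        folds = make_folds(counts, k=5, seed=1)
        sizes = pd.Series(folds).value_counts()
        assert (sizes == 2).all()

    def test_presence_balance_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            counts = {i: int(rng.integers(5, 50)) for i in range(12)}
            folds = make_folds(counts, k=5, seed=rng)
            loads = pd.Series({f: sum(counts[c] for c, ff in folds.items() if ff == f) for f in range(5)})
            assert loads.max() / loads.min() <= 2.0

    def test_every_cluster_in_exactly_one_fold(self):
        counts = {i: 5 + i for i in range(9)}
        folds = make_folds(counts, k=5, seed=3)
        assert set(folds) == set(counts)


class TestFoldTest:
    def test_perfect_concordance_passes(self):
        pred = np.linspace(1, 10, 200)
        obs = pred**2  # strictly increasing in prediction
        rho, p, passed = fold_test(pred, obs)
        assert rho == pytest.approx(1.0)
        assert passed

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        pred = rng.random(300)
        obs = rng.poisson(2, 300)
        r1 = fold_test(pred, obs)
        r2 = fold_test(np.exp(5 * pred), obs)
        assert r1 == pytest.approx(r2)

    def test_few_cells_reduce_bins_with_warning(self):
        with pytest.warns(UserWarning, match="reducing bins"):
            fold_test(np.arange(10.0), np.arange(10.0))


def _fold_scenario(informative_clusters=4, noise_clusters=1, seed=0):
    """A 5-cluster design: 4 predictable held-out blocks, the rest hopeless
    (constant covariates, so held-out predictions cannot rank cells)."""
    rng = np.random.default_rng(seed)
    frames = []
    for cid in range(informative_clusters + noise_clusters):
        n = 600
        if cid < informative_clusters:
            dist = rng.uniform(0, 20000, n)
        else:
            dist = np.full(n, 5000.0)
        eta = 1.5 - 4.0 * dist / 20000
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "response": y,
                    "panel": [f"c{cid}p{i}" for i in range(n)],
                    "cluster_id": cid,
                    "year": 2011,
                    "row": np.arange(n) // 40,
                    "col": np.arange(n) % 40,
                    "distance": dist,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestFps:
    def test_four_of_five_folds_give_point_eight(self):
        design = _fold_scenario(seed=1)
        folds = {cid: cid for cid in range(5)}
        report = fps_score(design, [("year", "factor"), ("distance", "linear")], folds)
        passed = [f[2] for f in report.folds]
        assert passed == [True, True, True, True, False]
        assert report.fps == pytest.approx(0.8)

    def test_fps_values_are_fifths(self):
        report = CVReport(folds=[(1, 0.01, True)] * 3 + [(0, 0.5, False)] * 2, fps=3 / 5)
        assert report.fps in {0.0, 0.2, 0.4, 0.6, 0.8, 1.0}


class TestForwardSelect:
    def _selection_design(self, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for cid in range(5):
            n = 400
            dist = rng.uniform(0, 20000, n)
            good = rng.standard_normal(n)
            eta = 0.5 - 1.0 * dist / 20000 + 1.5 * good
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "response": y,
                        "panel": [f"c{cid}p{i}" for i in range(n)],
                        "cluster_id": cid,
                        "year": 2011,
                        "row": np.arange(n) // 40,
                        "col": np.arange(n) % 40,
                        "distance": dist,
                        "good_a": good,
                        "good_b": good.copy(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_no_candidates_returns_base(self):
        design = self._selection_design(1)
        folds = {cid: cid for cid in range(5)}
        model, trace = forward_select(design, [], folds)
        assert [t for t in model.terms] == [("year", "factor"), ("distance", "linear")]
        assert len(trace) == 1

    def test_tie_goes_to_earlier_declared_candidate(self):
        design = self._selection_design(2)
        folds = {cid: cid for cid in range(5)}
        model, trace = forward_select(design, ["good_b", "good_a"], folds)
        selected = [t["term"] for t in trace.to_dict("records") if t["selected"] and t["step"] > 0]
        if selected:  # identical columns tie exactly; earlier name wins
            assert selected[0] == "good_b"

    def test_informative_candidate_selected(self):
        design = self._selection_design(3)
        folds = {cid: cid for cid in range(5)}
        model, trace = forward_select(design, ["good_a"], folds)
        names = {t[0] for t in model.terms}
        assert "good_a" in names


class TestPrediction:
    def _distance_surface(self):
        land = np.zeros((20, 20), bool)
        land[10, 0] = True
        grid = GridSpec(20, 20, land)
        return su.atsea_distance(grid, [(10, 0)])

    def test_negative_distance_model_monotone_and_normalised(self):
        dist = self._distance_surface()
        df = _logistic_design(400, seed=9)
        model = fit_gee(df, [("year", "factor"), ("distance", "linear")])
        from sealusage.habitat import predict_null_cluster

        cov = su.CovariateStack(dist.grid)
        u = predict_null_cluster(model, dist, cov)
        assert u.sum() == pytest.approx(1.0, abs=1e-9)
        sea = dist.reachable()
        order = np.argsort(dist.values[sea])
        vals = u[sea][order]
        sign = np.sign(model.beta[model.colnames.index("distance")])
        diffs = np.diff(vals)
        assert (diffs <= 1e-15).all() if sign < 0 else (diffs >= -1e-15).all()

    def test_covariate_shift_invariance(self):
        # adding a constant to a covariate field and refitting changes
        # nothing after standardisation
        df = _logistic_design(500, seed=10)
        shifted = df.copy()
        shifted["sand"] = shifted["sand"] + 10.0
        terms = [("year", "factor"), ("distance", "linear"), ("sand", "spline")]
        m1 = fit_gee(df, terms)
        m2 = fit_gee(shifted, terms)
        lp1 = m1.linear_predictor(df)
        lp2 = m2.linear_predictor(shifted)
        assert np.abs(lp1 - lp2).max() < 1e-6


class TestBootstrapResponse:
    def test_zero_covariance_collapses_interval(self):
        df = _logistic_design(300, seed=11)
        model = fit_gee(df, [("year", "factor"), ("distance", "linear"), ("sand", "linear")])
        model.cov = np.zeros_like(model.cov)
        curve = bootstrap_response(model, "sand", n_boot=100, seed=1)
        assert np.allclose(curve["lower95"], curve["response"])
        assert np.allclose(curve["upper95"], curve["response"])

    def test_interval_width_grows_with_covariance(self):
        df = _logistic_design(300, seed=12)
        model = fit_gee(df, [("year", "factor"), ("distance", "linear"), ("sand", "linear")])
        c1 = bootstrap_response(model, "sand", n_boot=2000, seed=2)
        model.cov = model.cov * 4.0
        c2 = bootstrap_response(model, "sand", n_boot=2000, seed=2)
        w1 = (c1["upper95"] - c1["lower95"]).mean()
        w2 = (c2["upper95"] - c2["lower95"]).mean()
        assert w2 > w1

    def test_band_covers_truth_on_well_specified_fit(self):
        rng = np.random.default_rng(13)
        cover = []
        for rep in range(20):
            df = _logistic_design(800, seed=100 + rep)
            model = fit_gee(df, [("year", "factor"), ("distance", "linear"), ("sand", "linear")])
            curve = bootstrap_response(model, "sand", n_boot=500, seed=rep)
            zs, _ = standardise(curve["sand"].to_numpy(), model.standardisation["sand"])
            # prediction fixes distance at its mean (z = 0) and year at the
            # reference level, so the generating curve reduces to 0.5 + 0.8 z
            truth = np.exp(0.5 + 0.8 * zs)
            inside = (curve["lower95"] <= truth) & (truth <= curve["upper95"])
            cover.append(inside.mean())
        assert np.mean(cover) >= 0.8
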