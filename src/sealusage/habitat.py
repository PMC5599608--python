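"""Presence/pseudo-absence habitat preference model with panel-robust inference.

At-sea telemetry fixes (presences) are contrasted with pseudo-absences drawn
from the sea cells available to the same haul-out cluster (five per presence).
The model is a binomial logit GEE with an *independence* working correlation:
point estimates coincide with the ordinary logistic maximum-likelihood fit
and uncertainty comes from a panel-clustered sandwich covariance.  Panels are
individual animals for presences while every pseudo-absence is its own panel.

The linear predictor always contains deployment year (factor) and at-sea
distance (linear); remaining environmental covariates are offered as linear
terms or cubic B-spline smooths (4 degrees of freedom, one interior knot at
the covariate mean, boundary knots at the training extremes).  Covariates are
standardised (mean 0, sd 1) before basis construction and the parameters kept
for prediction.  Forward selection adds the term with the largest gain in the
fold pass score (FPS) of a 5-fold haul-out-cluster-blocked cross-validation:
a fold passes when the Spearman correlation between 40 equal-count bins of
predicted usage and the binned presence counts is significantly positive
(one-sided, alpha = 0.05); FPS = passed folds / 5.

Predicted usage for a haul-out cluster with no telemetry ("null" cluster) is
the exponential of the linear predictor over cells reachable from that
cluster, year fixed at the training median, normalised to sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .grid import GridSpec, CovariateStack
from .seadist import DistanceSurface

logger = logging.getLogger(__name__)

BASE_TERMS = (("year", "factor"), ("distance", "linear"))
DEFAULT_PSEUDO_ABSENCE_RATIO = 5
VIF_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# standardisation and spline bases


def standardise(x: np.ndarray, params: tuple[float, float] | None = None):
    """z = (x - mean) / sd with sample sd (ddof=1); params reusable at prediction.

    Returns ``(z, (mean, sd))``.  Zero-sd input raises at fit time (the
    caller drops the covariate with a warning).
    """
    x = np.asarray(x, dtype=float)
    if params is None:
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        if s <= 0:
            raise ValueError("covariate has zero standard deviation")
        params = (m, s)
    m, s = params
    return (x - m) / s, params


def spline_basis(
    z: np.ndarray, df: int = 4, knots: dict | None = None
) -> tuple[np.ndarray, dict]:
    """Cubic B-spline basis columns, intercept excluded.

    Fit-time (``knots is None``): boundary knots at the data min/max and
    ``df - 3`` interior knots — for the default df=4 a single interior knot
    at the *mean* of the (standardised) covariate.  The full order-4 basis on
    that knot vector has df+1 functions; dropping the first leaves ``df``
    columns, the usual intercept-free parameterisation.  Prediction-time
    values outside the boundary knots are clamped to the boundary (warned).

    Returns ``(basis, knots)`` with the knot dictionary reusable at
    prediction time.
    """
    z = np.asarray(z, dtype=float)
    if df < 4:
        raise ValueError("cubic spline basis needs df >= 4")
    if knots is None:
        a, b = float(np.min(z)), float(np.max(z))
        if not b > a:
            raise ValueError("degenerate covariate: no spread for spline knots")
        if df == 4:
            interior = [float(np.mean(z))]
        else:
            qs = np.linspace(0, 1, df - 2)[1:-1]
            interior = [float(v) for v in np.quantile(z, qs)]
        knots = {"boundary": (a, b), "interior": interior}
    else:
        a, b = knots["boundary"]
        interior = list(knots["interior"])
        if (z < a - 1e-12).any() or (z > b + 1e-12).any():
            warnings.warn("spline evaluation outside boundary knots; clamping")
    zc = np.clip(z, a, b)
    t = np.array([a] * 4 + interior + [b] * 4, dtype=float)
    M = BSpline.design_matrix(zc, t, k=3, extrapolate=False)
    if scipy.sparse.issparse(M):
        M = M.toarray()
    return M[:, 1:], knots


def bspline_full_basis(z: np.ndarray, knots: dict) -> np.ndarray:
    """The complete (partition-of-unity) B-spline family, for diagnostics."""
    a, b = knots["boundary"]
    t = np.array([a] * 4 + list(knots["interior"]) + [b] * 4, dtype=float)
    M = BSpline.design_matrix(np.clip(np.asarray(z, float), a, b), t, k=3, extrapolate=False)
    return M.toarray() if scipy.sparse.issparse(M) else np.asarray(M)


# ---------------------------------------------------------------------------
# design assembly


def sample_pseudo_absences(
    presences: pd.DataFrame,
    reachable_cells: dict[int, np.ndarray],
    ratio: int = DEFAULT_PSEUDO_ABSENCE_RATIO,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Design rows: each presence plus ``ratio`` pseudo-absences.

    ``presences`` needs columns ``animal_id, cluster_id, year, row, col``.
    Pseudo-absences are drawn uniformly (with replacement) from the sea cells
    reachable from the presence's haul-out cluster and inherit its year and
    cluster; each gets a unique panel id, while presence rows share their
    animal's panel.  Covariates are attached separately
    (:func:`attach_covariates`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    pa_counter = 0
    for r in presences.itertuples():
        cid = int(r.cluster_id)
        cells = reachable_cells.get(cid)
        if cells is None or len(cells) == 0:
            raise ValueError(f"no reachable sea cells for haul-out cluster {cid}")
        rows.append(
            dict(
                response=1,
                panel=f"animal:{r.animal_id}",
                animal_id=str(r.animal_id),
                cluster_id=cid,
                year=int(r.year),
                row=int(r.row),
                col=int(r.col),
            )
        )
        picks = rng.integers(0, len(cells), size=ratio)
        for p in picks:
            rr, cc = cells[p]
            rows.append(
                dict(
                    response=0,
                    panel=f"pa:{pa_counter}",
                    animal_id=str(r.animal_id),
                    cluster_id=cid,
                    year=int(r.year),
                    row=int(rr),
                    col=int(cc),
                )
            )
            pa_counter += 1
    return pd.DataFrame(rows)


def attach_covariates(
    design: pd.DataFrame,
    covariates: CovariateStack,
    distance_surfaces: dict[int, DistanceSurface],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Add environmental covariates and cluster-specific at-sea distance."""
    df = design.copy()
    r = df["row"].to_numpy(int)
    c = df["col"].to_numpy(int)
    names = covariates.names() if names is None else names
    for name in names:
        df[name] = covariates[name][r, c]
    dist = np.empty(len(df))
    for cid, g in df.groupby("cluster_id"):
        surf = distance_surfaces[int(cid)].values
        dist[g.index.to_numpy()] = surf[g["row"].to_numpy(int), g["col"].to_numpy(int)]
    df["distance"] = dist
    if not np.isfinite(df["distance"]).all():
        bad = int((~np.isfinite(df["distance"])).sum())
        raise ValueError(f"{bad} design rows fall on cells unreachable from their cluster")
    return df


def vif_screen(covariates: pd.DataFrame, threshold: float = VIF_THRESHOLD):
    """Variance inflation factors and mutually exclusive covariate pairs.

    VIF_j = 1 / (1 - R^2_j) from regressing covariate j (with intercept) on
    the others.  For every covariate above the threshold the most correlated
    partner is flagged; flagged pairs may not enter the same model.
    """
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    n, p = X.shape
    if p < 2:
        raise ValueError("vif_screen needs at least two covariates")
    if n <= p:
        raise ValueError("vif_screen needs more rows than covariates")
    vifs = {}
    for j in range(p):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        vifs[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    corr = np.corrcoef(X, rowvar=False)
    pairs: set[frozenset] = set()
    for j, name in enumerate(names):
        if vifs[name] > threshold:
            partner = int(np.argmax(np.abs(corr[j]) - 2.0 * np.eye(p)[j]))
            pairs.add(frozenset((name, names[partner])))
    return pd.Series(vifs), sorted(tuple(sorted(p)) for p in pairs)


# ---------------------------------------------------------------------------
# model


@dataclass
class HabitatModel:
    """A fitted habitat preference model (logit GEE, independence working corr.)."""

    terms: list[tuple[str, str]]  # (name, 'factor' | 'linear' | 'spline')
    beta: np.ndarray
    cov: np.ndarray
    colnames: list[str]
    standardisation: dict[str, tuple[float, float]]
    splines: dict[str, dict]
    year_levels: list[int]
    median_year: int
    naive_cov: np.ndarray | None = None

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = build_design_matrix(df, self.terms, self.standardisation, self.splines, self.year_levels)
        return X @ self.beta

    def to_dict(self) -> dict:
        return {
            "terms": [list(t) for t in self.terms],
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "colnames": self.colnames,
            "standardisation": {k: list(v) for k, v in self.standardisation.items()},
            "splines": {
                k: {"boundary": list(v["boundary"]), "interior": list(v["interior"])}
                for k, v in self.splines.items()
            },
            "year_levels": self.year_levels,
            "median_year": self.median_year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HabitatModel":
        return cls(
            terms=[tuple(t) for t in d["terms"]],
            beta=np.asarray(d["beta"], float),
            cov=np.asarray(d["cov"], float),
            colnames=list(d["colnames"]),
            standardisation={k: tuple(v) for k, v in d["standardisation"].items()},
            splines={
                k: {"boundary": tuple(v["boundary"]), "interior": list(v["interior"])}
                for k, v in d["splines"].items()
            },
            year_levels=[int(y) for y in d["year_levels"]],
            median_year=int(d["median_year"]),
        )


def build_design_matrix(
    df: pd.DataFrame,
    terms: list[tuple[str, str]],
    standardisation: dict[str, tuple[float, float]],
    splines: dict[str, dict],
    year_levels: list[int],
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for name, kind in terms:
        if kind == "factor":
            yr = df["year"].to_numpy(int)
            for level in year_levels[1:]:
                cols.append((yr == level).astype(float))
                names.append(f"year[{level}]")
        elif kind == "linear":
            z, _ = standardise(df[name].to_numpy(), standardisation[name])
            cols.append(z)
            names.append(name)
        elif kind == "spline":
            z, _ = standardise(df[name].to_numpy(), standardisation[name])
            B, _ = spline_basis(z, knots=splines[name])
            for j in range(B.shape[1]):
                cols.append(B[:, j])
                names.append(f"{name}.s{j + 1}")
        else:
            raise ValueError(f"unknown term kind {kind!r}")
    return np.column_stack(cols), names


def _prepare_spec(
    design: pd.DataFrame, terms: list[tuple[str, str]]
) -> tuple[dict[str, tuple[float, float]], dict[str, dict], list[int]]:
    """Training-time standardisation, spline knots and year levels."""
    standardisation: dict[str, tuple[float, float]] = {}
    splines: dict[str, dict] = {}
    for name, kind in terms:
        if kind == "factor":
            continue
        _, params = standardise(design[name].to_numpy())
        standardisation[name] = params
        if kind == "spline":
            z, _ = standardise(design[name].to_numpy(), params)
            _, knots = spline_basis(z)
            splines[name] = knots
    year_levels = sorted(int(y) for y in design["year"].unique())
    return standardisation, splines, year_levels


def fit_gee(design: pd.DataFrame, terms: list[tuple[str, str]] | None = None) -> HabitatModel:
    """Binomial logit fit with panel-clustered sandwich covariance.

    With an independence working correlation the GEE point estimates are the
    ordinary Bernoulli logistic MLE; the covariance is the panel-clustered
    sandwich (no small-sample correction, so singleton panels reduce it to
    HC0).  Raises on separation / non-convergence with a diagnostic.
    """
    terms = list(BASE_TERMS) if terms is None else list(terms)
    y = design["response"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both response classes must be present")
    standardisation, splines, year_levels = _prepare_spec(design, terms)
    X, colnames = build_design_matrix(design, terms, standardisation, splines, year_levels)
    groups = pd.factorize(design["panel"])[0]
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(
                cov_type="cluster",
                cov_kwds={"groups": groups, "use_correction": False},
                maxiter=200,
            )
        except Exception as e:  # statsmodels raises PerfectSeparation / LinAlg errors
            raise ValueError(f"habitat model failed to converge (separation?): {e}") from e
    if not (np.isfinite(res.params).all() and np.isfinite(res.cov_params()).all()):
        raise ValueError("habitat model failed to converge: non-finite estimates")
    if np.abs(res.params).max() > 50:
        raise ValueError("habitat model failed to converge: quasi-separation (huge coefficients)")
    return HabitatModel(
        terms=terms,
        beta=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        colnames=colnames,
        standardisation=standardisation,
        splines=splines,
        year_levels=year_levels,
        median_year=int(np.median(design.loc[design["response"] == 1, "year"])),
        naive_cov=np.asarray(model.fit().cov_params()),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    folds: list[tuple[float, float, bool]]  # (rho, p, passed)
    fps: float


def make_folds(
    presence_counts: dict[int, int], k: int = 5, seed: int | np.random.Generator = 0, max_retries: int = 100
) -> dict[int, int]:
    """Partition haul-out clusters into k blocks balanced on presence counts.

    Greedy bin-packing over a shuffled cluster order: each cluster goes to the
    currently lightest fold, so no cluster is ever split across folds.
    Reshuffles if some fold ends with zero presences.
    """
    if len(presence_counts) < k:
        raise ValueError(f"need at least {k} clusters for {k} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = sorted(presence_counts)
    for _ in range(max_retries):
        order = rng.permutation(len(ids))
        loads = np.zeros(k)
        assign: dict[int, int] = {}
        for i in order:
            f = int(np.argmin(loads))
            assign[ids[i]] = f
            loads[f] += presence_counts[ids[i]]
        if (loads > 0).all():
            return assign
    raise ValueError("could not build folds with presences in every fold")


def _bin_edges(n: int, n_bins: int) -> list[int]:
    """Sizes of equal-count bins; the remainder is spread over leading bins."""
    q, r = divmod(n, n_bins)
    return [q + 1] * r + [q] * (n_bins - r)


def fold_test(
    predicted: np.ndarray, observed: np.ndarray, n_bins: int = 40, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Binned Spearman test of observed-vs-predicted concordance for one fold.

    Cells are sorted by prediction and partitioned into ``n_bins`` equal-count
    bins (remainder spread over the leading bins); per bin the mean predicted
    value and the summed observed presences are correlated (Spearman).  The
    fold passes when the one-sided p-value for positive association is below
    ``alpha``.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    n = len(predicted)
    if n < n_bins:
        warnings.warn(f"only {n} cells in fold; reducing bins from {n_bins}")
        n_bins = max(2, n)
    order = np.argsort(predicted, kind="stable")
    sizes = _bin_edges(n, n_bins)
    mean_pred, sum_obs = [], []
    start = 0
    for sz in sizes:
        idx = order[start : start + sz]
        mean_pred.append(predicted[idx].mean())
        sum_obs.append(observed[idx].sum())
        start += sz
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan rho -> fail below
        rho, p = stats.spearmanr(mean_pred, sum_obs, alternative="greater")
    if np.isnan(rho):
        return 0.0, 1.0, False
    return float(rho), float(p), bool(p < alpha)


def fps_score(
    design: pd.DataFrame,
    terms: list[tuple[str, str]],
    folds: dict[int, int],
    n_bins: int = 40,
    alpha: float = 0.05,
) -> CVReport:
    """Fold pass score of a model specification under cluster-blocked CV.

    For each fold the model is refit on the other folds and usage
    ``exp(linear predictor)`` is predicted for the held-out cells (cells
    visited by held-out presences and their pseudo-absences, keyed by
    cluster and cell); per-cell observed presence counts are compared with
    the prediction through :func:`fold_test`.  FPS = passed folds / k.
    """
    k = max(folds.values()) + 1
    results = []
    for f in range(k):
        test_clusters = {cid for cid, ff in folds.items() if ff == f}
        train = design[~design["cluster_id"].isin(test_clusters)]
        test = design[design["cluster_id"].isin(test_clusters)]
        if train.empty or test.empty or test["response"].max() == 0:
            results.append((0.0, 1.0, False))
            continue
        try:
            model = fit_gee(train, terms)
        except ValueError:
            results.append((0.0, 1.0, False))
            continue
        cells = (
            test.groupby(["cluster_id", "row", "col"], sort=True)
            .agg(response=("response", "sum"))
            .reset_index()
        )
        feat = test.drop_duplicates(subset=["cluster_id", "row", "col"]).drop(columns=["response"])
        cells = cells.merge(feat, on=["cluster_id", "row", "col"], how="left")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = np.exp(model.linear_predictor(cells))
        results.append(fold_test(pred, cells["response"].to_numpy(), n_bins=n_bins, alpha=alpha))
    fps = sum(r[2] for r in results) / k
    return CVReport(folds=results, fps=fps)


def forward_select(
    design: pd.DataFrame,
    candidates: list[str],
    folds: dict[int, int],
    exclusion_pairs: list[tuple[str, str]] | None = None,
    base_terms: tuple = BASE_TERMS,
    n_bins: int = 40,
    alpha: float = 0.05,
) -> tuple[HabitatModel, pd.DataFrame]:
    """Forward selection on FPS over linear and spline variants of candidates.

    At each step the candidate (in either variant) with the largest FPS
    increase joins the model; ties go to the candidate listed earlier (and to
    the linear variant within a candidate).  Selection stops when no addition
    increases the FPS.  Returns the final model refit on all data and the
    selection trace.
    """
    excluded = {frozenset(p) for p in (exclusion_pairs or [])}
    terms = list(base_terms)
    base_report = fps_score(design, terms, folds, n_bins=n_bins, alpha=alpha)
    if base_report.fps == 0:
        raise ValueError("base model (year + at-sea distance) has FPS 0; selection aborted")
    trace = [dict(step=0, term="<base>", variant="", fps=base_report.fps, selected=True)]
    current_fps = base_report.fps
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        best = None  # (fps, cand_index, variant_index, name, kind)
        for ci, name in enumerate(remaining):
            in_model = {t[0] for t in terms}
            if any(frozenset((name, other)) in excluded for other in in_model):
                continue
            for vi, kind in enumerate(("linear", "spline")):
                try:
                    rep = fps_score(design, terms + [(name, kind)], folds, n_bins=n_bins, alpha=alpha)
                except ValueError:
                    continue
                trace.append(dict(step=step, term=name, variant=kind, fps=rep.fps, selected=False))
                key = (-rep.fps, ci, vi)
                if best is None or key < best[0]:
                    best = (key, name, kind, rep.fps)
        if best is None or best[3] <= current_fps:
            break
        _, name, kind, fps = best
        terms.append((name, kind))
        remaining.remove(name)
        current_fps = fps
        for t in trace:
            if t["step"] == step and t["term"] == name and t["variant"] == kind:
                t["selected"] = True
    final = fit_gee(design, terms)
    return final, pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# prediction


def predict_null_cluster(
    model: HabitatModel,
    distance_surface: DistanceSurface,
    covariates: CovariateStack,
    year: int | None = None,
) -> np.ndarray:
    """Normalised predicted usage surface for a (null) haul-out cluster.

    exp(linear predictor) over sea cells reachable from the cluster, with the
    cluster's own at-sea distance surface as the distance covariate and year
    fixed at the training median; unreachable cells are zero and the surface
    sums to one.
    """
    grid = distance_surface.grid
    reach = distance_surface.reachable()
    rows, cols = np.nonzero(reach)
    df = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "year": (model.median_year if year is None else int(year)),
            "distance": distance_surface.values[rows, cols],
        }
    )
    for name, kind in model.terms:
        if kind != "factor" and name != "distance":
            df[name] = covariates[name][rows, cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lp = model.linear_predictor(df)
    lp = lp - lp.max()  # guard against overflow; normalisation removes the shift
    usage = np.zeros((grid.nrows, grid.ncols))
    usage[rows, cols] = np.exp(lp)
    total = usage.sum()
    if total <= 0:
        raise ValueError("predicted usage is identically zero")
    return usage / total


def bootstrap_response(
    model: HabitatModel,
    covariate: str,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Parametric-bootstrap response curve with pointwise 95% CI.

    Draws beta* ~ N(beta, V) and evaluates exp(linear predictor) over a grid
    of the focal covariate with other covariates at their training means and
    factors at the reference level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if covariate not in {t[0] for t in model.terms}:
        raise ValueError(f"{covariate!r} is not a model term")
    m, s = model.standardisation[covariate]
    if covariate in model.splines:
        a, b = model.splines[covariate]["boundary"]
    else:
        a, b = -2.0, 2.0
    zgrid = np.linspace(a, b, n_grid)
    df = pd.DataFrame({covariate: m + s * zgrid})
    df["year"] = model.year_levels[0]
    df["distance"] = model.standardisation.get("distance", (0.0, 1.0))[0]
    for name, kind in model.terms:
        if kind != "factor" and name not in df:
            df[name] = model.standardisation[name][0]
    X, _ = build_design_matrix(df, model.terms, model.standardisation, model.splines, model.year_levels)
    V = np.asarray(model.cov)
    if np.allclose(V, 0):
        draws = np.tile(model.beta, (n_boot, 1))
    else:
        jitter = 0.0
        for _ in range(4):
            try:
                L = np.linalg.cholesky(V + jitter * np.eye(len(V)))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-10)
        else:
            raise ValueError("model covariance is not positive semi-definite")
        draws = model.beta + rng.standard_normal((n_boot, len(model.beta))) @ L.T
    curves = np.exp(draws @ X.T)
    point = np.exp(X @ model.beta)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {covariate: df[covariate], "response": point, "lower95": lo, "upper95": hi}
    )
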