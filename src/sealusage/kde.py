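"""Kernel density usage surfaces with discovery-rate weighting.

Each animal's at-sea fixes are smoothed into a continuous usage surface with
a bivariate normal kernel.  The 2x2 bandwidth matrix is selected per animal
(pooling all of the animal's at-sea locations) by an unconstrained plug-in
selector: the fourth-order integrated density derivative functionals are
estimated on sphered data with a normal-scale pilot and the asymptotic MISE
is minimised numerically over symmetric positive-definite matrices.  A
normal-scale (Silverman-type) matrix is the fallback for degenerate inputs.

Animals contribute unequally: tags live for days to months, and long tag
records cover more ground.  The *discovery rate* (index of information
content) — the number of new grid cells an animal visited during its tag's
lifespan — is modelled by an overdispersed Poisson log-link regression on a
smooth of tag lifespan plus tag type, and the fitted rates, normalised
within each haul-out cluster, weight the per-animal surfaces in the cluster
aggregate.  Every cluster usage surface is renormalised to sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .grid import GridSpec
from .habitat import spline_basis, standardise

logger = logging.getLogger(__name__)

_HERMITE = {
    0: lambda t: np.ones_like(t),
    1: lambda t: t,
    2: lambda t: t * t - 1.0,
    3: lambda t: t**3 - 3.0 * t,
    4: lambda t: t**4 - 6.0 * t * t + 3.0,
}


@dataclass
class UsageSurface:
    """Nonnegative per-cell intensity on the analysis grid.

    ``state`` tracks normalisation: 'per-animal' and 'per-cluster' surfaces
    sum to one over sea cells; 'seal-units' surfaces integrate to expected
    seals.
    """

    grid: GridSpec
    values: np.ndarray
    state: str = "per-animal"

    def total(self) -> float:
        return float(self.values.sum())


def normal_scale_bandwidth(points: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Normal-scale bandwidth matrix H = n^(-1/3) * Sigma (d = 2)."""
    n = len(points)
    S = np.cov(points, rowvar=False, ddof=1)
    if ridge > 0:
        S = S + ridge * np.eye(2)
    return float(n) ** (-1.0 / 3.0) * S


def _psi_functionals(Y: np.ndarray, g: float) -> dict[tuple[int, int], float]:
    """Fourth-order density derivative functionals psi_r on sphered data.

    psi_r = n^-2 sum_ij D^r phi_{g^2 I}(Y_i - Y_j), evaluated pairwise with a
    scalar pilot g; D^(a,b) of a product Gaussian is the Hermite form
    phi(u)phi(v) g^-(a+b) He_a(u/g) He_b(v/g).
    """
    n = len(Y)
    du = (Y[:, None, 0] - Y[None, :, 0]) / g
    dv = (Y[:, None, 1] - Y[None, :, 1]) / g
    base = np.exp(-0.5 * (du * du + dv * dv)) / (2.0 * np.pi * g * g)
    out = {}
    for a, b in [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]:
        term = base * _HERMITE[a](du) * _HERMITE[b](dv) / g ** (a + b)
        out[(a, b)] = float(term.sum()) / (n * n)
    return out


def _amise(h11: float, h12: float, h22: float, psi: dict, n: int) -> float:
    det = h11 * h22 - h12 * h12
    if det <= 0:
        return np.inf
    var_term = 1.0 / (4.0 * np.pi * n * np.sqrt(det))
    b = (
        h11 * h11 * psi[(4, 0)]
        + 4.0 * h11 * h12 * psi[(3, 1)]
        + (2.0 * h11 * h22 + 4.0 * h12 * h12) * psi[(2, 2)]
        + 4.0 * h12 * h22 * psi[(1, 3)]
        + h22 * h22 * psi[(0, 4)]
    )
    return var_term + 0.25 * b


def select_bandwidth(
    points: np.ndarray, method: str = "plugin", max_pairs_n: int = 2000, seed: int = 0
) -> np.ndarray:
    """Plug-in 2x2 bandwidth matrix for one animal's at-sea positions.

    The data are sphered with the sample covariance, psi functionals are
    estimated with a normal-scale pilot g = n^(-1/8), and the AMISE is
    minimised over SPD matrices (Cholesky parameterisation, started at the
    normal-scale matrix).  Subsamples to ``max_pairs_n`` points for the
    O(n^2) functional estimates.  ``method='normal-scale'`` or degenerate
    inputs give the normal-scale matrix (ridged if necessary, with warning).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(points)
    if n < 10:
        raise ValueError("bandwidth selection needs at least 10 points")
    S = np.cov(points, rowvar=False, ddof=1)
    scale = max(np.abs(points).max(), 1.0)
    if np.linalg.det(S) <= (1e-8 * scale) ** 4 or not np.isfinite(S).all():
        warnings.warn("degenerate point cloud; falling back to ridged normal-scale bandwidth")
        return normal_scale_bandwidth(points, ridge=(1e-3 * scale) ** 2)
    if method == "normal-scale":
        return normal_scale_bandwidth(points)
    if method != "plugin":
        raise ValueError(f"unknown bandwidth method {method!r}")

    A = np.linalg.cholesky(S)
    Y = np.linalg.solve(A, points.T).T  # sphered: unit sample covariance
    if n > max_pairs_n:
        rng = np.random.default_rng(seed)
        Y = Y[rng.choice(n, size=max_pairs_n, replace=False)]
    g = float(len(Y)) ** (-1.0 / 8.0)
    psi = _psi_functionals(Y, g)

    h0 = float(n) ** (-1.0 / 3.0)  # normal-scale on sphered data

    def objective(theta: np.ndarray) -> float:
        l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        return _amise(l11 * l11, l11 * l21, l21 * l21 + l22 * l22, psi, n)

    x0 = np.array([0.5 * np.log(h0), 0.0, 0.5 * np.log(h0)])
    res = optimize.minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    theta = res.x if np.isfinite(res.fun) and res.fun < objective(x0) else x0
    l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
    Hs = np.array([[l11 * l11, l11 * l21], [l11 * l21, l21 * l21 + l22 * l22]])
    H = A @ Hs @ A.T
    H = 0.5 * (H + H.T)
    if np.linalg.det(H) <= 0 or not np.isfinite(H).all():
        warnings.warn("plug-in optimisation failed; falling back to normal-scale bandwidth")
        return normal_scale_bandwidth(points)
    return H


def kde_surface(points: np.ndarray, H: np.ndarray, grid: GridSpec, chunk: int = 512) -> UsageSurface:
    """Per-animal usage surface: bivariate normal KDE on sea-cell centres.

    The kernel mixture is evaluated at cell centres, multiplied by the cell
    area, masked to sea and renormalised to one.  Raises if effectively all
    kernel mass falls on land.
    """
    points = np.asarray(points, dtype=float)
    H = np.asarray(H, dtype=float)
    evals = np.linalg.eigvalsh(H)
    if evals.min() <= 0:
        raise ValueError("bandwidth matrix must be symmetric positive-definite")
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))
    sea_rc = grid.sea_cells()
    cx, cy = grid.centre_of(sea_rc[:, 0], sea_rc[:, 1])
    centres = np.column_stack([cx, cy])
    dens = np.zeros(len(centres))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        d = centres[:, None, :] - p[None, :, :]
        q = (
            d[:, :, 0] * (Hinv[0, 0] * d[:, :, 0] + Hinv[0, 1] * d[:, :, 1])
            + d[:, :, 1] * (Hinv[1, 0] * d[:, :, 0] + Hinv[1, 1] * d[:, :, 1])
        )
        dens += norm * np.exp(-0.5 * q).sum(axis=1)
    dens *= grid.cell_area / len(points)
    total = dens.sum()
    if total <= 1e-12:
        raise ValueError("kernel mass falls entirely on land / outside the grid")
    values = np.zeros((grid.nrows, grid.ncols))
    values[sea_rc[:, 0], sea_rc[:, 1]] = dens / total
    return UsageSurface(grid=grid, values=values, state="per-animal")


def discovery_rate(track: pd.DataFrame, grid: GridSpec) -> int:
    """Number of distinct sea cells holding at least one at-sea fix."""
    at_sea = track[~track["at_haulout"].astype(bool)]
    if at_sea.empty:
        return 0
    r, c = grid.cell_of(at_sea["x_m"].to_numpy(), at_sea["y_m"].to_numpy())
    ok = grid.in_bounds(r, c)
    r, c = r[ok], c[ok]
    sea = grid.sea[r, c]
    return int(len(set(zip(r[sea].tolist(), c[sea].tolist()))))


def fit_weight_model(rates: pd.DataFrame, tag_meta: pd.DataFrame) -> pd.DataFrame:
    """Fitted discovery rates from lifespan and tag type.

    Quasi-Poisson (log link, Pearson-estimated dispersion) regression of the
    discovery rate on a fixed-df cubic spline of tag lifespan plus a tag-type
    factor.  Returns per-animal rows with ``fitted_rate``; weights are later
    normalised within each cluster's contributing animals.  A single tag type
    drops the factor (logged); zero lifespan spread drops the smooth.
    """
    df = rates.merge(tag_meta[["animal_id", "tag_type", "lifespan_h"]], on="animal_id", how="left")
    if df["lifespan_h"].isna().any():
        missing = df.loc[df["lifespan_h"].isna(), "animal_id"].tolist()
        raise ValueError(f"tag metadata missing for animals: {missing}")
    n = len(df)
    if n < 8:
        raise ValueError("weight model needs at least 8 animals")
    cols = [np.ones(n)]
    life = df["lifespan_h"].to_numpy(float)
    if np.std(life, ddof=1) > 0:
        z, params = standardise(life)
        if len(np.unique(life)) >= 5:
            B, _ = spline_basis(z)
            cols.extend(B.T)
        else:
            cols.append(z)
    types = df["tag_type"].unique()
    if len(types) > 1:
        ref = sorted(types)[0]
        for t in sorted(types)[1:]:
            cols.append((df["tag_type"] == t).to_numpy(float))
    else:
        logger.info("single tag type %s; factor dropped from weight model", types[0])
    X = np.column_stack(cols)
    y = df["discovery_rate"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    df = df.copy()
    df["fitted_rate"] = res.predict(X)
    # quasi-Poisson: Pearson-estimated overdispersion (affects inference only;
    # the point fit is identical to the Poisson likelihood fit)
    df.attrs["dispersion"] = (
        float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    )
    return df


def cluster_usage(
    surfaces: dict[str, UsageSurface], fitted_rates: dict[str, float]
) -> tuple[UsageSurface, dict[str, float]]:
    """Aggregate one cluster's per-animal surfaces with normalised weights.

    Weights are the animals' fitted discovery rates normalised to sum to one
    over the cluster's contributors; the weighted mixture is renormalised to
    one.  Returns the cluster surface and the weights used.
    """
    if not surfaces:
        raise ValueError("cluster has no animal surfaces")
    animals = sorted(surfaces)
    w = np.array([float(fitted_rates[a]) for a in animals])
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("fitted rates must be positive and finite")
    w = w / w.sum()
    grid = surfaces[animals[0]].grid
    acc = np.zeros((grid.nrows, grid.ncols))
    for a, wa in zip(animals, w):
        s = surfaces[a]
        if s.values.shape != acc.shape:
            raise ValueError("surfaces on mismatched grids")
        acc += wa * s.values
    total = acc.sum()
    if total <= 0:
        raise ValueError("aggregated surface has zero mass")
    out = UsageSurface(grid=grid, values=acc / total, state="per-cluster")
    return out, dict(zip(animals, w))
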