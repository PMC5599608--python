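"""Uncertainty propagation and population scaling of usage surfaces.

Three variance sources are combined per grid cell:

* *within-cluster* variance — how much the normalised usage surface would
  change with different tagged animals.  Modelled from data-rich telemetry
  clusters (>= 7 tagged animals by default): the per-cell empirical variance
  across animals' surfaces is regressed (log scale, so predictions stay
  positive) on log mean usage and the number of tagged animals; data-poor
  and null clusters are predicted with sample size 0.
* *population* variance — cluster counts divided by a bootstrap of haul-out
  probability (the proportion of the population ashore during a survey),
  drawn from a moment-matched beta distribution.
* the two are combined by the independent-product formula for Var(N u) and
  scaled by the mean fraction of time animals spend at sea.

Cells get normal-approximation 95% intervals truncated below at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kde import UsageSurface

logger = logging.getLogger(__name__)

DATA_RICH_MIN_ANIMALS = 7
EPS = 1e-12

#: default haul-out probability (mean, sd): the fraction of the population
#: ashore during an August moult count.  Configurable; site-specific
#: estimates should replace it for real data.
DEFAULT_HAULOUT_PROB = (0.72, 0.05)


@dataclass
class VarianceModel:
    """log(variance + eps) ~ a + b*log(mean + eps) + c*n_animals."""

    coef: np.ndarray  # (intercept, log-mean slope, sample-size slope)
    residual_scale: float

    def predict(self, mean_surface: np.ndarray, n_animals: int) -> np.ndarray:
        lp = (
            self.coef[0]
            + self.coef[1] * np.log(np.asarray(mean_surface, float) + EPS)
            + self.coef[2] * float(n_animals)
        )
        return np.exp(lp)


@dataclass
class PopulationEstimate:
    cluster_id: int
    mean: float
    variance: float
    haulout_prob_mean: float
    haulout_prob_sd: float


def within_cluster_variance(surfaces: dict[str, UsageSurface]) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean and empirical variance across a cluster's animal surfaces."""
    stack = np.stack([s.values for s in surfaces.values()])
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1) if len(stack) > 1 else np.zeros_like(mean)
    return mean, var


def fit_variance_model(
    cluster_surfaces: dict[int, dict[str, UsageSurface]],
    min_animals: int = DATA_RICH_MIN_ANIMALS,
    max_cells_per_cluster: int = 2000,
    seed: int = 0,
    min_clusters: int = 3,
) -> VarianceModel:
    """Fit the within-cluster variance regression on data-rich clusters.

    ``cluster_surfaces`` maps cluster id -> {animal id -> per-animal surface}.
    Only clusters with >= ``min_animals`` animals are used; cells with zero
    mean usage are skipped (both variance and mean are structurally zero
    there).  Requires at least ``min_clusters`` data-rich clusters; when the
    contributing clusters all share one sample size the sample-size slope is
    not identifiable and is fixed at zero.
    """
    rich = {cid: s for cid, s in cluster_surfaces.items() if len(s) >= max(min_animals, 2)}
    if len(rich) < min_clusters:
        raise ValueError(
            f"only {len(rich)} clusters have >= {min_animals} tagged animals; "
            "relax the data-rich threshold (min_animals) in the configuration"
        )
    rng = np.random.default_rng(seed)
    ys, Xs = [], []
    for cid, surfaces in rich.items():
        stack = np.stack([s.values for s in surfaces.values()])
        mean = stack.mean(axis=0)
        var = stack.var(axis=0, ddof=1)
        mask = mean > 0
        m = mean[mask]
        v = var[mask]
        if len(m) > max_cells_per_cluster:
            idx = rng.choice(len(m), size=max_cells_per_cluster, replace=False)
            m, v = m[idx], v[idx]
        ys.append(np.log(v + EPS))
        Xs.append(np.column_stack([np.ones(len(m)), np.log(m + EPS), np.full(len(m), float(len(surfaces)))]))
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    if len({len(s) for s in rich.values()}) < 2:
        # one distinct sample size: the n-slope is unidentifiable, fix at 0
        coef2, *_ = np.linalg.lstsq(X[:, :2], y, rcond=None)
        coef = np.array([coef2[0], coef2[1], 0.0])
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    return VarianceModel(coef=coef, residual_scale=float(np.sqrt((resid**2).sum() / dof)))


def predict_variance(model: VarianceModel, mean_surface: np.ndarray, n_animals: int) -> np.ndarray:
    """Within-cluster variance surface at a given tagged-animal sample size.

    Null clusters use ``n_animals = 0``.  Cells with zero mean usage get the
    model floor (the eps-driven minimum), keeping the surface positive.
    """
    return model.predict(mean_surface, n_animals)


def population_estimate(
    cluster_id: int,
    cluster_count: float,
    haulout_prob: tuple[float, float] = DEFAULT_HAULOUT_PROB,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PopulationEstimate:
    """Bootstrap a cluster population estimate from its count.

    Haul-out probability draws p* come from a beta distribution
    moment-matched to (mean, sd) and truncated to (0.01, 0.99); the cluster
    population is count / p*.  Degenerate sd = 0 gives the point estimate
    count / mean with zero variance; invalid beta moments fall back to a
    logit-normal (warned).
    """
    p_mean, p_sd = haulout_prob
    if not (0 < p_mean < 1):
        raise ValueError("haul-out probability mean must lie in (0, 1)")
    if cluster_count < 0:
        raise ValueError("cluster count must be nonnegative")
    if p_sd == 0:
        mean = cluster_count / p_mean
        return PopulationEstimate(cluster_id, mean, 0.0, p_mean, p_sd)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = p_mean * (1 - p_mean) / (p_sd**2) - 1.0
    if nu <= 0:
        warnings.warn("haul-out probability sd too large for a beta; using logit-normal")
        mu = np.log(p_mean / (1 - p_mean))
        sigma = p_sd / (p_mean * (1 - p_mean))  # delta method on the logit
        draws = 1.0 / (1.0 + np.exp(-(mu + sigma * rng.standard_normal(n_boot))))
    else:
        draws = rng.beta(p_mean * nu, (1 - p_mean) * nu, size=n_boot)
    draws = np.clip(draws, 0.01, 0.99)
    pops = cluster_count / draws
    return PopulationEstimate(cluster_id, float(pops.mean()), float(pops.var(ddof=1)), p_mean, p_sd)


def at_sea_fraction(tracks: pd.DataFrame) -> tuple[float, pd.Series]:
    """Fraction of regularised fixes spent at sea, averaged over animals.

    Each animal gets equal weight regardless of tag lifespan.  Returns the
    overall mean and the per-animal series.
    """
    if tracks.empty:
        raise ValueError("no tracks")
    per_animal = tracks.groupby("animal_id")["at_haulout"].apply(lambda s: 1.0 - s.astype(bool).mean())
    return float(per_animal.mean()), per_animal


def scale_and_combine(
    usage: UsageSurface,
    variance_surface: np.ndarray,
    pop: PopulationEstimate,
    at_sea_frac: float,
    z: float = 1.959963984540054,
) -> dict[str, np.ndarray]:
    """Scale a normalised cluster surface to seal units with per-cell CIs.

    mean = N f u;  var = f^2 (N^2 s_u^2 + u^2 s_N^2 + s_u^2 s_N^2) for
    independent N (cluster population) and u (normalised usage); the 95%
    interval is mean +/- 1.96 sd with the lower bound truncated at zero.
    """
    u = np.asarray(usage.values, float)
    s2u = np.asarray(variance_surface, float)
    if (u < 0).any() or (s2u < 0).any() or pop.mean < 0 or pop.variance < 0 or at_sea_frac < 0:
        raise ValueError("negative inputs to scale_and_combine")
    f = float(at_sea_frac)
    mean = pop.mean * f * u
    var = f * f * (pop.mean**2 * s2u + u * u * pop.variance + s2u * pop.variance)
    sd = np.sqrt(var)
    lower = np.maximum(mean - z * sd, 0.0)
    upper = mean + z * sd
    return {"mean": mean, "variance": var, "lower95": lower, "upper95": upper}
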