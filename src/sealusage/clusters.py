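"""Haul-out identification, spatial clustering and count adjustment.

Onshore haul-out cells come from two sources: telemetry fixes flagged
hauled-out, and terrestrial count surveys with at least one animal.  Cells
are aggregated into clusters by centroid (UPGMC) agglomeration on the
shortest *at-sea* distance between them, scanned over cut scales 0.6-15 km
in 0.6 km steps; a single change point in the n_clusters-vs-scale series
picks the working aggregation scale.  Clusters with telemetry from at least
one tagged animal are *telemetry* clusters; clusters known only from counts
are *null* clusters and later receive habitat-model-predicted usage.

Zero-count telemetry clusters are retained by giving them a provisional
count of one and rescaling all cluster counts so the grand total equals the
original surveyed total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .grid import GridSpec
from .seadist import pairwise_atsea_distances
from .telemetry import snap_haulout_cell

logger = logging.getLogger(__name__)

#: clustering scales (km): 0.6 (no clustering) to 15 (maximum), step 0.6
DEFAULT_SCALES_KM = np.round(np.arange(1, 26) * 0.6, 10)

#: stand-in for an unreachable (infinite) at-sea distance; far above any scale
_FAR = 1.0e12


@dataclass
class HaulOutCluster:
    cluster_id: int
    cells: list[tuple[int, int]]
    type: str  # "telemetry" | "null"
    raw_count: float
    adjusted_count: float
    tagged_animals: set[str] = field(default_factory=set)


def most_recent_counts(survey: pd.DataFrame) -> pd.DataFrame:
    """Most recent available count per surveyed cell.

    The latest survey year wins; ties are broken by the larger count (and
    logged).  Unsurveyed cells (NaN count) are dropped — a surveyed zero is
    information, an unsurveyed cell is not.
    """
    df = survey.dropna(subset=["count"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["row", "col", "count", "survey_year"])
    df = df.sort_values(["survey_year", "count"], kind="stable")
    dup = df.duplicated(subset=["row", "col"], keep=False)
    if dup.any():
        logger.info("%d cells surveyed in multiple years; keeping the most recent", dup.sum() // 2)
    out = df.drop_duplicates(subset=["row", "col"], keep="last").reset_index(drop=True)
    out["row"] = out["row"].astype(int)
    out["col"] = out["col"].astype(int)
    return out


def identify_haulout_cells(
    tracks: pd.DataFrame, survey: pd.DataFrame, grid: GridSpec
) -> list[tuple[int, int]]:
    """Union of telemetry haul-out cells and surveyed cells with count > 0."""
    cells: set[tuple[int, int]] = set()
    if len(tracks):
        hauled = tracks[tracks["at_haulout"].astype(bool)]
        for x, y in zip(hauled["x_m"], hauled["y_m"]):
            cells.add(snap_haulout_cell(grid, float(x), float(y)))
    counts = most_recent_counts(survey)
    for _, r in counts[counts["count"] > 0].iterrows():
        cells.add((int(r["row"]), int(r["col"])))
    return sorted(cells)


def cluster_scan(
    haulout_cells: list[tuple[int, int]],
    grid: GridSpec,
    scales_km: np.ndarray = DEFAULT_SCALES_KM,
    method: str = "atsea-upgmc",
    distances: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Number of clusters at each cut scale, plus the merge tree.

    Centroid (UPGMC) agglomeration on the pairwise shortest at-sea distance
    matrix between haul-out cells (``method="atsea-upgmc"``, default) or on
    cell-centre coordinates (``method="coords"``).  At-sea distances between
    onshore cells are measured waterline to waterline, which drops the legs
    inside the cells themselves, so they are floored at the straight-line
    centre distance (a sea path can never be shorter).  Merging is strict
    (distance < scale), so the minimum 0.6 km scale performs no clustering.
    Merge heights are monotonised (running maximum) before cutting so
    n_clusters is guaranteed non-increasing in scale despite possible
    centroid inversions.  Pairs with no at-sea route never merge and are
    logged.

    Returns ``(scan, Z)`` where scan has columns ``scale_km, n_clusters`` and
    Z is the monotonised scipy linkage matrix (heights in metres).
    """
    cells = [tuple(map(int, c)) for c in haulout_cells]
    n = len(cells)
    if n < 2:
        raise ValueError("cluster_scan needs at least 2 haul-out cells")
    if method == "coords":
        xy = np.array([grid.centre_of(r, c) for r, c in cells], dtype=float)
        Z = sch.linkage(xy, method="centroid")
    elif method == "atsea-upgmc":
        if distances is None:
            distances = pairwise_atsea_distances(grid, np.array(cells))
        D = np.asarray(distances, dtype=float).copy()
        xy = np.array([grid.centre_of(r, c) for r, c in cells], dtype=float)
        euclid = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        D = np.maximum(D, euclid)
        if np.isinf(D).any():
            logger.warning("unreachable haul-out cell pairs; they stay singletons at every scale")
            D[np.isinf(D)] = _FAR
        iu = np.triu_indices(n, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns: centroid assumes Euclidean input
            Z = sch.linkage(D[iu], method="centroid")
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    Z = Z.copy()
    Z[:, 2] = np.maximum.accumulate(Z[:, 2])
    heights_m = Z[:, 2]
    n_clusters = [int(n - np.sum(heights_m < s * 1000.0 - 1e-9)) for s in scales_km]
    scan = pd.DataFrame({"scale_km": np.asarray(scales_km, float), "n_clusters": n_clusters})
    return scan, Z


def changepoint_scale(scan: pd.DataFrame) -> float:
    """Single change point in the mean of the n_clusters series (AMOC).

    Exhaustive at-most-one-change search minimising the summed squared error
    of a two-segment piecewise-constant fit; returns the scale of the first
    point after the break.  A flat series returns the minimum scale with a
    warning.
    """
    y = np.asarray(scan["n_clusters"], dtype=float)
    scales = np.asarray(scan["scale_km"], dtype=float)
    m = len(y)
    if m < 4:
        raise ValueError("change-point analysis needs a series of length >= 4")
    if np.allclose(y, y[0]):
        warnings.warn("n_clusters series is flat; returning the minimum scale")
        return float(scales.min())

    def sse(a: np.ndarray) -> float:
        return float(((a - a.mean()) ** 2).sum()) if len(a) else 0.0

    best_tau, best_cost = None, np.inf
    for tau in range(1, m):
        cost = sse(y[:tau]) + sse(y[tau:])
        if cost < best_cost - 1e-12:
            best_cost, best_tau = cost, tau
    return float(scales[best_tau])


def cut_clusters(Z: np.ndarray, scale_km: float) -> np.ndarray:
    """Cluster labels (0-based) cutting the monotonised tree at a scale.

    Merging is strict (height < scale), matching :func:`cluster_scan`.
    """
    labels = sch.fcluster(Z, t=scale_km * 1000.0 - 1e-6, criterion="distance")
    return labels - 1


def classify_and_adjust(
    haulout_cells: list[tuple[int, int]],
    labels: np.ndarray,
    tracks: pd.DataFrame,
    assoc: pd.DataFrame,
    survey: pd.DataFrame,
    grid: GridSpec,
) -> list[HaulOutCluster]:
    """Assign cluster types and rescaled counts.

    A cluster is *telemetry* when at least one tagged animal hauls out in (or
    has at-sea fixes associated with) a member cell, else *null*.  Cluster
    raw counts sum the member cells' most recent counts; telemetry clusters
    with zero count get a provisional one, and all counts are rescaled so the
    total matches the original surveyed total.
    """
    cells = [tuple(map(int, c)) for c in haulout_cells]
    counts = most_recent_counts(survey)
    count_map = {(int(r.row), int(r.col)): float(r.count) for r in counts.itertuples()}

    animals_by_cell: dict[tuple[int, int], set[str]] = {}
    if len(tracks):
        hauled = tracks[tracks["at_haulout"].astype(bool)]
        for aid, x, y in zip(hauled["animal_id"], hauled["x_m"], hauled["y_m"]):
            cell = snap_haulout_cell(grid, float(x), float(y))
            animals_by_cell.setdefault(cell, set()).add(str(aid))
    if len(assoc):
        for aid, r, c in zip(assoc["animal_id"], assoc["assoc_row"], assoc["assoc_col"]):
            animals_by_cell.setdefault((int(r), int(c)), set()).add(str(aid))

    clusters: list[HaulOutCluster] = []
    for cid in sorted(set(int(l) for l in labels)):
        members = [cells[i] for i in range(len(cells)) if labels[i] == cid]
        raw = sum(count_map.get(cell, 0.0) for cell in members)
        animals: set[str] = set()
        for cell in members:
            animals |= animals_by_cell.get(cell, set())
        ctype = "telemetry" if animals else "null"
        clusters.append(HaulOutCluster(cid, members, ctype, raw, raw, animals))

    total_raw = sum(c.raw_count for c in clusters)
    if total_raw <= 0:
        raise ValueError("all cluster counts are zero; population cannot be scaled")
    provisional = [
        1.0 if (c.type == "telemetry" and c.raw_count == 0) else c.raw_count for c in clusters
    ]
    factor = total_raw / sum(provisional)
    for c, p in zip(clusters, provisional):
        c.adjusted_count = p * factor
    return clusters


def clusters_to_geojson(clusters: list[HaulOutCluster], grid: GridSpec) -> dict:
    """GeoJSON FeatureCollection of cluster multipoints with properties."""
    features = []
    for c in clusters:
        coords = [[float(x), float(y)] for x, y in (grid.centre_of(r, cc) for r, cc in c.cells)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "MultiPoint", "coordinates": coords},
                "properties": {
                    "cluster_id": int(c.cluster_id),
                    "type": c.type,
                    "raw_count": float(c.raw_count),
                    "adjusted_count": float(c.adjusted_count),
                    "animals": sorted(c.tagged_animals),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
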