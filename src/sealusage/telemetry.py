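"""Telemetry cleansing, two-hourly regularisation and trip segmentation.

Raw tag fixes arrive as tabular records (animal id, UTC timestamp, projected
x/y, tag type, wet/dry haul-out flag).  Processing steps: drop incomplete
and duplicated records, linearly interpolate each animal's track onto a
uniform two-hourly clock (never across gaps longer than ``max_gap_h``),
detect haul-out events, and split the track into at-sea trips bounded by
haul-out events.  Each at-sea fix is associated with one haul-out cell —
fixes in the first half of a trip with the departure haul-out, fixes in the
second half with the destination — which later decides the haul-out cluster
whose usage surface the fix contributes to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["animal_id", "timestamp", "x_m", "y_m", "tag_type", "at_haulout"]


@dataclass
class TripSegment:
    """A maximal run of at-sea fixes bounded by haul-out events (or track ends)."""

    animal_id: str
    fixes: pd.DataFrame
    departure_cell: tuple[int, int] | None
    destination_cell: tuple[int, int] | None


def cleanse(
    fixes: pd.DataFrame, min_fixes: int = 10
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop incomplete/duplicate records; exclude animals with too few fixes.

    Returns the cleansed frame (per-animal time-sorted, original relative
    order of surviving records preserved) and a log of excluded animals.
    """
    df = fixes.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry input lacks columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.dropna(subset=REQUIRED_COLUMNS)
    df = df[np.isfinite(df["x_m"]) & np.isfinite(df["y_m"])]
    df = df.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    df = df.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)

    exclusions: dict[str, str] = {}
    keep = []
    for animal, g in df.groupby("animal_id", sort=False):
        if len(g) < min_fixes:
            exclusions[str(animal)] = f"only {len(g)} fixes after cleansing (< {min_fixes})"
            continue
        keep.append(g)
    if exclusions:
        logger.info("cleanse excluded %d animals: %s", len(exclusions), exclusions)
    out = pd.concat(keep, ignore_index=True) if keep else df.iloc[0:0].copy()
    return out, exclusions


def regularise(
    fixes: pd.DataFrame, interval_h: float = 2.0, max_gap_h: float = 24.0
) -> pd.DataFrame:
    """Linear interpolation onto a uniform clock anchored at each segment start.

    Gaps longer than ``max_gap_h`` split the track into segments; no
    interpolation (or extrapolation) bridges a gap.  An interpolated fix is
    flagged hauled-out only when both bracketing observed fixes are hauled
    out at the same position.  Adds a ``segment`` column.
    """
    out = []
    for animal, g in fixes.groupby("animal_id", sort=False):
        g = g.sort_values("timestamp", kind="stable").reset_index(drop=True)
        t = g["timestamp"]
        gap = t.diff().dt.total_seconds() / 3600.0
        seg_id = (gap > max_gap_h).cumsum()
        for s, seg in g.groupby(seg_id, sort=True):
            seg = seg.reset_index(drop=True)
            if len(seg) == 1:
                row = seg.iloc[[0]].copy()
                row["segment"] = int(s)
                out.append(row)
                continue
            th = (seg["timestamp"] - seg["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
            n_steps = int(np.floor(th[-1] / interval_h + 1e-9))
            clock = np.arange(n_steps + 1) * interval_h
            idx = np.searchsorted(th, clock, side="left")
            rows = []
            for ck, i in zip(clock, idx):
                if i < len(th) and abs(th[i] - ck) < 1e-9:
                    r = seg.iloc[i].copy()
                else:
                    lo, hi = i - 1, i
                    w = (ck - th[lo]) / (th[hi] - th[lo])
                    r = seg.iloc[lo].copy()
                    r["x_m"] = (1 - w) * seg["x_m"].iloc[lo] + w * seg["x_m"].iloc[hi]
                    r["y_m"] = (1 - w) * seg["y_m"].iloc[lo] + w * seg["y_m"].iloc[hi]
                    same_spot = (
                        bool(seg["at_haulout"].iloc[lo])
                        and bool(seg["at_haulout"].iloc[hi])
                        and abs(seg["x_m"].iloc[lo] - seg["x_m"].iloc[hi]) < 1e-6
                        and abs(seg["y_m"].iloc[lo] - seg["y_m"].iloc[hi]) < 1e-6
                    )
                    r["at_haulout"] = same_spot
                    r["timestamp"] = seg["timestamp"].iloc[0] + pd.Timedelta(hours=float(ck))
                rows.append(r)
            seg_out = pd.DataFrame(rows).reset_index(drop=True)
            seg_out["segment"] = int(s)
            out.append(seg_out)
    if not out:
        res = fixes.iloc[0:0].copy()
        res["segment"] = pd.Series(dtype=int)
        return res
    res = pd.concat(out, ignore_index=True)
    res["at_haulout"] = res["at_haulout"].astype(bool)
    return res


def detect_resolution(tracks: pd.DataFrame) -> float:
    """Median consecutive-step distance (m) pooled over animals, at-sea steps.

    Diagnostic for choosing the grid cell size; the pipeline default stays at
    600 m.  Steps between two hauled-out fixes (zero movement by construction)
    are excluded so long haul-out bouts do not drag the median to zero.
    """
    dists = []
    keys = ["animal_id"] + (["segment"] if "segment" in tracks.columns else [])
    for _, g in tracks.groupby(keys, sort=False):
        g = g.sort_values("timestamp")
        dx = g["x_m"].diff().to_numpy()[1:]
        dy = g["y_m"].diff().to_numpy()[1:]
        both_haul = (g["at_haulout"].to_numpy()[1:]) & (g["at_haulout"].to_numpy()[:-1])
        step = np.hypot(dx, dy)[~both_haul]
        dists.append(step)
    if not dists:
        raise ValueError("no steps available")
    pooled = np.concatenate(dists)
    if pooled.size == 0:
        raise ValueError("no at-sea steps available")
    return float(np.median(pooled))


def snap_haulout_cell(grid: GridSpec, x: float, y: float, max_radius: int = 3) -> tuple[int, int]:
    """Grid cell of a hauled-out fix, snapped to the nearest land cell."""
    r, c = grid.cell_of(x, y)
    r = int(np.clip(r, 0, grid.nrows - 1))
    c = int(np.clip(c, 0, grid.ncols - 1))
    if grid.land[r, c]:
        return r, c
    best, best_d = None, np.inf
    for dr in range(-max_radius, max_radius + 1):
        for dc in range(-max_radius, max_radius + 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.nrows and 0 <= cc < grid.ncols and grid.land[rr, cc]:
                d = dr * dr + dc * dc
                if d < best_d:
                    best, best_d = (rr, cc), d
    if best is None:
        raise ValueError(f"no land cell within {max_radius} cells of hauled-out fix at ({x}, {y})")
    return best


def segment_trips(
    track: pd.DataFrame, grid: GridSpec
) -> list[TripSegment]:
    """Split one animal's regularised track into haul-out-bounded trips.

    At-sea fixes at or before the trip's temporal midpoint associate with the
    departure haul-out, later fixes with the destination; trips truncated by
    a track end associate wholly with their single bounding haul-out.
    Raises ``ValueError`` if the track has no haul-out events at all (such
    animals are excluded from the analysis).
    """
    animals = track["animal_id"].unique()
    if len(animals) != 1:
        raise ValueError("segment_trips expects a single animal's track")
    animal = str(animals[0])
    if not track["at_haulout"].any():
        raise ValueError(f"animal {animal} has no haul-out records; excluded")
    trips: list[TripSegment] = []
    keys = ["segment"] if "segment" in track.columns else [None]
    grouped = track.groupby("segment", sort=True) if keys != [None] else [(0, track)]
    for _, seg in grouped:
        seg = seg.sort_values("timestamp").reset_index(drop=True)
        at_sea = ~seg["at_haulout"].to_numpy()
        if not at_sea.any():
            continue
        # maximal runs of at-sea fixes
        edges = np.flatnonzero(np.diff(np.concatenate(([0], at_sea.astype(int), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            dep = dest = None
            if start > 0:
                r = seg.iloc[start - 1]
                dep = snap_haulout_cell(grid, r["x_m"], r["y_m"])
            if stop < len(seg):
                r = seg.iloc[stop]
                dest = snap_haulout_cell(grid, r["x_m"], r["y_m"])
            trips.append(TripSegment(animal, seg.iloc[start:stop].copy(), dep, dest))
    return trips


def associate_fixes(trips: list[TripSegment]) -> pd.DataFrame:
    """At-sea fixes with their associated haul-out cell, one row per fix.

    Columns: animal_id, timestamp, x_m, y_m, assoc_row, assoc_col, trip_id.
    Trips with neither a departure nor destination haul-out are dropped.
    """
    rows = []
    for k, trip in enumerate(trips):
        dep, dest = trip.departure_cell, trip.destination_cell
        if dep is None and dest is None:
            continue
        if dep is None:
            assoc = [dest] * len(trip.fixes)
        elif dest is None:
            assoc = [dep] * len(trip.fixes)
        else:
            t = trip.fixes["timestamp"]
            mid = t.iloc[0] + (t.iloc[-1] - t.iloc[0]) / 2
            assoc = [dep if ts <= mid else dest for ts in t]
        for (_, r), cell in zip(trip.fixes.iterrows(), assoc):
            rows.append(
                dict(
                    animal_id=trip.animal_id,
                    timestamp=r["timestamp"],
                    x_m=r["x_m"],
                    y_m=r["y_m"],
                    assoc_row=cell[0],
                    assoc_col=cell[1],
                    trip_id=k,
                )
            )
    return pd.DataFrame(rows, columns=["animal_id", "timestamp", "x_m", "y_m", "assoc_row", "assoc_col", "trip_id"])


def prepare(
    fixes: pd.DataFrame,
    grid: GridSpec,
    interval_h: float = 2.0,
    max_gap_h: float = 24.0,
    min_fixes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Cleanse, regularise and segment every animal.

    Returns ``(tracks, at_sea, exclusions)``: the regularised tracks, the
    associated at-sea fix table (see :func:`associate_fixes`) and a log of
    animals excluded for too few fixes or no haul-out records.
    """
    clean, exclusions = cleanse(fixes, min_fixes=min_fixes)
    tracks = regularise(clean, interval_h=interval_h, max_gap_h=max_gap_h)
    assoc_parts = []
    kept = []
    for animal, g in tracks.groupby("animal_id", sort=False):
        try:
            trips = segment_trips(g, grid)
        except ValueError as e:
            exclusions[str(animal)] = str(e)
            logger.info("excluding animal %s: %s", animal, e)
            continue
        kept.append(g)
        assoc_parts.append(associate_fixes(trips))
    tracks_out = pd.concat(kept, ignore_index=True) if kept else tracks.iloc[0:0]
    assoc = (
        pd.concat(assoc_parts, ignore_index=True)
        if assoc_parts
        else associate_fixes([])
    )
    return tracks_out, assoc, exclusions
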