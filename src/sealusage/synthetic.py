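"""Synthetic seascapes, haul-outs, count surveys and central-place telemetry.

This module generates worlds with known ground truth that reproduce the
statistical structure the estimation pipeline assumes: a gridded seascape
with smooth environmental covariates, coastal haul-out sites with a
partial-coverage terrestrial count survey, and tagged animals alternating
haul-out bouts with at-sea trips whose stationary spatial preference is
log-linear in the covariates.

The at-sea walk is a Metropolis-type biased random walk: a move is proposed
uniformly over the symmetric 16-neighbourhood and accepted with probability
``min(1, exp(beta . (x_new - x_old)))`` (rejected or inadmissible proposals
keep the animal in place).  Because the proposal kernel is symmetric, the
walk is reversible with stationary occupancy exactly proportional to
``exp(beta . x)`` over reachable sea cells — the exponential-of-linear-
predictor form the habitat model estimates.  A naive softmax step choice
(probability proportional to ``exp(beta . x)`` over neighbours) is *not*
used: it is reversible with respect to ``exp(beta.x) * sum_neighbours
exp(beta.x)``, roughly the square of the intended preference on smooth
fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .grid import DEFAULT_CELL_M, NEIGHBOURS_16, GridSpec, CovariateStack
from .raster import read_ascii_grid, write_ascii_grid
from .seadist import atsea_distance, build_sea_graph

#: density of sea water, kg m-3
RHO_SEAWATER = 1027.0

#: default preference coefficients of the simulated walk: per-km at-sea
#: distance decay plus effects per standard deviation of sand fraction and
#: tidal power.  The distance decay (e-folding ~3 km) confines most usage
#: within ~10-20 km of the haul-out, the scale observed for harbour seals;
#: positive sand and power effects mimic preference for sandy sediment and
#: tidally energetic foraging areas.
DEFAULT_TRUE_BETA = {"distance": -0.35, "sand": 0.6, "tidal_power": 0.4}

SURVEY_YEARS = (2008, 2015)


def tidal_power(current_speed: np.ndarray | float, rho: float = RHO_SEAWATER) -> np.ndarray | float:
    """Annual mean tidal power (W m-2) from mean current speed: P = rho U^3 / 2."""
    return 0.5 * rho * np.asarray(current_speed, dtype=float) ** 3


def _gaussian_field(shape: tuple[int, int], range_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-variance Gaussian random field.

    White noise convolved with a Gaussian kernel whose sigma is the requested
    correlation range divided by 2 (the Gaussian correlogram of the smoothed
    field decays to ~0.14 at lag 2*sigma).
    """
    noise = rng.standard_normal(shape)
    sigma = max(range_cells, 1e-6) / 2.0
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def gen_grid(
    nrows: int,
    ncols: int,
    land_fraction: float,
    seed: int,
    cell_size: float = DEFAULT_CELL_M,
    smooth_cells: float = 3.0,
    max_retries: int = 20,
) -> GridSpec:
    """Random land/sea grid with a single connected sea region.

    The mask thresholds a smoothed Gaussian field at the ``land_fraction``
    quantile; sea components other than the largest (8-connected) are flipped
    to land.  If that leaves fewer than half the intended sea cells connected,
    the field is re-drawn (internal jitter) up to ``max_retries`` times.
    """
    if not (10 <= nrows <= 2000 and 10 <= ncols <= 2000):
        raise ValueError("grid dimensions must be within [10, 2000]")
    if not (0 <= land_fraction < 0.9):
        raise ValueError("land_fraction must be in [0, 0.9)")
    if land_fraction == 0:
        return GridSpec(nrows, ncols, np.zeros((nrows, ncols), bool), cell_size=cell_size)
    rng = np.random.default_rng(seed)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity for the sea
    for _ in range(max_retries):
        f = _gaussian_field((nrows, ncols), smooth_cells, rng)
        thr = np.quantile(f, 1.0 - land_fraction)
        land = f > thr
        sea = ~land
        labels, n_comp = ndimage.label(sea, structure=structure)
        if n_comp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
        main = 1 + int(np.argmax(sizes))
        if sizes[main - 1] < 0.5 * sea.sum():
            continue
        land = labels != main
        return GridSpec(nrows, ncols, land, cell_size=cell_size)
    raise RuntimeError(
        f"could not generate a connected sea region in {max_retries} attempts "
        f"(nrows={nrows}, ncols={ncols}, land_fraction={land_fraction})"
    )


def gen_covariates(grid: GridSpec, variogram_range_m: float = 3000.0, seed: int = 0) -> CovariateStack:
    """Smooth covariate fields: depth, currents/tidal power, sediments.

    Depth is a softplus-transformed Gaussian field (positive, metres); the
    mean current speed field U is lognormal around ~1 m s-1 and annual mean
    tidal power is rho U^3 / 2 with rho = 1027 kg m-3.  Peak spring and neap
    flows are scaled copies of U (spring > neap).  Sand/gravel/mud come from
    an additive logistic-normal transform of two correlated Gaussian fields,
    so they are positive and sum to one everywhere.
    """
    rng = np.random.default_rng(seed)
    shape = (grid.nrows, grid.ncols)
    range_cells = variogram_range_m / grid.cell_size

    stack = CovariateStack(grid)
    depth_f = _gaussian_field(shape, range_cells, rng)
    stack["depth"] = 40.0 * np.log1p(np.exp(depth_f)) + 5.0  # ~5-100 m

    u_f = _gaussian_field(shape, range_cells, rng)
    u = np.exp(0.5 * u_f)  # median 1 m s-1
    stack["current_speed"] = u
    stack["tidal_power"] = tidal_power(u)
    stack["peak_spring_flow"] = 1.9 * u
    stack["peak_neap_flow"] = 1.0 * u

    z1 = _gaussian_field(shape, range_cells, rng)
    z2_raw = _gaussian_field(shape, range_cells, rng)
    z2 = 0.5 * z1 + np.sqrt(1 - 0.25) * z2_raw  # correlated sediment axes
    e1, e2 = np.exp(1.2 * z1), np.exp(1.2 * z2)
    denom = 1.0 + e1 + e2
    stack["sand"] = e1 / denom
    stack["gravel"] = e2 / denom
    stack["mud"] = 1.0 / denom
    return stack


def gen_haulouts_and_counts(
    grid: GridSpec,
    n_sites: int,
    total_population: int,
    survey_coverage: float,
    seed: int,
    n_groups: int | None = None,
    min_separation_m: float = 5000.0,
    group_spread_m: float = 900.0,
) -> tuple[list[tuple[int, int]], np.ndarray, pd.DataFrame]:
    """Place haul-out sites on the coast and run a partial count survey.

    Haul-outs aggregate in reality, so sites are placed in ``n_groups``
    spatial groups: group centres are coastal cells at least
    ``min_separation_m`` apart (straight line) and the remaining sites fall
    within ``group_spread_m`` of a centre.  Returns ``(haulout_cells,
    true_counts, survey)``.  ``survey`` has one row per coastal cell with
    columns ``row, col, count, survey_year``; unsurveyed cells carry NaN
    count and year (distinct from a surveyed zero), surveyed cells a year in
    2008-2015.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if total_population < n_sites:
        raise ValueError("total_population must be >= n_sites")
    rng = np.random.default_rng(seed)
    coastal = grid.coastal_land_cells()
    if len(coastal) < n_sites:
        raise ValueError(f"only {len(coastal)} coastal cells for {n_sites} haul-out sites")
    if n_groups is None:
        n_groups = n_sites
    n_groups = min(n_groups, n_sites)
    xy = np.column_stack(grid.centre_of(coastal[:, 0], coastal[:, 1]))

    # group centres: greedy placement with minimum separation, relaxing the
    # separation when the coast cannot accommodate it
    sep = float(min_separation_m)
    centres: list[int] = []
    while True:
        order = rng.permutation(len(coastal))
        centres = []
        for k in order:
            if centres and np.min(np.hypot(*(xy[centres] - xy[k]).T)) < sep:
                continue
            centres.append(int(k))
            if len(centres) == n_groups:
                break
        if len(centres) == n_groups or sep < grid.cell_size:
            break
        sep *= 0.7
    if len(centres) < n_groups:
        raise ValueError("could not place the requested number of haul-out groups")

    chosen_idx = list(centres)
    extra = n_sites - n_groups
    if extra > 0:
        pool = [k for k in range(len(coastal)) if k not in set(chosen_idx)]
        for _ in range(extra):
            centre = centres[int(rng.integers(n_groups))]
            near = [k for k in pool if np.hypot(*(xy[k] - xy[centre])) <= group_spread_m]
            pick = int(rng.choice(near)) if near else int(rng.choice(pool))
            chosen_idx.append(pick)
            pool.remove(pick)
    chosen = [tuple(map(int, coastal[k])) for k in chosen_idx]

    probs = rng.dirichlet(np.ones(n_sites))
    # every site holds at least one animal
    counts = np.ones(n_sites, dtype=int)
    counts += rng.multinomial(total_population - n_sites, probs)

    haul_lookup = {cell: int(c) for cell, c in zip(chosen, counts)}
    n_surveyed = int(round(survey_coverage * len(coastal)))
    surveyed_idx = set(rng.choice(len(coastal), size=n_surveyed, replace=False).tolist())
    rows = []
    for k, (r, c) in enumerate(map(tuple, coastal)):
        if k in surveyed_idx:
            rows.append(
                dict(
                    row=r,
                    col=c,
                    count=float(haul_lookup.get((r, c), 0)),
                    survey_year=float(rng.integers(SURVEY_YEARS[0], SURVEY_YEARS[1] + 1)),
                )
            )
        else:
            rows.append(dict(row=r, col=c, count=np.nan, survey_year=np.nan))
    survey = pd.DataFrame(rows)
    return chosen, counts, survey


@dataclass
class SyntheticWorld:
    """A generated study system with known ground truth."""

    grid: GridSpec
    covariates: CovariateStack
    haulout_cells: list[tuple[int, int]]
    true_counts: np.ndarray
    survey: pd.DataFrame
    true_beta: dict[str, float]
    seed: int
    #: mean/sd of each preference covariate over sea cells, as used by the walk
    standardisation: dict[str, tuple[float, float]] = field(default_factory=dict)

    def sea_zscore(self, name: str) -> np.ndarray:
        m, s = self.standardisation[name]
        return (self.covariates[name] - m) / s


def gen_world(
    nrows: int = 60,
    ncols: int = 60,
    land_fraction: float = 0.25,
    n_sites: int = 12,
    n_groups: int | None = 8,
    total_population: int = 300,
    survey_coverage: float = 0.85,
    variogram_range_m: float = 3000.0,
    true_beta: dict[str, float] | None = None,
    seed: int = 0,
    min_separation_m: float = 5000.0,
    group_spread_m: float = 900.0,
) -> SyntheticWorld:
    """Convenience builder wiring grid, covariates, haul-outs and survey."""
    rng = np.random.default_rng(seed)
    grid = gen_grid(nrows, ncols, land_fraction, seed=int(rng.integers(2**31)))
    cov = gen_covariates(grid, variogram_range_m=variogram_range_m, seed=int(rng.integers(2**31)))
    haulouts, counts, survey = gen_haulouts_and_counts(
        grid,
        n_sites,
        total_population,
        survey_coverage,
        seed=int(rng.integers(2**31)),
        n_groups=n_groups,
        min_separation_m=min_separation_m,
        group_spread_m=group_spread_m,
    )
    beta = dict(DEFAULT_TRUE_BETA if true_beta is None else true_beta)
    sea = grid.sea
    standardisation = {
        name: (float(cov[name][sea].mean()), float(cov[name][sea].std(ddof=0)))
        for name in ("sand", "tidal_power")
    }
    return SyntheticWorld(
        grid=grid,
        covariates=cov,
        haulout_cells=haulouts,
        true_counts=counts,
        survey=survey,
        true_beta=beta,
        seed=seed,
        standardisation=standardisation,
    )


def _preference_score(world: SyntheticWorld, dist_surface: np.ndarray) -> np.ndarray:
    """beta . x per cell: per-km distance + z-scored sand and tidal power."""
    b = world.true_beta
    finite = np.where(np.isfinite(dist_surface), dist_surface, 0.0)
    score = b["distance"] * finite / 1000.0
    score = score + b["sand"] * world.sea_zscore("sand")
    score = score + b["tidal_power"] * world.sea_zscore("tidal_power")
    return score


def simulate_tracks(
    world: SyntheticWorld,
    n_animals: int,
    mean_lifespan_h: float = 600.0,
    interval_h: float = 2.0,
    seed: int = 0,
    mean_trip_steps: float = 12.0,
    mean_haul_steps: float = 6.0,
    min_lifespan_h: float = 168.0,
    start_year_range: tuple[int, int] = (2009, 2013),
    tagged_site_fraction: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tagged animals alternating haul-out bouts and at-sea trips.

    Returns ``(fixes, tag_meta)``: fixes with columns ``animal_id, timestamp,
    x_m, y_m, tag_type, at_haulout`` on an exact ``interval_h`` clock, and per
    -animal metadata ``animal_id, tag_type, deployment_year, lifespan_h,
    home_row, home_col``.  Trip and haul-out bout lengths are geometric;
    tag lifespans are exponential with a 168 h floor, reproducing the
    short/long tag-lifespan contrast the discovery-rate weighting corrects.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = np.random.default_rng(seed)
    grid = world.grid
    graph = build_sea_graph(grid)

    # per-haulout distance surfaces and preference scores
    dist_cache: dict[int, np.ndarray] = {}
    score_cache: dict[int, np.ndarray] = {}
    for k, cell in enumerate(world.haulout_cells):
        if not grid.adjacent_sea(*cell):
            raise RuntimeError(f"haul-out cell {cell} has no adjacent sea cell")
        d = atsea_distance(grid, [cell], graph=graph).values
        if not np.isfinite(d[grid.sea]).any():
            raise RuntimeError(f"no sea cell reachable from haul-out {cell}")
        dist_cache[k] = d
        score_cache[k] = _preference_score(world, d)

    # tagging campaigns reach only part of the coast: a random subset of
    # sites is tagged at all (the rest can only appear via count surveys);
    # effort is spread round-robin over the tagged sites first, then
    # proportional to site abundance
    n_sites = len(world.haulout_cells)
    n_tagged = max(1, int(round(tagged_site_fraction * n_sites)))
    tagged_sites = rng.choice(n_sites, size=n_tagged, replace=False)
    site_probs = world.true_counts[tagged_sites].astype(float)
    site_probs = site_probs / site_probs.sum()
    site_order = rng.permutation(tagged_sites)
    fixes = []
    meta = []
    for a in range(n_animals):
        animal_id = f"A{a:03d}"
        if a < len(site_order):
            home = int(site_order[a])
        else:
            home = int(rng.choice(tagged_sites, p=site_probs))
        home_cell = world.haulout_cells[home]
        dist = dist_cache[home]
        score = score_cache[home]
        lifespan = max(min_lifespan_h, float(rng.exponential(mean_lifespan_h)))
        lifespan = min(lifespan, 6.0 * mean_lifespan_h)
        n_steps = int(lifespan // interval_h)
        tag_type = "SRDL" if rng.random() < 0.5 else "GPS"
        year = int(rng.integers(start_year_range[0], start_year_range[1] + 1))
        t0 = pd.Timestamp(f"{year}-06-01", tz="UTC") + pd.Timedelta(hours=int(rng.integers(0, 24)))

        waterline = grid.adjacent_sea(*home_cell)
        hx, hy = grid.centre_of(*home_cell)
        state = "haul"
        remaining = int(rng.geometric(1.0 / mean_haul_steps))
        pos: tuple[int, int] | None = None
        returning = False
        for step in range(n_steps):
            ts = t0 + pd.Timedelta(hours=step * interval_h)
            if state == "haul":
                fixes.append((animal_id, ts, float(hx), float(hy), tag_type, True))
                remaining -= 1
                if remaining <= 0:
                    state = "sea"
                    returning = False
                    remaining = int(rng.geometric(1.0 / mean_trip_steps))
                    pos = tuple(waterline[rng.integers(len(waterline))])
                continue
            # at sea
            r, c = pos
            if not returning:
                dr, dc, _, _ = NEIGHBOURS_16[rng.integers(len(NEIGHBOURS_16))]
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < grid.nrows
                    and 0 <= cc < grid.ncols
                    and grid.sea[rr, cc]
                    and np.isfinite(dist[rr, cc])
                ):
                    # moves over land are inadmissible (walk lives on the sea graph)
                    blocked = False
                    for ir, ic in NEIGHBOURS_16[_offset_index(dr, dc)][2]:
                        mr, mc = r + ir, c + ic
                        if not (0 <= mr < grid.nrows and 0 <= mc < grid.ncols) or grid.land[mr, mc]:
                            blocked = True
                            break
                    if not blocked and np.log(rng.random()) < score[rr, cc] - score[r, c]:
                        pos = (rr, cc)
            else:
                # greedy descent of the at-sea distance surface back home
                best = None
                for dr, dc, inter, _ in NEIGHBOURS_16:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < grid.nrows and 0 <= cc < grid.ncols) or grid.land[rr, cc]:
                        continue
                    if any(
                        not (0 <= r + ir < grid.nrows and 0 <= c + ic < grid.ncols)
                        or grid.land[r + ir, c + ic]
                        for ir, ic in inter
                    ):
                        continue
                    if best is None or dist[rr, cc] < dist[best]:
                        best = (rr, cc)
                if best is not None and dist[best] < dist[pos]:
                    pos = best
            x, y = grid.centre_of(*pos)
            jx, jy = (rng.random(2) - 0.5) * grid.cell_size
            fixes.append((animal_id, ts, float(x + jx), float(y + jy), tag_type, False))
            remaining -= 1
            if remaining <= 0 and not returning:
                returning = True
            if returning and dist[pos] <= 0.0:
                state = "haul"
                remaining = int(rng.geometric(1.0 / mean_haul_steps))
        meta.append(
            dict(
                animal_id=animal_id,
                tag_type=tag_type,
                deployment_year=year,
                lifespan_h=lifespan,
                home_row=home_cell[0],
                home_col=home_cell[1],
            )
        )
    fixes_df = pd.DataFrame(
        fixes, columns=["animal_id", "timestamp", "x_m", "y_m", "tag_type", "at_haulout"]
    )
    return fixes_df, pd.DataFrame(meta)


_OFFSET_INDEX = {(dr, dc): i for i, (dr, dc, _, _) in enumerate(NEIGHBOURS_16)}


def _offset_index(dr: int, dc: int) -> int:
    return _OFFSET_INDEX[(dr, dc)]


# ---------------------------------------------------------------------------
# serialisation


def write_world(world: SyntheticWorld, fixes: pd.DataFrame, meta: pd.DataFrame, outdir: str | Path) -> None:
    """Persist a synthetic study as plain-text artefacts.

    telemetry.csv, counts.csv, tag_meta.csv, one .asc raster per covariate
    plus the land mask, haulouts.geojson, and truth.yaml (true preference
    coefficients and per-site counts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    f = fixes.copy()
    f["timestamp"] = pd.to_datetime(f["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    f.to_csv(outdir / "telemetry.csv", index=False)
    world.survey.to_csv(outdir / "counts.csv", index=False)
    meta.to_csv(outdir / "tag_meta.csv", index=False)
    grid = world.grid
    write_ascii_grid(outdir / "land_mask.asc", grid, grid.land.astype(float))
    for name, layer in world.covariates.items():
        write_ascii_grid(outdir / f"{name}.asc", grid, layer)
    features = []
    for (r, c), n in zip(world.haulout_cells, world.true_counts):
        x, y = grid.centre_of(r, c)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"row": int(r), "col": int(c), "true_count": int(n)},
            }
        )
    with open(outdir / "haulouts.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    truth = {
        "true_beta": {k: float(v) for k, v in world.true_beta.items()},
        "true_counts": {f"{r},{c}": int(n) for (r, c), n in zip(world.haulout_cells, world.true_counts)},
        "standardisation": {k: [float(m), float(s)] for k, (m, s) in world.standardisation.items()},
        "seed": int(world.seed),
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)


def read_world(indir: str | Path) -> tuple[SyntheticWorld, pd.DataFrame, pd.DataFrame]:
    """Reload a persisted synthetic study: (world, fixes, tag_meta)."""
    indir = Path(indir)
    land_vals, header = read_ascii_grid(indir / "land_mask.asc")
    from .raster import grid_from_header

    grid = grid_from_header(header, land_vals > 0.5)
    cov = CovariateStack(grid)
    for name in ("depth", "current_speed", "tidal_power", "peak_spring_flow", "peak_neap_flow", "sand", "gravel", "mud"):
        path = indir / f"{name}.asc"
        if path.exists():
            cov[name], _ = read_ascii_grid(path)
    survey = pd.read_csv(indir / "counts.csv")
    with open(indir / "truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    cells, counts = [], []
    for key, n in truth["true_counts"].items():
        r, c = key.split(",")
        cells.append((int(r), int(c)))
        counts.append(int(n))
    world = SyntheticWorld(
        grid=grid,
        covariates=cov,
        haulout_cells=cells,
        true_counts=np.asarray(counts),
        survey=survey,
        true_beta={k: float(v) for k, v in truth["true_beta"].items()},
        seed=int(truth.get("seed", 0)),
        standardisation={k: (float(v[0]), float(v[1])) for k, v in truth.get("standardisation", {}).items()},
    )
    fixes = pd.read_csv(indir / "telemetry.csv", parse_dates=["timestamp"])
    meta = pd.read_csv(indir / "tag_meta.csv")
    return world, fixes, meta
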