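"""Total usage map assembly and the end-to-end pipeline.

``assemble`` sums the population-scaled cluster maps (means and, assuming
independence across clusters, variances) into one at-sea usage map with 95%
confidence surfaces and provenance — the fraction of total usage contributed
by telemetry-based density estimation versus habitat-model prediction.

``run_pipeline`` drives the whole analysis on a synthetic world through the
stage order simulate -> prep -> distance -> cluster -> kde -> habitat ->
scale -> assemble, persisting plain-text intermediates in the output
directory.  A stage is skipped when its outputs already exist and no
upstream stage was re-run, so deleting one intermediate re-runs only that
stage and everything downstream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as hc
from . import habitat as hb
from . import kde as kd
from . import telemetry as tp
from . import uncertainty as un
from .grid import GridSpec
from .raster import read_ascii_grid, write_ascii_grid
from .seadist import DistanceSurface, atsea_distance, build_sea_graph
from .synthetic import gen_world, read_world, simulate_tracks, write_world

logger = logging.getLogger(__name__)

STAGES = ["simulate", "prep", "distance", "cluster", "kde", "habitat", "scale", "assemble"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "sealusage_run",
    "world": {
        "nrows": 60,
        "ncols": 60,
        "land_fraction": 0.25,
        "n_sites": 12,
        "n_groups": 8,
        "total_population": 300,
        "survey_coverage": 0.85,
        "variogram_range_m": 3000.0,
        "min_separation_m": 5000.0,
    },
    "tracks": {"n_animals": 30, "mean_lifespan_h": 600.0, "interval_h": 2.0},
    "prep": {"min_fixes": 10, "max_gap_h": 24.0},
    "cluster": {"method": "atsea-upgmc"},
    "habitat": {
        "ratio": 5,
        "k": 5,
        "n_bins": 40,
        "candidates": ["depth", "sand", "gravel", "tidal_power", "peak_spring_flow", "peak_neap_flow"],
    },
    # the synthetic demo tags far fewer animals than a real campaign, so the
    # data-rich threshold is relaxed from 7 to 3 in the default configuration
    "uncertainty": {"haulout_prob": [0.72, 0.05], "n_boot": 10000, "min_animals": 3},
}


@dataclass
class ScaledClusterMap:
    cluster_id: int
    type: str
    mean: np.ndarray
    variance: np.ndarray


@dataclass
class UsageMapWithCI:
    grid: GridSpec
    mean: np.ndarray
    variance: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    provenance: dict[str, float] = field(default_factory=dict)


def assemble(maps: list[ScaledClusterMap], grid: GridSpec, z: float = 1.959963984540054) -> UsageMapWithCI:
    """Combine scaled cluster maps into one usage map with 95% CIs.

    Means and variances are summed cell-wise (independence across clusters)
    and the confidence surfaces recomputed from the combined variance.
    """
    if not maps:
        raise ValueError("no cluster maps to assemble")
    shape = (grid.nrows, grid.ncols)
    mean = np.zeros(shape)
    var = np.zeros(shape)
    totals = {"telemetry": 0.0, "model": 0.0}
    for m in maps:
        if m.mean.shape != shape or m.variance.shape != shape:
            raise ValueError(f"cluster {m.cluster_id}: map grid mismatch")
        mean += m.mean
        var += m.variance
        totals["telemetry" if m.type == "telemetry" else "model"] += float(m.mean.sum())
    grand = totals["telemetry"] + totals["model"]
    prov = {k: (v / grand if grand > 0 else 0.0) for k, v in totals.items()}
    sd = np.sqrt(var)
    return UsageMapWithCI(
        grid=grid,
        mean=mean,
        variance=var,
        lower95=np.maximum(mean - z * sd, 0.0),
        upper95=mean + z * sd,
        provenance=prov,
    )


def summarise(
    usage_map: UsageMapWithCI,
    cluster_totals: pd.DataFrame | None = None,
    distance_surface: DistanceSurface | None = None,
    band_km: float = 5.0,
) -> dict:
    """Headline numbers of an assembled map.

    Totals with CI bounds, provenance percentages, optional per-cluster
    totals and the fraction of usage within successive at-sea distance bands
    of the nearest haul-out.
    """
    out = {
        "total_mean": float(usage_map.mean.sum()),
        "total_lower95": float(usage_map.lower95.sum()),
        "total_upper95": float(usage_map.upper95.sum()),
        "provenance_telemetry_pct": 100.0 * usage_map.provenance.get("telemetry", 0.0),
        "provenance_model_pct": 100.0 * usage_map.provenance.get("model", 0.0),
    }
    if cluster_totals is not None:
        out["cluster_totals"] = cluster_totals.to_dict(orient="records")
    if distance_surface is not None:
        d = distance_surface.values
        ok = np.isfinite(d) & usage_map.grid.sea
        total = usage_map.mean[ok].sum()
        bands = {}
        edges = np.arange(0, np.nanmax(d[ok]) / 1000.0 + band_km, band_km)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = ok & (d >= lo * 1000.0) & (d < hi * 1000.0)
            bands[f"{lo:g}-{hi:g}km"] = float(usage_map.mean[mask].sum() / total) if total > 0 else 0.0
        out["distance_bands"] = bands
    return out


# ---------------------------------------------------------------------------
# pipeline


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


class Pipeline:
    """Staged, restartable analysis run on a synthetic world."""

    def __init__(self, config: dict | None = None):
        self.config = _merge(DEFAULT_CONFIG, config or {})
        self.outdir = Path(self.config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.config["seed"])
        self._ran: set[str] = set()
        # in-memory state
        self.world = None
        self.fixes = None
        self.meta = None
        self.tracks = None
        self.assoc = None
        self.haulout_cells = None
        self.pair_dist = None
        self.scan = None
        self.linkage = None
        self.chosen_scale_km = None
        self.clusters = None
        self.graph = None
        self.dist_surfaces: dict[int, DistanceSurface] = {}
        self.animal_surfaces: dict[int, dict[str, kd.UsageSurface]] = {}
        self.cluster_surfaces: dict[int, kd.UsageSurface] = {}
        self.weights: dict[int, dict[str, float]] = {}
        self.discovery = None
        self.model = None
        self.trace = None
        self.scaled: list[ScaledClusterMap] = []
        self.populations: list[un.PopulationEstimate] = []
        self.at_sea_frac = None
        self.result: UsageMapWithCI | None = None
        self.summary: dict | None = None

    # -- helpers ---------------------------------------------------------
    def _worlddir(self) -> Path:
        return self.outdir / "world"

    def _outputs(self, stage: str) -> list[Path]:
        w, o = self._worlddir(), self.outdir
        return {
            "simulate": [w / "telemetry.csv", w / "truth.yaml", w / "land_mask.asc"],
            "prep": [o / "tracks.csv", o / "assoc.csv", o / "exclusions.yaml"],
            "distance": [o / "haulout_cells.csv", o / "haulout_dist.csv"],
            "cluster": [o / "scan.csv", o / "clusters.geojson", o / "cluster_scale.yaml"],
            "kde": [o / "discovery.csv", o / "weights.yaml", o / "kde.done"],
            "habitat": [o / "habitat_model.yaml", o / "selection_trace.csv"],
            "scale": [o / "populations.csv", o / "scale.done"],
            "assemble": [o / "usage_mean.asc", o / "usage_lower95.asc", o / "usage_upper95.asc", o / "summary.yaml"],
        }[stage]

    def _needs(self, stage: str) -> bool:
        if any(s in self._ran for s in STAGES[: STAGES.index(stage)]):
            return True
        return not all(p.exists() for p in self._outputs(stage))

    # -- stage bodies ----------------------------------------------------
    def _stage_simulate(self) -> None:
        cfg = self.config
        self.world = gen_world(seed=self.seed, **cfg["world"])
        self.fixes, self.meta = simulate_tracks(self.world, seed=self.seed + 1, **cfg["tracks"])
        write_world(self.world, self.fixes, self.meta, self._worlddir())

    def _load_simulate(self) -> None:
        self.world, self.fixes, self.meta = read_world(self._worlddir())

    def _stage_prep(self) -> None:
        cfg = self.config["prep"]
        self.tracks, self.assoc, excl = tp.prepare(self.fixes, self.world.grid, **cfg)
        t = self.tracks.copy()
        t["timestamp"] = pd.to_datetime(t["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        t.to_csv(self.outdir / "tracks.csv", index=False)
        a = self.assoc.copy()
        a["timestamp"] = pd.to_datetime(a["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        a.to_csv(self.outdir / "assoc.csv", index=False)
        with open(self.outdir / "exclusions.yaml", "w") as fh:
            yaml.safe_dump(excl, fh)

    def _load_prep(self) -> None:
        self.tracks = pd.read_csv(self.outdir / "tracks.csv", parse_dates=["timestamp"])
        self.assoc = pd.read_csv(self.outdir / "assoc.csv", parse_dates=["timestamp"])

    def _stage_distance(self) -> None:
        grid = self.world.grid
        self.graph = build_sea_graph(grid)
        cells = hc.identify_haulout_cells(self.tracks, self.world.survey, grid)
        self.haulout_cells = cells
        pd.DataFrame(cells, columns=["row", "col"]).to_csv(self.outdir / "haulout_cells.csv", index=False)
        from .seadist import pairwise_atsea_distances

        self.pair_dist = pairwise_atsea_distances(grid, np.array(cells), graph=self.graph)
        pd.DataFrame(self.pair_dist).to_csv(self.outdir / "haulout_dist.csv", index=False)

    def _load_distance(self) -> None:
        cells = pd.read_csv(self.outdir / "haulout_cells.csv")
        self.haulout_cells = [tuple(map(int, r)) for r in cells.to_numpy()]
        self.pair_dist = pd.read_csv(self.outdir / "haulout_dist.csv").to_numpy(dtype=float)
        self.graph = build_sea_graph(self.world.grid)

    def _stage_cluster(self) -> None:
        grid = self.world.grid
        self.scan, self.linkage = hc.cluster_scan(
            self.haulout_cells, grid, method=self.config["cluster"]["method"], distances=self.pair_dist
        )
        self.scan.to_csv(self.outdir / "scan.csv", index=False)
        self.chosen_scale_km = hc.changepoint_scale(self.scan)
        labels = hc.cut_clusters(self.linkage, self.chosen_scale_km)
        self.clusters = hc.classify_and_adjust(
            self.haulout_cells, labels, self.tracks, self.assoc, self.world.survey, grid
        )
        with open(self.outdir / "clusters.geojson", "w") as fh:
            json.dump(hc.clusters_to_geojson(self.clusters, grid), fh, indent=1)
        with open(self.outdir / "cluster_scale.yaml", "w") as fh:
            yaml.safe_dump({"chosen_scale_km": float(self.chosen_scale_km)}, fh)

    def _load_cluster(self) -> None:
        with open(self.outdir / "cluster_scale.yaml") as fh:
            self.chosen_scale_km = float(yaml.safe_load(fh)["chosen_scale_km"])
        with open(self.outdir / "clusters.geojson") as fh:
            gj = json.load(fh)
        grid = self.world.grid
        out = []
        for f in gj["features"]:
            p = f["properties"]
            cells = [tuple(map(int, grid.cell_of(x, y))) for x, y in f["geometry"]["coordinates"]]
            out.append(
                hc.HaulOutCluster(
                    int(p["cluster_id"]), cells, p["type"], float(p["raw_count"]),
                    float(p["adjusted_count"]), set(p["animals"]),
                )
            )
        self.clusters = out
        self.scan = pd.read_csv(self.outdir / "scan.csv")

    def _cluster_of_cell(self) -> dict[tuple[int, int], int]:
        return {cell: c.cluster_id for c in self.clusters for cell in c.cells}

    def _ensure_dist_surfaces(self) -> None:
        if self.graph is None:
            self.graph = build_sea_graph(self.world.grid)
        for c in self.clusters:
            if c.cluster_id not in self.dist_surfaces:
                self.dist_surfaces[c.cluster_id] = atsea_distance(
                    self.world.grid, np.array(c.cells), graph=self.graph, source=c.cluster_id
                )

    def _stage_kde(self) -> None:
        grid = self.world.grid
        cell2cl = self._cluster_of_cell()
        assoc = self.assoc.copy()
        assoc["cluster_id"] = [
            cell2cl.get((int(r), int(c)), -1) for r, c in zip(assoc["assoc_row"], assoc["assoc_col"])
        ]
        assoc = assoc[assoc["cluster_id"] >= 0]

        rates = pd.DataFrame(
            [
                {"animal_id": aid, "discovery_rate": kd.discovery_rate(g, grid)}
                for aid, g in self.tracks.groupby("animal_id")
            ]
        )
        self.discovery = rates
        try:
            fitted = kd.fit_weight_model(rates, self.meta)
        except ValueError as e:
            logger.warning("weight model unavailable (%s); using equal weights", e)
            fitted = rates.copy()
            fitted["fitted_rate"] = 1.0
        rate_map = dict(zip(fitted["animal_id"], fitted["fitted_rate"]))
        rates.to_csv(self.outdir / "discovery.csv", index=False)

        bandwidths: dict[str, np.ndarray] = {}
        for aid, g in assoc.groupby("animal_id"):
            pts = g[["x_m", "y_m"]].to_numpy()
            if len(pts) < 10:
                logger.info("animal %s has %d at-sea fixes; skipped from KDE", aid, len(pts))
                continue
            bandwidths[aid] = kd.select_bandwidth(pts)

        self.animal_surfaces = {}
        self.cluster_surfaces = {}
        self.weights = {}
        for c in self.clusters:
            if c.type != "telemetry":
                continue
            group: dict[str, kd.UsageSurface] = {}
            for aid, g in assoc[assoc["cluster_id"] == c.cluster_id].groupby("animal_id"):
                if aid not in bandwidths:
                    continue
                pts = g[["x_m", "y_m"]].to_numpy()
                try:
                    group[str(aid)] = kd.kde_surface(pts, bandwidths[aid], grid)
                except ValueError as e:
                    logger.warning("KDE failed for animal %s cluster %d: %s", aid, c.cluster_id, e)
            if not group:
                logger.warning("telemetry cluster %d has no usable surfaces", c.cluster_id)
                continue
            self.animal_surfaces[c.cluster_id] = group
            surf, w = kd.cluster_usage(group, {a: rate_map.get(a, 1.0) for a in group})
            self.cluster_surfaces[c.cluster_id] = surf
            self.weights[c.cluster_id] = w
            write_ascii_grid(self.outdir / f"cluster_{c.cluster_id}_usage.asc", grid, surf.values)
            for aid, s in group.items():
                write_ascii_grid(self.outdir / f"animal_{aid}_cluster_{c.cluster_id}.asc", grid, s.values)
        with open(self.outdir / "weights.yaml", "w") as fh:
            yaml.safe_dump({int(k): {a: float(x) for a, x in v.items()} for k, v in self.weights.items()}, fh)
        (self.outdir / "kde.done").write_text("ok\n")

    def _load_kde(self) -> None:
        grid = self.world.grid
        self.discovery = pd.read_csv(self.outdir / "discovery.csv")
        with open(self.outdir / "weights.yaml") as fh:
            self.weights = yaml.safe_load(fh) or {}
        self.cluster_surfaces = {}
        self.animal_surfaces = {}
        for c in self.clusters:
            p = self.outdir / f"cluster_{c.cluster_id}_usage.asc"
            if p.exists():
                vals, _ = read_ascii_grid(p)
                vals = np.nan_to_num(vals)
                self.cluster_surfaces[c.cluster_id] = kd.UsageSurface(grid, vals, "per-cluster")
                group = {}
                for aid in self.weights.get(c.cluster_id, {}):
                    ap = self.outdir / f"animal_{aid}_cluster_{c.cluster_id}.asc"
                    if ap.exists():
                        av, _ = read_ascii_grid(ap)
                        group[aid] = kd.UsageSurface(grid, np.nan_to_num(av), "per-animal")
                self.animal_surfaces[c.cluster_id] = group

    def _presence_table(self) -> pd.DataFrame:
        grid = self.world.grid
        cell2cl = self._cluster_of_cell()
        year_map = dict(zip(self.meta["animal_id"], self.meta["deployment_year"]))
        a = self.assoc
        r, c = grid.cell_of(a["x_m"].to_numpy(), a["y_m"].to_numpy())
        df = pd.DataFrame(
            {
                "animal_id": a["animal_id"],
                "cluster_id": [cell2cl.get((int(ar), int(ac)), -1) for ar, ac in zip(a["assoc_row"], a["assoc_col"])],
                "row": r,
                "col": c,
            }
        )
        ok = (df["cluster_id"] >= 0) & grid.in_bounds(r, c)
        df = df[ok]
        df = df[grid.sea[df["row"], df["col"]]]
        df["year"] = [int(year_map[a]) for a in df["animal_id"]]
        return df.reset_index(drop=True)

    def _stage_habitat(self) -> None:
        cfg = self.config["habitat"]
        grid = self.world.grid
        self._ensure_dist_surfaces()
        presences = self._presence_table()
        reachable = {
            c.cluster_id: np.argwhere(self.dist_surfaces[c.cluster_id].reachable())
            for c in self.clusters
        }
        design = hb.sample_pseudo_absences(
            presences, reachable, ratio=cfg["ratio"], seed=np.random.default_rng(self.seed + 2)
        )
        candidates = [n for n in cfg["candidates"] if n in self.world.covariates]
        design = hb.attach_covariates(design, self.world.covariates, self.dist_surfaces, names=candidates)
        vifs, pairs = hb.vif_screen(design[candidates])
        with open(self.outdir / "vif.yaml", "w") as fh:
            yaml.safe_dump({"vif": {k: float(v) for k, v in vifs.items()}, "excluded_pairs": [list(p) for p in pairs]}, fh)
        counts = design[design["response"] == 1].groupby("cluster_id").size().to_dict()
        k = min(int(cfg["k"]), len(counts))
        if k < int(cfg["k"]):
            logger.warning("only %d presence clusters; reducing cross-validation folds to %d", len(counts), k)
        if k < 2:
            raise ValueError("need at least 2 presence clusters for cross-validation")
        folds = hb.make_folds(counts, k=k, seed=np.random.default_rng(self.seed + 3))
        self.model, self.trace = hb.forward_select(
            design, candidates, folds, exclusion_pairs=pairs, n_bins=cfg["n_bins"]
        )
        self.trace.to_csv(self.outdir / "selection_trace.csv", index=False)
        with open(self.outdir / "habitat_model.yaml", "w") as fh:
            yaml.safe_dump(self.model.to_dict(), fh)
        # null-cluster predicted usage
        for c in self.clusters:
            if c.type == "null":
                u = hb.predict_null_cluster(self.model, self.dist_surfaces[c.cluster_id], self.world.covariates)
                self.cluster_surfaces[c.cluster_id] = kd.UsageSurface(grid, u, "per-cluster")
                write_ascii_grid(self.outdir / f"cluster_{c.cluster_id}_usage.asc", grid, u)

    def _load_habitat(self) -> None:
        with open(self.outdir / "habitat_model.yaml") as fh:
            self.model = hb.HabitatModel.from_dict(yaml.safe_load(fh))
        self.trace = pd.read_csv(self.outdir / "selection_trace.csv")
        grid = self.world.grid
        for c in self.clusters:
            if c.type == "null":
                p = self.outdir / f"cluster_{c.cluster_id}_usage.asc"
                if p.exists():
                    vals, _ = read_ascii_grid(p)
                    self.cluster_surfaces[c.cluster_id] = kd.UsageSurface(grid, np.nan_to_num(vals), "per-cluster")

    def _stage_scale(self) -> None:
        cfg = self.config["uncertainty"]
        self.at_sea_frac, _ = un.at_sea_fraction(self.tracks)
        try:
            var_model = un.fit_variance_model(
                self.animal_surfaces, min_animals=cfg["min_animals"], seed=self.seed + 4
            )
        except ValueError as e:
            # small campaigns may leave too few multi-animal clusters for the
            # regression; fall back to whatever clusters have >= 2 animals
            logger.warning("%s; falling back to all multi-animal clusters", e)
            var_model = un.fit_variance_model(
                self.animal_surfaces, min_animals=2, seed=self.seed + 4, min_clusters=1
            )
        p_mean, p_sd = cfg["haulout_prob"]
        self.scaled = []
        self.populations = []
        rows = []
        for c in self.clusters:
            surf = self.cluster_surfaces.get(c.cluster_id)
            if surf is None:
                logger.warning("cluster %d has no usage surface; skipped", c.cluster_id)
                continue
            n_animals = len(self.animal_surfaces.get(c.cluster_id, {}))
            if c.type == "telemetry" and n_animals >= cfg["min_animals"]:
                _, var_surface = un.within_cluster_variance(self.animal_surfaces[c.cluster_id])
            else:
                var_surface = un.predict_variance(var_model, surf.values, 0 if c.type == "null" else n_animals)
                var_surface = np.where(surf.values > 0, var_surface, 0.0)
            pop = un.population_estimate(
                c.cluster_id, c.adjusted_count, (p_mean, p_sd), n_boot=cfg["n_boot"],
                seed=np.random.default_rng(self.seed + 5 + c.cluster_id),
            )
            self.populations.append(pop)
            parts = un.scale_and_combine(surf, var_surface, pop, self.at_sea_frac)
            self.scaled.append(ScaledClusterMap(c.cluster_id, c.type, parts["mean"], parts["variance"]))
            rows.append(
                dict(
                    cluster_id=c.cluster_id, type=c.type, n_animals=n_animals,
                    adjusted_count=c.adjusted_count, population_mean=pop.mean,
                    population_var=pop.variance, scaled_total=float(parts["mean"].sum()),
                )
            )
        pd.DataFrame(rows).to_csv(self.outdir / "populations.csv", index=False)
        (self.outdir / "scale.done").write_text("ok\n")

    def _load_scale(self) -> None:
        # scaled maps are cheap to recompute deterministically
        self._stage_scale()

    def _stage_assemble(self) -> None:
        grid = self.world.grid
        self.result = assemble(self.scaled, grid)
        all_haulouts = [cell for c in self.clusters for cell in c.cells]
        dist_all = atsea_distance(grid, np.array(all_haulouts), graph=self.graph)
        per_cluster = pd.read_csv(self.outdir / "populations.csv")
        self.summary = summarise(self.result, per_cluster, dist_all)
        self.summary["chosen_scale_km"] = float(self.chosen_scale_km)
        self.summary["n_clusters"] = len(self.clusters)
        self.summary["n_telemetry_clusters"] = sum(1 for c in self.clusters if c.type == "telemetry")
        self.summary["n_null_clusters"] = sum(1 for c in self.clusters if c.type == "null")
        self.summary["at_sea_fraction"] = float(self.at_sea_frac)
        write_ascii_grid(self.outdir / "usage_mean.asc", grid, self.result.mean)
        write_ascii_grid(self.outdir / "usage_lower95.asc", grid, self.result.lower95)
        write_ascii_grid(self.outdir / "usage_upper95.asc", grid, self.result.upper95)
        with open(self.outdir / "provenance.json", "w") as fh:
            json.dump({k: float(v) for k, v in self.result.provenance.items()}, fh, indent=1)
        with open(self.outdir / "summary.yaml", "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.summary)), fh)
        with open(self.outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"seed": self.seed, "config": json.loads(json.dumps(self.config))}, fh)

    # -- driver ----------------------------------------------------------
    def run(self, through: str = "assemble") -> "Pipeline":
        if through not in STAGES:
            raise ValueError(f"unknown stage {through!r}")
        for stage in STAGES[: STAGES.index(through) + 1]:
            body = getattr(self, f"_stage_{stage}")
            loader = getattr(self, f"_load_{stage}", None)
            t0 = time.time()
            if self._needs(stage):
                logger.info("running stage %s", stage)
                try:
                    body()
                except Exception:
                    logger.error("stage %s failed", stage)
                    raise
                self._ran.add(stage)
            else:
                logger.info("stage %s up to date; loading outputs", stage)
                if loader is not None:
                    loader()
            logger.info("stage %s done in %.2fs", stage, time.time() - t0)
        return self


def run_pipeline(config: dict | None = None, through: str = "assemble") -> Pipeline:
    """Run (or resume) the full analysis; returns the pipeline with results."""
    return Pipeline(config).run(through=through)
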