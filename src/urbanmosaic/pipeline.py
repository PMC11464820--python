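"""Staged pipeline runner with manifests.

Wires the framework's steps — classify, build (rasterize + priority
merge), integrate (global backfill), validate, index, occupancy — over
files on disk, writing a JSON manifest per run (inputs, config hash, seed)
so deterministic stages can be re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_features
from .features import read_features, write_features
from .index import IndexConfig, urbanization_index
from .occupancy import (
    DetectionHistory,
    compare_aic,
    fit_autologistic,
    naive_occupancy,
    summarize_covariate,
)
from .overlay import ReclassMap, align_nearest, build_lulc, integrate, reclass_global
from .raster import GridSpec, read_raster, write_raster
from .registry import ClassRegistry, default_registry
from .validate import completeness, confusion, kappa, precision, stratified_sample

logger = logging.getLogger(__name__)

ALL_STAGES = ("classify", "build", "integrate", "validate", "index", "occupancy")


@dataclass
class RunConfig:
    out_dir: Path
    features_polygons: Path | None = None
    features_lines: Path | None = None
    global_raster: Path | None = None
    registry_path: Path | None = None
    detections: Path | None = None
    sites: Path | None = None
    grid: GridSpec | None = None
    crs: str | None = None
    seed: int = 0
    n_per_class: int = 30
    index_config: IndexConfig = field(default_factory=IndexConfig)
    reclass_path: Path | None = None

    def registry(self) -> ClassRegistry:
        if self.registry_path:
            return ClassRegistry.from_yaml(self.registry_path)
        return default_registry()


def _hash_config(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if not k.startswith("_")}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, stages) -> dict:
    """Run the requested stages in order; returns the artifact manifest."""
    stages = [s for s in ALL_STAGES if s in set(stages)]
    if not stages:
        raise ValueError("no recognized stages requested")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg = cfg.registry()
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _hash_config(cfg),
        "stages": stages,
        "artifacts": {},
    }
    art = manifest["artifacts"]

    def need(path, stage, hint):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"stage {stage!r} needs {hint}; run {hint} first or pass the path")
        return Path(path)

    fc_polys = fc_lines = None
    if "classify" in stages or "build" in stages:
        fc_polys = read_features(need(cfg.features_polygons, "classify", "polygon features"), "polygons", crs=cfg.crs)
        fc_lines = read_features(need(cfg.features_lines, "classify", "line features"), "lines", crs=cfg.crs)

    if "classify" in stages:
        cls_dir = out / "classified"
        cls_dir.mkdir(exist_ok=True)
        for label, fc in (("polygons", fc_polys), ("lines", fc_lines)):
            by_class = classify_features(fc, reg)
            for code, sub in by_class.items():
                if len(sub) == 0:
                    continue
                p = cls_dir / f"class_{code:02d}_{label}.geojson"
                write_features(sub, p)
                art[f"classify/{p.name}"] = str(p)
                logger.info("class %s (%s): %d features", code, label, len(sub))

    lulc_osm_path = out / "lulc_osm.tif"
    if "build" in stages:
        grid = cfg.grid
        if grid is None:
            raise ValueError("build stage needs a grid (bbox + cell size)")
        osm_r = build_lulc(fc_polys, fc_lines, reg, grid)
        write_raster(osm_r, lulc_osm_path)
        art["build/lulc_osm.tif"] = str(lulc_osm_path)
        logger.info("built OSM-only raster: %d void cells", int((osm_r.values == osm_r.nodata).sum()))

    lulc_path = out / "lulc.tif"
    if "integrate" in stages:
        osm_r = read_raster(need(lulc_osm_path, "integrate", "build"))
        glob = read_raster(need(cfg.global_raster, "integrate", "a global raster"))
        rmap = ReclassMap.from_csv(cfg.reclass_path) if cfg.reclass_path else _default_reclass()
        glob_f = reclass_global(glob, rmap)
        if not glob_f.same_grid(osm_r):
            glob_f = align_nearest(glob_f, osm_r.grid())
        merged = integrate(osm_r, glob_f)
        write_raster(merged, lulc_path)
        art["integrate/lulc.tif"] = str(lulc_path)

    if "validate" in stages:
        osm_r = read_raster(need(lulc_osm_path, "validate", "build"))
        glob = read_raster(need(cfg.global_raster, "validate", "a global raster"))
        rmap = ReclassMap.from_csv(cfg.reclass_path) if cfg.reclass_path else _default_reclass()
        glob_f = reclass_global(glob, rmap)
        if not glob_f.same_grid(osm_r):
            glob_f = align_nearest(glob_f, osm_r.grid())
        rep = completeness(osm_r, glob_f, reg)
        final = read_raster(lulc_path) if lulc_path.exists() else integrate(osm_r, glob_f)
        sample = stratified_sample(final, cfg.n_per_class, cfg.seed)
        pairs = [
            (code, int(glob_f.values[rc]))
            for rc, code in sample
            if glob_f.values[rc] != glob_f.nodata
        ]
        cm = confusion(pairs)
        report = {
            "overall_completeness": rep.overall_completeness,
            "urban_proportion": rep.urban_proportion,
            "unknown_subcategory_share": {str(k): v for k, v in rep.unknown_subcategory_share.items()},
            "per_class_area_diff_m2": {str(k): v for k, v in rep.per_class_area_diff.items()},
            "kappa_vs_global": kappa(cm),
            "precision_vs_global": {str(k): v for k, v in precision(cm).items()},
            "n_points": cm.n,
        }
        vp = out / "validation.json"
        vp.write_text(json.dumps(report, indent=2))
        art["validate/validation.json"] = str(vp)

    index_path = out / "index.tif"
    if "index" in stages:
        lulc = read_raster(need(lulc_path, "index", "integrate"))
        idx = urbanization_index(lulc, cfg.index_config)
        write_raster(idx, index_path)
        art["index/index.tif"] = str(index_path)

    if "occupancy" in stages:
        records = pd.read_csv(need(cfg.detections, "occupancy", "a detections CSV"))
        h = DetectionHistory.from_records(records)
        sites_df = pd.read_csv(need(cfg.sites, "occupancy", "a sites CSV")).set_index("site")
        sites_df.index = sites_df.index.astype(str)
        xy = sites_df.loc[h.sites, ["x", "y"]].to_numpy()
        idx = read_raster(need(index_path, "occupancy", "index"))
        cov = summarize_covariate(idx, xy)
        fits = {
            "null": fit_autologistic(h, cov, "null", seed=cfg.seed),
            "covariate": fit_autologistic(h, cov, "covariate", seed=cfg.seed),
        }
        table = compare_aic(fits)
        per_season, avg = naive_occupancy(h)
        best = fits[table.loc[0, "model"]]
        occ_report = {
            "naive_occupancy": {"per_season": per_season, "average": avg},
            "aic_table": table.to_dict(orient="records"),
            "best_model": table.loc[0, "model"],
            "estimates": {
                "beta": best.params.beta.tolist(),
                "theta": best.params.theta,
                "alpha": best.params.alpha.tolist(),
                "se": np.asarray(best.se()).tolist(),
            },
        }
        op = out / "occupancy.json"
        op.write_text(json.dumps(occ_report, indent=2))
        art["occupancy/occupancy.json"] = str(op)

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    return manifest


def _default_reclass():
    from .fixtures import default_reclass_map

    return default_reclass_map()
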