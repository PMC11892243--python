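"""Reading and writing the pipeline's on-disk formats.

Points travel as CSV (``x_um, y_um, confidence, compartment``) or QuPath-style
GeoJSON point features; label rasters as single-channel PNG/TIFF with a
sidecar JSON carrying ``{mpp, origin_um, class_map}``; heatmaps as float32
TIFF (or 8-bit PNG, value/255) with the same sidecar; configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .geometry import LabelRaster
from .points import DetectionConfig, PointSet
from .scoring import FlagCriteria, ScoringConfig

__all__ = [
    "read_points_csv", "write_points_csv",
    "read_points_geojson", "write_points_geojson",
    "read_raster", "write_raster",
    "read_heatmap", "write_heatmap",
    "load_config", "detection_config_from", "scoring_config_from", "flag_criteria_from",
    "summarize_manifest",
]


# -- points -------------------------------------------------------------------


def write_points_csv(points: PointSet, path: str | Path) -> None:
    comp = points.compartment
    df = pd.DataFrame({
        "x_um": points.xy_um[:, 0],
        "y_um": points.xy_um[:, 1],
        "confidence": points.confidence,
        "compartment": comp if comp is not None else [""] * len(points),
    })
    df.to_csv(path, index=False)


def read_points_csv(path: str | Path) -> PointSet:
    df = pd.read_csv(path)
    if df.empty:
        return PointSet.empty()
    xy = df[["x_um", "y_um"]].to_numpy(float)
    conf = df["confidence"].to_numpy(float) if "confidence" in df else None
    comp = None
    if "compartment" in df and df["compartment"].notna().any():
        comp = df["compartment"].fillna("unassigned").astype(str).to_numpy(object)
    return PointSet(xy, conf, comp)


def write_points_geojson(points: PointSet, path: str | Path) -> None:
    """QuPath-compatible point features: confidence and classification properties."""
    feats = []
    comp = points.compartment
    for i in range(len(points)):
        props: dict = {"confidence": float(points.confidence[i]), "objectType": "detection"}
        if comp is not None:
            props["classification"] = {"name": str(comp[i])}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(points.xy_um[i, 0]), float(points.xy_um[i, 1])]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_points_geojson(path: str | Path) -> PointSet:
    data = json.loads(Path(path).read_text())
    xy, conf, comp = [], [], []
    has_comp = False
    for f in data.get("features", []):
        if f.get("geometry", {}).get("type") != "Point":
            continue
        xy.append(f["geometry"]["coordinates"][:2])
        props = f.get("properties", {})
        conf.append(float(props.get("confidence", 1.0)))
        cls = props.get("classification")
        if cls:
            has_comp = True
            comp.append(cls.get("name", "unassigned") if isinstance(cls, dict) else str(cls))
        else:
            comp.append("unassigned")
    if not xy:
        return PointSet.empty()
    return PointSet(np.array(xy, float), np.array(conf),
                    np.array(comp, dtype=object) if has_comp else None)


# -- rasters ------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(raster: LabelRaster, path: str | Path) -> None:
    path = Path(path)
    grid = raster.grid.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, grid)
    else:
        Image.fromarray(grid, mode="L").save(path)
    meta = {"mpp": raster.mpp, "origin_um": list(raster.origin_um),
            "class_map": dict(raster.class_map)}
    _sidecar(path).write_text(json.dumps(meta))


def read_raster(path: str | Path) -> LabelRaster:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
    else:
        grid = np.asarray(Image.open(path))
    return LabelRaster(grid, float(meta["mpp"]), {k: int(v) for k, v in meta["class_map"].items()},
                       tuple(meta.get("origin_um", (0.0, 0.0))))


def write_heatmap(heatmap: np.ndarray, mpp: float, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, heatmap.astype(np.float32))
        encoding = "float32"
    else:
        Image.fromarray(np.clip(np.rint(heatmap * 255), 0, 255).astype(np.uint8), "L").save(path)
        encoding = "uint8/255"
    _sidecar(path).write_text(json.dumps({"mpp": mpp, "encoding": encoding}))


def read_heatmap(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        heat = tifffile.imread(path).astype(np.float64)
    else:
        heat = np.asarray(Image.open(path), dtype=np.float64) / 255.0
    return heat, float(meta["mpp"])


# -- configuration ------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def detection_config_from(cfg: dict) -> DetectionConfig:
    return DetectionConfig(**{k: cfg[k] for k in
                              ("confidence_threshold", "min_separation_um", "nms_radius_um")
                              if k in cfg})


def scoring_config_from(cfg: dict) -> ScoringConfig:
    keys = ("hpf_diameter_mm", "min_tumour_frac", "cutoff_per_mm2",
            "manual_cutoff_per_hpf", "n_manual_hpfs")
    return ScoringConfig(**{k: cfg[k] for k in keys if k in cfg})


def flag_criteria_from(cfg: dict) -> FlagCriteria:
    keys = ("min_tumour_area_mm2", "min_eligible_fields", "min_cancer_fraction",
            "flag_on_stain_failure")
    return FlagCriteria(**{k: cfg[k] for k in keys if k in cfg})


# -- dataset manifests --------------------------------------------------------


def summarize_manifest(entries) -> dict:
    """Validate and total a dataset manifest.

    Each entry describes one annotated source: ``{"cohort": str, "wsis": int,
    "regions": int, "annotations": int}``.  Returns per-cohort rows plus
    ``n_wsis`` / ``n_regions`` / ``n_annotations`` grand totals.
    """
    rows = []
    for e in entries:
        for k in ("wsis", "regions", "annotations"):
            v = e.get(k)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"manifest entry {e.get('cohort')!r}: {k} must be a "
                                 f"nonnegative integer, got {v!r}")
        rows.append(dict(e))
    if not rows:
        raise ValueError("empty manifest")
    return {
        "cohorts": rows,
        "n_wsis": sum(r["wsis"] for r in rows),
        "n_regions": sum(r["regions"] for r in rows),
        "n_annotations": sum(r["annotations"] for r in rows),
    }
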