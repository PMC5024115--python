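"""File interchange: scene-series directories (multi-band TIFF + CSV
index + YAML grid), single-band masks, GeoJSON polygon sets, and YAML
scene configs."""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .cloudmask import MaskOverride
from .grid import Grid
from .series import BANDS, SceneSeries
from .synthetic_scene import (
    Blob,
    CloudModel,
    GlintEvent,
    IslandEvent,
    PlumeEvent,
    SceneConfig,
    footprint_for_area,
)


def save_grid(grid: Grid, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "lat_min": grid.lat_min,
                "lat_max": grid.lat_max,
                "lon_min": grid.lon_min,
                "lon_max": grid.lon_max,
                "pixel_size_m": grid.pixel_size_m,
            },
            fh,
        )


def load_grid(path) -> Grid:
    with open(path) as fh:
        return Grid(**yaml.safe_load(fh))


def save_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def save_series(series: SceneSeries, outdir) -> None:
    """Write a series as per-date multi-band TIFFs plus index.csv and
    grid.yaml. Band order in each TIFF follows ``BANDS``; the cloud mask
    is appended as a final uint8-encoded plane."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_grid(series.grid, outdir / "grid.yaml")
    rows = []
    for i, date in enumerate(series.dates):
        stack = np.stack(
            [series.bands[wl][i].astype(np.float32) for wl in BANDS]
            + [series.cloud[i].astype(np.float32)]
        )
        name = f"scene_{date.isoformat()}.tif"
        tifffile.imwrite(outdir / name, stack)
        rows.append({"date": date.isoformat(), "solar_zenith": float(series.solar_zenith[i]),
                     "file": name})
    pd.DataFrame(rows).to_csv(outdir / "index.csv", index=False)


def load_series(indir) -> SceneSeries:
    indir = Path(indir)
    grid = load_grid(indir / "grid.yaml")
    index = pd.read_csv(indir / "index.csv")
    dates, zeniths, frames = [], [], []
    for _, row in index.iterrows():
        dates.append(dt.date.fromisoformat(row["date"]))
        zeniths.append(float(row["solar_zenith"]))
        frames.append(tifffile.imread(indir / row["file"]))
    stack = np.stack(frames)  # (T, nbands+1, ny, nx)
    bands = {wl: stack[:, b].astype(np.float32) for b, wl in enumerate(BANDS)}
    cloud = stack[:, len(BANDS)] > 0.5
    return SceneSeries(grid=grid, dates=tuple(dates), bands=bands, cloud=cloud,
                       solar_zenith=np.array(zeniths))


def polygons_to_geojson(features, path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)


def geojson_features(path):
    """Yield (shapely geometry, properties dict) from a GeoJSON file."""
    with open(path) as fh:
        fc = json.load(fh)
    for feat in fc.get("features", []):
        yield shape(feat["geometry"]), feat.get("properties", {}) or {}


def load_overrides(path) -> list[MaskOverride]:
    """Read cloudmask overrides from GeoJSON with ``mode`` and optional
    ``date_start``/``date_end`` properties."""
    out = []
    for geom, props in geojson_features(path):
        out.append(
            MaskOverride(
                polygon=geom,
                mode=props["mode"],
                date_start=dt.date.fromisoformat(props["date_start"]) if props.get("date_start") else None,
                date_end=dt.date.fromisoformat(props["date_end"]) if props.get("date_end") else None,
            )
        )
    return out


def _footprint_from_spec(spec, grid: Grid):
    if "polygon" in spec:
        return spec["polygon"]
    if "disk" in spec:
        d = spec["disk"]
        return Blob(d["lon"], d["lat"], d["radius_m"])
    if "area_km2" in spec:
        return footprint_for_area(grid, spec["lon"], spec["lat"], spec["area_km2"])
    raise ValueError(f"footprint spec must give 'polygon', 'disk' or 'area_km2': {spec}")


def _as_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def config_from_yaml(path) -> SceneConfig:
    """Build a SceneConfig from a YAML recipe (see README for schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    grid = Grid(**doc["grid"])
    dates = doc["dates"]
    kwargs = dict(
        grid=grid,
        start_date=_as_date(dates["start"]),
        end_date=_as_date(dates["end"]),
        revisit_days=int(dates.get("revisit_days", 1)),
        seed=int(doc.get("seed", 0)),
        noise_sd=float(doc.get("noise_sd", 0.002)),
    )
    if "spectra" in doc:
        kwargs["spectra"] = {cls: tuple(v) for cls, v in doc["spectra"].items()}
    if "reefs" in doc:
        kwargs["reef_polygons"] = {
            rid: _footprint_from_spec(spec, grid) for rid, spec in doc["reefs"].items()
        }
    if "islands" in doc:
        kwargs["islands"] = tuple(
            IslandEvent(
                reef_id=e["reef_id"],
                footprint=_footprint_from_spec(e["footprint"], grid),
                start_date=_as_date(e["start"]),
                end_date=_as_date(e["end"]),
                growth_curve=e.get("curve"),
            )
            for e in doc["islands"]
        )
    if "plumes" in doc:
        kwargs["plumes"] = tuple(
            PlumeEvent(
                reef_id=e["reef_id"],
                date=_as_date(e["date"]),
                footprint=_footprint_from_spec(e["footprint"], grid),
                ti_amplitude=float(e.get("ti_amplitude", 0.05)),
            )
            for e in doc["plumes"]
        )
    if "glints" in doc:
        kwargs["glints"] = tuple(
            GlintEvent(
                date=_as_date(e["date"]),
                magnitude=float(e["magnitude"]),
                pattern=e.get("pattern", "ramp"),
            )
            for e in doc["glints"]
        )
    if "clouds" in doc and doc["clouds"]:
        kwargs["clouds"] = CloudModel(**doc["clouds"])
    return SceneConfig(**kwargs)
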