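"""Shallow-water and new-island detection from reflectance time series.

Shallow water: pixels whose red band exceeds a reflectance threshold in
enough cloud-free passes within a calibration window. New islands: the
per-pixel ordinary-least-squares trend of the 859-nm band against time
in fractional years, thresholded at a calibrated slope.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .grid import Grid, PIXEL_AREA_KM2
from .series import DAYS_PER_YEAR, SceneSeries


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds.

    ``shallow_threshold`` (red-band reflectance) with ``shallow_min_count``
    exceedance passes define shallow water; ``slope_threshold`` (per year,
    on the dimensionless 859-nm reflectance) flags island creation;
    components below ``min_island_area_km2`` are reported but below the
    method's resolution; ``min_valid_obs`` guards slope fits against
    cloud-gap artifacts.
    """

    shallow_threshold: float = 0.005
    shallow_min_count: int = 20
    slope_threshold: float = 0.013
    min_island_area_km2: float = 0.06
    min_valid_obs: int = 10

    def __post_init__(self) -> None:
        for name in ("shallow_threshold", "shallow_min_count", "slope_threshold",
                     "min_island_area_km2", "min_valid_obs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SlopeGrid:
    """Per-pixel 859-nm trend (per year) and the cloud-free observation
    count behind each fit. Pixels with too few observations carry NaN."""

    slope: np.ndarray
    n_obs: np.ndarray
    min_valid_obs: int


def detect_shallow_water(
    series: SceneSeries,
    cfg: DetectionConfig | None = None,
    window: tuple[dt.date, dt.date] | None = None,
    band: int = 645,
) -> np.ndarray:
    """Shallow-water mask from red-band exceedance counts.

    A pixel is shallow iff its red-band value exceeds
    ``cfg.shallow_threshold`` in at least ``cfg.shallow_min_count``
    cloud-free passes inside ``window`` (inclusive; defaults to the full
    series span).
    """
    cfg = cfg or DetectionConfig()
    if window is None:
        window = (series.dates[0], series.dates[-1])
    d0, d1 = window
    if d0 > d1:
        raise ValueError("window start must not follow window end")
    if d0 < series.dates[0] or d1 > series.dates[-1]:
        raise ValueError("window extends outside the series date range")
    sel = [i for i, d in enumerate(series.dates) if d0 <= d <= d1]
    if not sel:
        raise ValueError("window contains no observations")
    red = series.bands[band]
    count = np.zeros(series.grid.shape, dtype=int)
    for i in sel:
        count += (~series.cloud[i]) & (red[i] > cfg.shallow_threshold)
    return count >= cfg.shallow_min_count


def fit_temporal_slope(
    series: SceneSeries,
    band: int = 859,
    cloud: np.ndarray | Sequence[np.ndarray] | None = None,
    min_valid_obs: int = 10,
) -> SlopeGrid:
    """Per-pixel OLS slope of a band against time, cloud-free obs only.

    Time is measured in fractional years from the first observation; the
    fit includes an intercept. Pixels with fewer than ``min_valid_obs``
    cloud-free observations (or a degenerate time spread) get NaN.
    """
    if band not in series.bands:
        raise ValueError(f"series has no band {band}")
    if cloud is None:
        cloud = series.cloud
    cloud = np.asarray(cloud, dtype=bool)
    if cloud.shape != (len(series), *series.grid.shape):
        raise ValueError("cloud stack shape does not match the series")
    t = series.years_since_start()
    y = series.bands[band]

    shape = series.grid.shape
    n = np.zeros(shape)
    st = np.zeros(shape)
    stt = np.zeros(shape)
    sy = np.zeros(shape)
    sty = np.zeros(shape)
    for i in range(len(series)):
        w = ~cloud[i]
        yi = np.where(w, y[i].astype(np.float64), 0.0)
        n += w
        st += w * t[i]
        stt += w * (t[i] * t[i])
        sy += yi
        sty += t[i] * yi

    denom = n * stt - st * st
    enough = n >= max(2, min_valid_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(enough & (denom > 0), (n * sty - st * sy) / denom, np.nan)
    return SlopeGrid(slope=slope, n_obs=n.astype(int), min_valid_obs=min_valid_obs)


def detect_new_islands(slopes: SlopeGrid, cfg: DetectionConfig | None = None) -> np.ndarray:
    """Pixels whose 859-nm trend exceeds the calibrated slope threshold
    with enough supporting observations."""
    cfg = cfg or DetectionConfig()
    with np.errstate(invalid="ignore"):
        hit = slopes.slope > cfg.slope_threshold
    return hit & (slopes.n_obs >= max(slopes.min_valid_obs, cfg.min_valid_obs))


@dataclass(frozen=True)
class IslandComponent:
    label: int
    n_pixels: int
    area_km2: float
    lat: float
    lon: float


def island_components(mask: np.ndarray, grid: Grid | None = None) -> list[IslandComponent]:
    """8-connected components of a detection mask with 1/16-km² areas.

    Centroids are reported in degrees when ``grid`` is given, otherwise
    as fractional (row, col) mapped through an identity grid.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    out = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if grid is not None:
            lat, lon = grid.rowcol_to_latlon(float(rows.mean()), float(cols.mean()))
        else:
            lat, lon = float(rows.mean()), float(cols.mean())
        out.append(
            IslandComponent(
                label=lab,
                n_pixels=rows.size,
                area_km2=rows.size * PIXEL_AREA_KM2,
                lat=lat,
                lon=lon,
            )
        )
    return out
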