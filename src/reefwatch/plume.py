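"""Turbidity-plume quantification.

Delineations (manual polygons or the automated surrogate) are rasterized
to pixel footprints; areas follow the fixed 1/16-km²-per-pixel rule.
Aggregations: per-reef time series, spatial frequency maps, union
("affected") extents, and the fraction of affected area hit only once.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .cloudmask import disk_element
from .grid import Grid, PIXEL_AREA_KM2, rasterize_polygon


@dataclass
class PlumeDelineation:
    """One dated plume delineation for one reef.

    ``footprint`` is the rasterized boolean mask; cloud-masked pixels
    are excluded at construction. ``source`` records provenance —
    automated surrogate delineations are labelled "auto" and are never
    silently merged with manual ones.
    """

    reef_id: str
    date: dt.date
    footprint: np.ndarray
    polygons: tuple = ()
    source: str = "manual"
    fully_clouded: bool = False

    def __post_init__(self) -> None:
        self.footprint = np.asarray(self.footprint, dtype=bool)

    @property
    def area_km2(self) -> float:
        return float(np.count_nonzero(self.footprint)) * PIXEL_AREA_KM2


def rasterize_delineation(
    reef_id: str,
    date: dt.date,
    polygons,
    grid: Grid,
    cloud: np.ndarray | None = None,
    source: str = "manual",
) -> PlumeDelineation:
    """Rasterize delineation polygons, excluding cloud-masked pixels."""
    footprint = rasterize_polygon(polygons, grid)
    if cloud is not None:
        footprint &= ~np.asarray(cloud, dtype=bool)
    return PlumeDelineation(reef_id=reef_id, date=date, footprint=footprint,
                            polygons=tuple(polygons) if polygons else (), source=source)


def plume_area(d: PlumeDelineation) -> float:
    """Plume areal extent in km²: footprint pixel count × 1/16."""
    return d.area_km2


def auto_delineate(
    ti: np.ndarray,
    reef_mask: np.ndarray,
    cloud: np.ndarray,
    ti_threshold: float | None = None,
    *,
    k: float = 5.0,
    buffer_px: int = 2,
    reef_id: str = "auto",
    date: dt.date | None = None,
) -> PlumeDelineation:
    """Automated plume-delineation surrogate for synthetic testing.

    Candidate pixels have TI above ``ti_threshold`` (default: median TI
    of clear, off-reef water plus ``k``·MAD) and are not cloud-masked;
    only the 8-connected components touching a ``buffer_px`` dilation of
    the reef mask are kept, so detached features are excluded. A fully
    clouded scene yields an empty delineation flagged ``fully_clouded``.
    """
    ti = np.asarray(ti, dtype=float)
    reef_mask = np.asarray(reef_mask, dtype=bool)
    cloud = np.asarray(cloud, dtype=bool)
    if cloud.all():
        return PlumeDelineation(reef_id=reef_id, date=date or dt.date.min,
                                footprint=np.zeros_like(cloud), source="auto",
                                fully_clouded=True)
    if ti_threshold is None:
        clear = ~cloud & ~reef_mask & np.isfinite(ti)
        if not clear.any():
            raise ValueError("no clear off-reef water available to calibrate the TI threshold")
        med = float(np.median(ti[clear]))
        mad = float(np.median(np.abs(ti[clear] - med)))
        ti_threshold = med + k * mad
    with np.errstate(invalid="ignore"):
        candidates = (ti > ti_threshold) & ~cloud
    labels, n = measure.label(candidates, connectivity=2, return_num=True)
    seed = ndimage.binary_dilation(reef_mask, structure=disk_element(buffer_px))
    keep = np.zeros_like(candidates)
    for lab in range(1, n + 1):
        comp = labels == lab
        if np.any(comp & seed):
            keep |= comp
    return PlumeDelineation(reef_id=reef_id, date=date or dt.date.min,
                            footprint=keep, source="auto")


def plume_time_series(
    ds: Sequence[PlumeDelineation],
    examined_without_plume: Sequence[tuple[str, dt.date]] = (),
) -> pd.DataFrame:
    """Table of (reef_id, date, area_km2), one row per delineation.

    Dates that were examined but showed no plume are recorded with area
    0 via ``examined_without_plume``. Duplicate (reef, date) pairs are an
    error.
    """
    rows = [(d.reef_id, d.date, d.area_km2) for d in ds]
    rows += [(reef, date, 0.0) for reef, date in examined_without_plume]
    df = pd.DataFrame(rows, columns=["reef_id", "date", "area_km2"])
    if df.duplicated(subset=["reef_id", "date"]).any():
        dup = df[df.duplicated(subset=["reef_id", "date"], keep=False)]
        raise ValueError(f"duplicate (reef_id, date) entries:\n{dup}")
    return df.sort_values(["reef_id", "date"]).reset_index(drop=True)


def coverage_count(ds: Sequence[PlumeDelineation]) -> np.ndarray:
    """Per-pixel count of delineations containing the pixel."""
    if not ds:
        raise ValueError("no delineations given")
    count = np.zeros(ds[0].footprint.shape, dtype=int)
    for d in ds:
        if d.footprint.shape != count.shape:
            raise ValueError("delineations lie on different grids")
        count += d.footprint
    return count


def plume_frequency_map(ds: Sequence[PlumeDelineation], n_total_images: int) -> np.ndarray:
    """Per-pixel plume frequency as percent of ``n_total_images``."""
    if n_total_images == 0:
        raise ValueError("n_total_images must be positive")
    n_dates = len({d.date for d in ds})
    if n_total_images < n_dates:
        raise ValueError("n_total_images must be at least the number of delineation dates")
    return 100.0 * coverage_count(ds) / n_total_images


def union_area_km2(ds: Sequence[PlumeDelineation]) -> float:
    """Union ("affected at least once") extent of the delineations, km²."""
    return float(np.count_nonzero(coverage_count(ds) > 0)) * PIXEL_AREA_KM2


def single_hit_fraction(ds: Sequence[PlumeDelineation]) -> float:
    """Fraction of ever-affected pixels covered by exactly one delineation."""
    count = coverage_count(ds)
    covered = count > 0
    n_covered = int(covered.sum())
    if n_covered == 0:
        raise ValueError("no pixel is covered by any delineation")
    return float((count == 1).sum()) / n_covered
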