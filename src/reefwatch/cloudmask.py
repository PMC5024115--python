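"""Final cloudmask construction: morphological dilation of the raw
per-scene cloud grid plus manual override polygons."""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import Grid, rasterize_polygon


def disk_element(radius_px: int) -> np.ndarray:
    """Euclidean disk structuring element: offsets with dx²+dy² ≤ r²."""
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return dy * dy + dx * dx <= r * r


def dilate_cloudmask(
    raw: np.ndarray, radius_m: float = 500.0, pixel_m: float = 250.0
) -> np.ndarray:
    """Dilate a raw cloud mask by ``radius_m`` of ground distance.

    Dilation uses a Euclidean disk of radius ceil(radius_m / pixel_m)
    pixels, so the default 500 m at 250-m pixels is a 2-pixel disk. The
    output is always a superset of the input.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be >= 0")
    raw = np.asarray(raw, dtype=bool)
    r = math.ceil(radius_m / pixel_m)
    if r == 0 or not raw.any():
        return raw.copy()
    return ndimage.binary_dilation(raw, structure=disk_element(r))


def threshold_cloud_probability(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean cloud mask from an upstream cloud-probability grid."""
    return np.asarray(prob, dtype=float) >= threshold


@dataclass(frozen=True)
class MaskOverride:
    """Manual cloudmask override: a polygon forced clear or cloudy
    within an optional date range (inclusive; None = open-ended)."""

    polygon: object
    mode: str  # "force_clear" | "force_cloud"
    date_start: dt.date | None = None
    date_end: dt.date | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("force_clear", "force_cloud"):
            raise ValueError(f"unknown override mode {self.mode!r}")

    def applies_on(self, date: dt.date | None) -> bool:
        if date is None:
            return True
        if self.date_start is not None and date < self.date_start:
            return False
        if self.date_end is not None and date > self.date_end:
            return False
        return True


def apply_overrides(
    mask: np.ndarray,
    overrides: Sequence[MaskOverride],
    date: dt.date | None,
    grid: Grid,
) -> np.ndarray:
    """Apply manual overrides to a cloud mask for one date.

    force_clear polygons unset pixels first; force_cloud polygons set
    pixels afterwards, so force_cloud wins where the two contradict (a
    warning is emitted for any contradicted pixel).
    """
    out = np.asarray(mask, dtype=bool).copy()
    active = [ov for ov in overrides if ov.applies_on(date)]
    clear = grid.empty_mask()
    cloud = grid.empty_mask()
    for ov in active:
        footprint = rasterize_polygon(ov.polygon, grid)
        if ov.mode == "force_clear":
            clear |= footprint
        else:
            cloud |= footprint
    conflict = clear & cloud
    if conflict.any():
        warnings.warn(
            f"{int(conflict.sum())} pixel(s) covered by contradictory overrides; "
            "force_cloud takes precedence",
            stacklevel=2,
        )
    out[clear] = False
    out[cloud] = True
    return out
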