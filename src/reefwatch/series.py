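"""Scene containers: single satellite passes and time-ordered stacks."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .grid import Grid

#: band center wavelengths (nm) carried by every scene
BANDS = (469, 555, 645, 859)

#: days per fractional year used for the time coordinate
DAYS_PER_YEAR = 365.25


@dataclass
class SceneObservation:
    """One satellite pass: per-band reflectance grids plus metadata.

    ``bands`` maps wavelength (nm) to a 2-D reflectance array. ``cloud``
    is a boolean grid (True = cloudy) or ``None`` when no cloud product
    accompanies the pass.
    """

    date: dt.date
    bands: dict[int, np.ndarray]
    solar_zenith: float = 0.0
    cloud: np.ndarray | None = None
    grid: Grid | None = None

    def require_bands(self, *wavelengths: int) -> None:
        missing = [w for w in wavelengths if w not in self.bands]
        if missing:
            raise ValueError(f"scene is missing required band(s): {missing}")


@dataclass
class SceneSeries:
    """Time-ordered scene stack on one shared grid.

    Band arrays are stored stacked with shape (T, ny, nx); per-index
    views are exposed through :meth:`observation`.
    """

    grid: Grid
    dates: tuple[dt.date, ...]
    bands: dict[int, np.ndarray]
    cloud: np.ndarray
    solar_zenith: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T = len(self.dates)
        for wl, arr in self.bands.items():
            if arr.shape != (T, *self.grid.shape):
                raise ValueError(f"band {wl} has shape {arr.shape}, expected {(T, *self.grid.shape)}")
        if self.cloud is None:
            self.cloud = np.zeros((T, *self.grid.shape), dtype=bool)
        if self.cloud.shape != (T, *self.grid.shape):
            raise ValueError("cloud stack shape mismatch")
        if self.solar_zenith is None:
            self.solar_zenith = np.zeros(T)
        if list(self.dates) != sorted(self.dates):
            raise ValueError("dates must be time-ordered")

    def __len__(self) -> int:
        return len(self.dates)

    def observation(self, i: int) -> SceneObservation:
        return SceneObservation(
            date=self.dates[i],
            bands={wl: arr[i] for wl, arr in self.bands.items()},
            solar_zenith=float(self.solar_zenith[i]),
            cloud=self.cloud[i],
            grid=self.grid,
        )

    def __iter__(self) -> Iterator[SceneObservation]:
        for i in range(len(self)):
            yield self.observation(i)

    def valid_obs_count(self) -> np.ndarray:
        """Per-pixel count of cloud-free observations."""
        return (~self.cloud).sum(axis=0)

    def years_since_start(self) -> np.ndarray:
        """Fractional years of each date relative to the first date."""
        t0 = self.dates[0]
        return np.array([(d - t0).days for d in self.dates], dtype=float) / DAYS_PER_YEAR
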