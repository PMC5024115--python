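"""Synthetic multi-band scene-series generator with known ground truth.

Builds MODIS-like daily reflectance stacks containing deep water, a
static shallow-reef field, growing island footprints, turbidity plumes,
additive sunglint episodes and random cloud fields. Every injected layer
is recorded in a :class:`SyntheticTruth` so downstream detectors can be
tested by parameter recovery.

Per-pixel compositing order is fixed: baseline → island growth → plume
→ glint → noise → cloud overwrite. Truth records each layer before the
cloud occludes it.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid import Grid, PIXEL_AREA_KM2, area_km2, as_geometry, rasterize_polygon
from .series import BANDS, SceneObservation, SceneSeries

__all__ = [
    "Blob",
    "CloudModel",
    "GlintEvent",
    "IslandEvent",
    "PlumeEvent",
    "SceneConfig",
    "SyntheticTruth",
    "benchmark_config",
    "footprint_for_area",
    "generate_series",
    "rasterize_polygon",
]

# per-class mean reflectance at (469, 555, 645, 859) nm, dimensionless.
# Deep water is dark in the red/NIR; reef adds benthic signal at 555/645;
# island/land is bright with high NIR (so land gives negative TI and a
# strong 859-nm step when built); cloud is bright in all bands.
DEFAULT_SPECTRA: dict[str, tuple[float, float, float, float]] = {
    "deep": (0.030, 0.020, 0.001, 0.002),
    "reef": (0.030, 0.055, 0.040, 0.003),
    "island": (0.10, 0.12, 0.15, 0.25),
    "cloud": (0.60, 0.60, 0.60, 0.60),
}

# additive glint spectral shape: multiplier per band applied to the glint
# magnitude field g, with the 859-nm multiplier fixed at 1. Chosen so the
# standard deglint coefficients (0.67, 0.94) exactly cancel injected glint
# over zero-NIR water.
DEFAULT_GLINT_SHAPE: dict[int, float] = {469: 0.67, 555: 0.80, 645: 0.94, 859: 1.0}


@dataclass(frozen=True)
class Blob:
    """Circular footprint: pixel centers within ``radius_m`` of (lon, lat)."""

    lon: float
    lat: float
    radius_m: float

    def rasterize(self, grid: Grid) -> np.ndarray:
        from .grid import M_PER_DEG

        lon2d, lat2d = grid.center_mesh()
        dx = (lon2d - self.lon) * M_PER_DEG
        dy = (lat2d - self.lat) * M_PER_DEG
        return dx * dx + dy * dy <= self.radius_m * self.radius_m


def _rasterize_footprint(footprint, grid: Grid) -> np.ndarray:
    if isinstance(footprint, np.ndarray):
        if footprint.shape != grid.shape:
            raise ValueError("footprint mask shape does not match grid")
        return footprint.astype(bool)
    if isinstance(footprint, Blob):
        return footprint.rasterize(grid)
    return rasterize_polygon(footprint, grid)


def footprint_for_area(
    grid: Grid, lon: float, lat: float, target_area_km2: float
) -> np.ndarray:
    """Compact pixel footprint of ``round(target_area_km2 * 16)`` pixels.

    Pixels are taken nearest-first from (lon, lat), so the returned mask
    is the closest 1/16-km²-quantized approximation of the target area.
    """
    n = int(round(target_area_km2 / PIXEL_AREA_KM2))
    if n == 0:
        return grid.empty_mask()
    lon2d, lat2d = grid.center_mesh()
    d2 = (lon2d - lon) ** 2 + (lat2d - lat) ** 2
    order = np.argsort(d2, axis=None, kind="stable")[:n]
    mask = grid.empty_mask()
    mask.ravel()[order] = True
    return mask


def linear_growth(tau: float) -> float:
    return tau


_NAMED_CURVES: dict[str, Callable[[float], float]] = {
    "linear": linear_growth,
    "sqrt": math.sqrt,
}


@dataclass(frozen=True)
class IslandEvent:
    """One island-building project: footprint filled in over time.

    ``growth_curve`` maps normalized time in [0, 1] to the fraction of
    the final footprint built; it must be non-decreasing with curve(0)=0
    and curve(1)=1. Strings name built-in curves ("linear", "sqrt").
    """

    reef_id: str
    footprint: object  # polygon-like, Blob, or boolean mask
    start_date: dt.date
    end_date: dt.date
    growth_curve: Callable[[float], float] | str | None = None

    def curve(self) -> Callable[[float], float]:
        c = self.growth_curve
        if c is None:
            return linear_growth
        if isinstance(c, str):
            try:
                return _NAMED_CURVES[c]
            except KeyError:
                raise ValueError(f"unknown growth curve {c!r}") from None
        return c

    def growth_fraction(self, date: dt.date) -> float:
        """Fraction of final footprint built at ``date`` (0 before start, 1 at/after end)."""
        if date < self.start_date:
            return 0.0
        if date >= self.end_date:
            return 1.0
        span = (self.end_date - self.start_date).days
        tau = (date - self.start_date).days / span
        return float(min(1.0, max(0.0, self.curve()(tau))))

    def validate(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError(f"island {self.reef_id!r}: end_date must follow start_date")
        c = self.curve()
        samples = [c(t) for t in np.linspace(0.0, 1.0, 51)]
        if any(b < a - 1e-12 for a, b in zip(samples, samples[1:])):
            raise ValueError(f"island {self.reef_id!r}: growth curve must be non-decreasing")


@dataclass(frozen=True)
class PlumeEvent:
    """A turbidity plume on one date: raises band 469 (and, weakly, 555)
    over the footprint so the injected TI strictly exceeds clear water."""

    reef_id: str
    date: dt.date
    footprint: object
    ti_amplitude: float = 0.05

    def validate(self) -> None:
        if self.ti_amplitude <= 0:
            raise ValueError(f"plume at {self.reef_id!r}: ti_amplitude must be positive")


@dataclass(frozen=True)
class GlintEvent:
    """Additive sunglint on one date: observed band = clean band + shape(λ)·g."""

    date: dt.date
    magnitude: float
    pattern: str = "ramp"  # "ramp": west→east linear ramp; "ramp_r": reversed; "uniform": constant
    spectral_shape: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_GLINT_SHAPE))

    def validate(self) -> None:
        if self.magnitude < 0:
            raise ValueError("glint magnitude must be >= 0")
        if self.pattern not in ("ramp", "ramp_r", "uniform"):
            raise ValueError(f"unknown glint pattern {self.pattern!r}")
        if self.spectral_shape.get(859) != 1.0:
            raise ValueError("glint spectral_shape must fix the 859-nm multiplier to 1")

    def field_on(self, grid: Grid) -> np.ndarray:
        if self.pattern == "uniform":
            return np.full(grid.shape, self.magnitude)
        ramp = np.linspace(0.0, 1.0, grid.nx)
        if self.pattern == "ramp_r":
            ramp = ramp[::-1]
        return np.broadcast_to(self.magnitude * ramp, grid.shape).copy()


@dataclass(frozen=True)
class CloudModel:
    """Random smoothed-noise cloud blobs thresholded to a coverage fraction."""

    coverage: float = 0.3
    coverage_sd: float = 0.1
    correlation_px: float = 3.0

    def validate(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("cloud coverage must be in [0, 1]")

    def sample(self, grid: Grid, rng: np.random.Generator) -> np.ndarray:
        frac = float(np.clip(rng.normal(self.coverage, self.coverage_sd), 0.0, 0.95))
        noise = rng.standard_normal(grid.shape)
        if frac <= 0.0:
            return grid.empty_mask()
        smooth = ndimage.gaussian_filter(noise, self.correlation_px)
        thr = np.quantile(smooth, 1.0 - frac)
        return smooth >= thr


@dataclass(frozen=True)
class SceneConfig:
    """Full recipe for a synthetic scene series.

    Identical config (including ``seed``) reproduces the series
    bit-for-bit.
    """

    grid: Grid
    start_date: dt.date
    end_date: dt.date
    revisit_days: int = 1
    seed: int = 0
    spectra: Mapping[str, Sequence[float]] = field(default_factory=lambda: dict(DEFAULT_SPECTRA))
    noise_sd: float = 0.002
    reef_polygons: Mapping[str, object] = field(default_factory=dict)
    islands: tuple[IslandEvent, ...] = ()
    plumes: tuple[PlumeEvent, ...] = ()
    glints: tuple[GlintEvent, ...] = ()
    clouds: CloudModel | None = None

    def dates(self) -> list[dt.date]:
        out = []
        d = self.start_date
        step = dt.timedelta(days=self.revisit_days)
        while d <= self.end_date:
            out.append(d)
            d += step
        return out

    def validate(self) -> None:
        if self.revisit_days <= 0:
            raise ValueError("revisit_days must be positive")
        if self.end_date < self.start_date:
            raise ValueError("date_range is empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, means in self.spectra.items():
            arr = np.asarray(means, dtype=float)
            if arr.shape != (len(BANDS),):
                raise ValueError(f"spectrum for class {cls!r} must have {len(BANDS)} entries")
            if np.any(arr < 0) or np.any(arr > 1.5):
                raise ValueError(f"spectrum for class {cls!r} must lie in [0, 1.5]")
        for ev in self.islands:
            ev.validate()
            if not (self.start_date <= ev.start_date and ev.end_date <= self.end_date):
                raise ValueError(f"island {ev.reef_id!r} dates fall outside the series date_range")
        for ev in self.plumes:
            ev.validate()
            if not (self.start_date <= ev.date <= self.end_date):
                raise ValueError(f"plume at {ev.reef_id!r} dated outside the series date_range")
        for ev in self.glints:
            ev.validate()
            if not (self.start_date <= ev.date <= self.end_date):
                raise ValueError("glint event dated outside the series date_range")
        if self.clouds is not None:
            self.clouds.validate()


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation, pre-cloud-occlusion.

    All stacks share the series grid and date axis.
    """

    grid: Grid
    dates: tuple[dt.date, ...]
    island: np.ndarray  # (T, ny, nx) bool
    plume: np.ndarray  # (T, ny, nx) bool
    cloud: np.ndarray  # (T, ny, nx) bool
    glint: np.ndarray  # (T, ny, nx) float32
    reef_mask: np.ndarray  # (ny, nx) bool

    def island_area_km2(self, i: int) -> float:
        return area_km2(self.island[i])

    def plume_area_km2(self, i: int) -> float:
        return area_km2(self.plume[i])

    def final_island_mask(self) -> np.ndarray:
        return self.island[-1] if len(self.dates) else self.grid.empty_mask()

    def deep_water_mask(self, exclusion_px: int = 1) -> np.ndarray:
        """Pixels that were never reef, never island, and not within
        ``exclusion_px`` pixels of any final island footprint."""
        final = self.island.any(axis=0) if len(self.dates) else self.grid.empty_mask()
        if exclusion_px > 0:
            final = ndimage.binary_dilation(final, iterations=exclusion_px)
        return ~(self.reef_mask | final)


def _solar_zenith(date: dt.date) -> float:
    """Deterministic seasonal solar zenith proxy (degrees, low-latitude)."""
    doy = date.timetuple().tm_yday
    return 15.0 + 20.0 * abs(math.sin(2.0 * math.pi * doy / 365.25))


def generate_series(config: SceneConfig) -> tuple[SceneSeries, SyntheticTruth]:
    """Generate a scene series and its ground truth from ``config``.

    Raises ``ValueError`` for invalid configs, including overlapping
    island footprints across distinct reef_ids and event dates outside
    the configured date range.
    """
    config.validate()
    grid = config.grid
    dates = config.dates()
    T = len(dates)
    ny, nx = grid.shape

    spectra = {cls: np.asarray(v, dtype=np.float32) for cls, v in config.spectra.items()}
    for required in ("deep", "reef", "island", "cloud"):
        if required not in spectra:
            raise ValueError(f"spectra must define class {required!r}")

    reef_mask = grid.empty_mask()
    for poly in config.reef_polygons.values():
        reef_mask |= _rasterize_footprint(poly, grid)

    # rasterize island footprints once; fail on cross-reef overlap
    island_masks: dict[str, np.ndarray] = {}
    for ev in config.islands:
        m = _rasterize_footprint(ev.footprint, grid)
        for other_id, other in island_masks.items():
            if other_id != ev.reef_id and np.any(m & other):
                raise ValueError(
                    f"island footprints for {ev.reef_id!r} and {other_id!r} overlap"
                )
        island_masks[ev.reef_id] = island_masks.get(ev.reef_id, grid.empty_mask()) | m

    # deterministic pixel fill order per island: nearest-to-centroid first
    island_orders: list[tuple[IslandEvent, np.ndarray]] = []
    for ev in config.islands:
        m = _rasterize_footprint(ev.footprint, grid)
        idx = np.flatnonzero(m)
        rows, cols = np.unravel_index(idx, grid.shape)
        cy, cx = rows.mean(), cols.mean()
        order = np.argsort((rows - cy) ** 2 + (cols - cx) ** 2, kind="stable")
        island_orders.append((ev, idx[order]))

    plume_by_date: dict[dt.date, list[PlumeEvent]] = {}
    for ev in config.plumes:
        plume_by_date.setdefault(ev.date, []).append(ev)
    glint_by_date: dict[dt.date, list[GlintEvent]] = {}
    for ev in config.glints:
        glint_by_date.setdefault(ev.date, []).append(ev)

    base = np.empty((ny, nx, len(BANDS)), dtype=np.float32)
    base[:] = spectra["deep"]
    base[reef_mask] = spectra["reef"]

    rng = np.random.default_rng(config.seed)

    bands = {wl: np.empty((T, ny, nx), dtype=np.float32) for wl in BANDS}
    cloud_stack = np.zeros((T, ny, nx), dtype=bool)
    truth_island = np.zeros((T, ny, nx), dtype=bool)
    truth_plume = np.zeros((T, ny, nx), dtype=bool)
    truth_glint = np.zeros((T, ny, nx), dtype=np.float32)
    zeniths = np.empty(T)

    for i, date in enumerate(dates):
        frame = base.copy()

        isl = grid.empty_mask()
        for ev, order in island_orders:
            f = ev.growth_fraction(date)
            k = int(math.ceil(f * order.size - 1e-9))
            if k > 0:
                isl.ravel()[order[:k]] = True
        frame[isl] = spectra["island"]
        truth_island[i] = isl

        plm = grid.empty_mask()
        for ev in plume_by_date.get(date, ()):
            m = _rasterize_footprint(ev.footprint, grid) & ~isl
            frame[m, 0] += ev.ti_amplitude
            frame[m, 1] += 0.6 * ev.ti_amplitude
            plm |= m
        truth_plume[i] = plm

        g_total = np.zeros((ny, nx), dtype=np.float32)
        for ev in glint_by_date.get(date, ()):
            g = ev.field_on(grid).astype(np.float32)
            for b, wl in enumerate(BANDS):
                frame[:, :, b] += np.float32(ev.spectral_shape.get(wl, 1.0)) * g
            g_total += g
        truth_glint[i] = g_total

        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, frame.shape).astype(np.float32)

        if config.clouds is not None:
            cld = config.clouds.sample(grid, rng)
            frame[cld] = spectra["cloud"]
            cloud_stack[i] = cld

        for b, wl in enumerate(BANDS):
            bands[wl][i] = frame[:, :, b]
        zeniths[i] = _solar_zenith(date)

    series = SceneSeries(
        grid=grid,
        dates=tuple(dates),
        bands=bands,
        cloud=cloud_stack,
        solar_zenith=zeniths,
    )
    truth = SyntheticTruth(
        grid=grid,
        dates=tuple(dates),
        island=truth_island,
        plume=truth_plume,
        cloud=cloud_stack.copy(),
        glint=truth_glint,
        reef_mask=reef_mask,
    )
    return series, truth


def benchmark_config(seed: int = 0) -> SceneConfig:
    """Default parameter-recovery benchmark.

    A 3-year daily series (2013-01-01 … 2015-12-31) with ~30% cloud
    cover, periodic sunglint episodes, turbidity plumes during
    construction, and island building only at designated reefs: one
    large (~6.4 km²) project, one mid-sized (~0.5 km²) and one
    single-pixel (~0.06 km²) project. A fourth reef stays untouched.
    """
    grid = Grid(lat_min=9.80, lat_max=10.00, lon_min=115.40, lon_max=115.70)
    start, end = dt.date(2013, 1, 1), dt.date(2015, 12, 31)

    reefs = {
        "alpha": Blob(115.47, 9.95, 4500.0),
        "beta": Blob(115.63, 9.95, 3000.0),
        "gamma": Blob(115.47, 9.85, 2500.0),
        "delta": Blob(115.63, 9.85, 3000.0),  # control reef, no construction
    }
    islands = (
        IslandEvent(
            "alpha",
            footprint_for_area(grid, 115.47, 9.95, 6.39),
            dt.date(2015, 1, 1),
            dt.date(2015, 10, 1),
        ),
        IslandEvent(
            "beta",
            footprint_for_area(grid, 115.63, 9.95, 0.50),
            dt.date(2014, 3, 1),
            dt.date(2014, 9, 1),
        ),
        IslandEvent(
            "gamma",
            footprint_for_area(grid, 115.47, 9.85, 0.0625),
            dt.date(2014, 6, 1),
            dt.date(2014, 8, 1),
        ),
    )

    plumes = []
    d = dt.date(2015, 1, 2)
    j = 0
    while d < dt.date(2015, 10, 1):
        radius = 2500.0 + 1500.0 * (j % 4)
        offset = 0.02 + 0.01 * (j % 3)
        plumes.append(
            PlumeEvent("alpha", d, Blob(115.47 + offset, 9.95 - offset, radius), ti_amplitude=0.06)
        )
        d += dt.timedelta(days=3)
        j += 1

    glints = []
    d = start
    j = 0
    while d <= end:
        glints.append(
            GlintEvent(
                d,
                magnitude=0.02 + 0.015 * (j % 4),
                pattern="ramp" if j % 2 == 0 else "ramp_r",
            )
        )
        d += dt.timedelta(days=9)
        j += 1

    return SceneConfig(
        grid=grid,
        start_date=start,
        end_date=end,
        seed=seed,
        reef_polygons=reefs,
        islands=islands,
        plumes=tuple(plumes),
        glints=tuple(glints),
        clouds=CloudModel(coverage=0.3, coverage_sd=0.1, correlation_px=3.0),
    )
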