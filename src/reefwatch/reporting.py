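"""Island-building accounting and campaign summaries.

Ships a verbatim survey table of observed island-building projects
(reef, country code, coordinates, reef/island/new areas, start/end
dates) plus the published per-country totals and per-reef plume
extents, and provides record loading, per-country aggregation and a
per-reef campaign report bundle.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import Grid
from .plume import PlumeDelineation, plume_time_series, union_area_km2

VALID_COUNTRIES = frozenset({"C", "V", "T"})

#: date sentinels used in the survey table
PRE_OLI = "Pre-OLI"
ONGOING = "Ongoing"


@dataclass(frozen=True)
class Censored:
    """An interval-censored area entry, e.g. "<0.01" → Censored(0, 0.01).

    Censored values are excluded from exact sums; callers may configure
    a point value explicitly if they need one.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo < self.hi:
            raise ValueError("censored interval must satisfy 0 <= lo < hi")


@dataclass(frozen=True)
class IslandRecord:
    """One survey row: an island-building project on one reef.

    ``new_area_km2`` equals ``island_area_km2`` for wholly new islands
    and is smaller for additions to pre-existing islands; "<x" entries
    are carried as :class:`Censored` intervals. Start/end are dates
    (month resolution) or the sentinels ``PRE_OLI`` / ``ONGOING``.
    Island area is *not* checked against reef area (reef outlines for
    some atolls are unreliable); only 0 ≤ new ≤ island is asserted.
    """

    reef_name: str
    country: str
    lat: float
    lon: float
    reef_area_km2: float
    island_area_km2: float
    new_area_km2: float | Censored
    start: dt.date | str
    end: dt.date | str

    def __post_init__(self) -> None:
        if self.country not in VALID_COUNTRIES:
            raise ValueError(f"unknown country code {self.country!r} for {self.reef_name!r}")
        hi = self.new_area_km2.hi if isinstance(self.new_area_km2, Censored) else self.new_area_km2
        lo = self.new_area_km2.lo if isinstance(self.new_area_km2, Censored) else self.new_area_km2
        if lo < 0 or hi > self.island_area_km2 + 1e-9:
            raise ValueError(
                f"{self.reef_name!r}: new area must satisfy 0 <= new <= island area"
            )
        for name, value in (("start", self.start), ("end", self.end)):
            if isinstance(value, str) and value not in (PRE_OLI, ONGOING):
                raise ValueError(f"{self.reef_name!r}: bad {name} sentinel {value!r}")

    def in_grid(self, grid: Grid) -> bool:
        return (grid.lat_min <= self.lat <= grid.lat_max
                and grid.lon_min <= self.lon <= grid.lon_max)


def _parse_month(text: str, row: int, fieldname: str) -> dt.date | str:
    text = text.strip()
    if text in (PRE_OLI, ONGOING):
        return text
    for fmt in ("%b %Y", "%B %Y"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"row {row}: cannot parse {fieldname} value {text!r} as month-year")


def _parse_area(text: str, row: int, fieldname: str) -> float | Censored:
    text = text.strip()
    if text.startswith("<"):
        try:
            hi = float(text[1:])
        except ValueError:
            raise ValueError(f"row {row}: bad censored {fieldname} value {text!r}") from None
        return Censored(0.0, hi)
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"row {row}: bad {fieldname} value {text!r}") from None


REQUIRED_COLUMNS = ("reef_name", "country", "lat", "lon", "reef_area_km2",
                    "island_area_km2", "new_area_km2", "start", "end")


def load_island_records(path=None) -> list[IslandRecord]:
    """Load island-building records from a CSV (default: packaged table).

    Malformed rows raise ``ValueError`` naming the row and field.
    """
    if path is None:
        source = resources.files("reefwatch.data").joinpath("table1.csv")
        fh = source.open("r", encoding="utf-8")
    else:
        fh = open(path, "r", encoding="utf-8")
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"CSV is missing required column(s): {missing}")
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                lat, lon = float(row["lat"]), float(row["lon"])
                reef_area = float(row["reef_area_km2"])
                island_area = float(row["island_area_km2"])
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from None
            records.append(
                IslandRecord(
                    reef_name=row["reef_name"].strip(),
                    country=row["country"].strip(),
                    lat=lat,
                    lon=lon,
                    reef_area_km2=reef_area,
                    island_area_km2=island_area,
                    new_area_km2=_parse_area(row["new_area_km2"], i, "new_area_km2"),
                    start=_parse_month(row["start"], i, "start"),
                    end=_parse_month(row["end"], i, "end"),
                )
            )
    return records


def country_totals(records: Sequence[IslandRecord]) -> pd.DataFrame:
    """Per-country sums of exact new-island areas.

    Returns columns ``country``, ``total_new_area_km2`` (unrounded),
    ``total_display`` (rounded to 2 decimals) and ``n_censored`` (rows
    whose new area is interval-censored and excluded from the sum).
    """
    totals: dict[str, float] = {}
    censored: dict[str, int] = {}
    for r in records:
        if r.country not in VALID_COUNTRIES:
            raise ValueError(f"unknown country code {r.country!r}")
        if isinstance(r.new_area_km2, Censored):
            censored[r.country] = censored.get(r.country, 0) + 1
            totals.setdefault(r.country, 0.0)
        else:
            totals[r.country] = totals.get(r.country, 0.0) + r.new_area_km2
            censored.setdefault(r.country, 0)
    rows = [
        {"country": c, "total_new_area_km2": totals[c],
         "total_display": round(totals[c], 2), "n_censored": censored[c]}
        for c in sorted(totals)
    ]
    return pd.DataFrame(rows, columns=["country", "total_new_area_km2",
                                       "total_display", "n_censored"])


def printed_country_totals() -> dict[str, float]:
    """Published per-country new-island-area totals (km²) from the
    packaged survey-table notes."""
    source = resources.files("reefwatch.data").joinpath("table1_country_totals.csv")
    with source.open("r", encoding="utf-8") as fh:
        return {row["country"]: float(row["total_new_area_km2"]) for row in csv.DictReader(fh)}


def plume_extent_summary() -> pd.DataFrame:
    """Published per-reef delineated-plume campaign summary: images
    examined, images with plumes, and union spatial extent (km²)."""
    source = resources.files("reefwatch.data").joinpath("plume_extents.csv")
    with source.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    return df


@dataclass
class ReefReport:
    reef_id: str
    record: IslandRecord | None
    island_trajectory: pd.DataFrame  # columns: date, area_km2
    plume_series: pd.DataFrame  # columns: reef_id, date, area_km2
    plume_union_km2: float
    frequency_map: np.ndarray | None
    outside_grid: bool = False

    @property
    def final_island_area_km2(self) -> float:
        if self.island_trajectory.empty:
            return 0.0
        return float(self.island_trajectory["area_km2"].iloc[-1])


@dataclass
class CampaignReport:
    reefs: dict[str, ReefReport]
    totals: pd.DataFrame

    def render_markdown(self) -> str:
        lines = ["# Campaign report", ""]
        for reef_id, rep in sorted(self.reefs.items()):
            lines.append(f"## {reef_id}")
            if rep.outside_grid:
                lines.append("*Record location lies outside the configured grid.*")
            lines.append(f"- final island area: {rep.final_island_area_km2:.4f} km²")
            lines.append(f"- plume observations: {len(rep.plume_series)}")
            lines.append(f"- plume union extent: {rep.plume_union_km2:.4f} km²")
            lines.append("")
        lines.append("## Totals")
        lines.append(self.totals.to_string(index=False))
        lines.append("")
        return "\n".join(lines)


def campaign_report(
    island_areas: Mapping[str, Sequence[tuple[dt.date, float]]],
    records: Sequence[IslandRecord] = (),
    plumes: Sequence[PlumeDelineation] = (),
    grid: Grid | None = None,
    n_total_images: Mapping[str, int] | None = None,
) -> CampaignReport:
    """Per-reef campaign bundle: island trajectory, plume series,
    frequency map and combined totals.

    ``island_areas`` maps reef id to a dated area trajectory (truth or
    detected). Plume delineations whose reef id is unknown raise an
    error. Records located outside ``grid`` (when given) are flagged,
    not dropped.
    """
    from .plume import plume_frequency_map

    known = set(island_areas)
    record_by_reef = {}
    for r in records:
        record_by_reef[r.reef_name] = r
        known.add(r.reef_name)
    for d in plumes:
        if d.reef_id not in known:
            raise ValueError(f"plume delineation references unknown reef id {d.reef_id!r}")

    reports: dict[str, ReefReport] = {}
    for reef_id in sorted(known):
        traj = pd.DataFrame(
            sorted(island_areas.get(reef_id, ()), key=lambda p: p[0]),
            columns=["date", "area_km2"],
        )
        reef_plumes = [d for d in plumes if d.reef_id == reef_id]
        if reef_plumes:
            ts = plume_time_series(reef_plumes)
            union = union_area_km2(reef_plumes)
            freq = None
            if n_total_images and reef_id in n_total_images:
                freq = plume_frequency_map(reef_plumes, n_total_images[reef_id])
        else:
            ts = pd.DataFrame(columns=["reef_id", "date", "area_km2"])
            union, freq = 0.0, None
        rec = record_by_reef.get(reef_id)
        reports[reef_id] = ReefReport(
            reef_id=reef_id,
            record=rec,
            island_trajectory=traj,
            plume_series=ts,
            plume_union_km2=union,
            frequency_map=freq,
            outside_grid=bool(rec is not None and grid is not None and not rec.in_grid(grid)),
        )

    totals = pd.DataFrame(
        [
            {
                "reef_id": reef_id,
                "final_island_area_km2": rep.final_island_area_km2,
                "plume_union_km2": rep.plume_union_km2,
            }
            for reef_id, rep in sorted(reports.items())
        ],
        columns=["reef_id", "final_island_area_km2", "plume_union_km2"],
    )
    return CampaignReport(reefs=reports, totals=totals)
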