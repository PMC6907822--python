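"""Data model and raster I/O for interleaved dual-sensor NDVI time series.

A 16-day-composite vegetation-index product delivers 23 nodes per sensor per
year.  Two sensors whose composite periods are offset by 8 days ("half
synthetic period dislocation") interleave into a 46-node annual series with a
uniform 8-day cadence.  Values are integer NDVI scaled by 10,000; each value
node carries a pixel-reliability code (0 good, 1 marginal, 2 snow/ice,
3 cloud, 255 fill).

On disk a stack is three files sharing a prefix: ``<prefix>.tif`` (values,
multiband int16), ``<prefix>.rel.tif`` (reliability, multiband uint8) and
``<prefix>.json`` (calendar + geotransform sidecar).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("cropseries")

#: scale factor between true NDVI and stored integers
NDVI_SCALE = 10_000

#: pixel-reliability codes
RELIABILITY_GOOD = 0
RELIABILITY_MARGINAL = 1
RELIABILITY_SNOW = 2
RELIABILITY_CLOUD = 3
RELIABILITY_FILL = 255

#: codes usable as interpolation anchors / retained untouched
GOOD_CODES = (RELIABILITY_GOOD, RELIABILITY_MARGINAL)
#: codes whose values are replaced during gap-filling
FLAGGED_CODES = (RELIABILITY_SNOW, RELIABILITY_CLOUD, RELIABILITY_FILL)

#: nominal composite start day-of-year grids for the two sensors
SENSOR_A_DOYS = tuple(range(1, 366, 16))   # 1, 17, ..., 353  (23 nodes)
SENSOR_B_DOYS = tuple(range(9, 366, 16))   # 9, 25, ..., 361  (23 nodes)


class CalendarError(ValueError):
    """Raised for inconsistent node calendars."""


class StackIOError(ValueError):
    """Raised for malformed raster stacks on disk."""


@dataclass(frozen=True)
class NodeCalendar:
    """Ordered list of (year, doy, sensor) composite nodes.

    ``sensor`` is ``"A"`` (start DOYs 1 + 16k) or ``"B"`` (9 + 16k).  A
    dual-sensor calendar has 46 nodes per year at an 8-day cadence; a
    single-sensor calendar has 23 at 16 days.
    """

    entries: tuple[tuple[int, int, str], ...]
    nodes_per_year: int

    def __post_init__(self) -> None:
        if not self.entries:
            raise CalendarError("calendar has no entries")
        keys = [(y, d) for y, d, _ in self.entries]
        if keys != sorted(keys) or len(set(keys)) != len(keys):
            raise CalendarError("calendar not strictly sorted by (year, doy)")
        for y, d, s in self.entries:
            grid = SENSOR_A_DOYS if s == "A" else SENSOR_B_DOYS
            if s not in ("A", "B"):
                raise CalendarError(f"unknown sensor {s!r}")
            if d not in grid:
                raise CalendarError(f"DOY {d} not on sensor-{s} grid")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _, _ in self.entries}))

    def year_indices(self, year: int) -> np.ndarray:
        """Node positions belonging to ``year``, in calendar order."""
        idx = np.array([i for i, (y, _, _) in enumerate(self.entries) if y == year])
        if idx.size == 0:
            raise CalendarError(f"year {year} not in calendar")
        return idx

    def doys(self) -> np.ndarray:
        return np.array([d for _, d, _ in self.entries])

    def to_dict(self) -> dict:
        return {
            "entries": [list(e) for e in self.entries],
            "nodes_per_year": self.nodes_per_year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NodeCalendar":
        return cls(
            entries=tuple((int(y), int(doy), str(s)) for y, doy, s in d["entries"]),
            nodes_per_year=int(d["nodes_per_year"]),
        )


def build_calendar(start_year: int, end_year: int, dual: bool = True) -> NodeCalendar:
    """Build the nominal composite-node calendar for a span of years.

    Dual-sensor calendars interleave sensor A (DOY 1 + 16k) and sensor B
    (DOY 9 + 16k) into 46 nodes per year sorted by (year, doy); single-sensor
    calendars carry sensor A's 23 nodes.  2004-2016 dual gives 598 nodes.
    """
    if end_year < start_year:
        raise CalendarError(f"end_year {end_year} < start_year {start_year}")
    entries: list[tuple[int, int, str]] = []
    for year in range(start_year, end_year + 1):
        nodes = [(year, d, "A") for d in SENSOR_A_DOYS]
        if dual:
            nodes += [(year, d, "B") for d in SENSOR_B_DOYS]
        entries.extend(sorted(nodes))
    return NodeCalendar(entries=tuple(entries), nodes_per_year=46 if dual else 23)


@dataclass
class TimeSeriesStack:
    """Raster cube of scaled NDVI with a paired reliability cube.

    ``values``: int16 array (n_nodes, n_rows, n_cols), NDVI x 10,000.
    ``reliability``: uint8 array, same shape, pixel-reliability codes.
    ``geotransform``: 6-tuple (x0, dx, 0, y0, 0, dy) mapping (col, row) to
    map coordinates, GDAL convention.
    """

    values: np.ndarray
    reliability: np.ndarray
    calendar: NodeCalendar
    geotransform: tuple[float, float, float, float, float, float] = (
        0.0, 250.0, 0.0, 0.0, 0.0, -250.0)
    pixel_size_m: float = 250.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.reliability = np.asarray(self.reliability)
        if self.values.ndim != 3:
            raise StackIOError("values must be 3-D (nodes, rows, cols)")
        if self.values.shape != self.reliability.shape:
            raise StackIOError("values and reliability shapes differ")
        if self.values.shape[0] != len(self.calendar):
            raise StackIOError(
                f"{self.values.shape[0]} bands but calendar has "
                f"{len(self.calendar)} nodes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def pixel_coords(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a pixel centre."""
        x0, dx, _, y0, _, dy = self.geotransform
        return x0 + (col + 0.5) * dx, y0 + (row + 0.5) * dy

    def copy(self) -> "TimeSeriesStack":
        return TimeSeriesStack(
            values=self.values.copy(),
            reliability=self.reliability.copy(),
            calendar=self.calendar,
            geotransform=self.geotransform,
            pixel_size_m=self.pixel_size_m,
        )


def interleave_stacks(stack_a: TimeSeriesStack,
                      stack_b: TimeSeriesStack) -> TimeSeriesStack:
    """Merge two single-sensor stacks into one series sorted by (year, doy).

    The two calendars must cover the same years on the A and B DOY grids over
    an identical pixel grid; values and reliability pass through unchanged
    into the merged node order.
    """
    if stack_a.values.shape[1:] != stack_b.values.shape[1:]:
        raise StackIOError("pixel grids differ between sensors")
    if stack_a.geotransform != stack_b.geotransform:
        raise StackIOError("geotransforms differ between sensors")
    if stack_a.calendar.years != stack_b.calendar.years:
        raise StackIOError("year ranges differ between sensors")
    merged = (
        [(y, d, s, "a", i) for i, (y, d, s) in enumerate(stack_a.calendar.entries)]
        + [(y, d, s, "b", i) for i, (y, d, s) in enumerate(stack_b.calendar.entries)]
    )
    keys = [(y, d) for y, d, _, _, _ in merged]
    if len(set(keys)) != len(keys):
        raise StackIOError("overlapping (year, DOY) nodes between sensors")
    merged.sort(key=lambda e: (e[0], e[1]))

    n = len(merged)
    rows, cols = stack_a.values.shape[1:]
    values = np.empty((n, rows, cols), dtype=stack_a.values.dtype)
    reliability = np.empty((n, rows, cols), dtype=stack_a.reliability.dtype)
    entries = []
    for out_i, (y, d, s, which, src_i) in enumerate(merged):
        src = stack_a if which == "a" else stack_b
        values[out_i] = src.values[src_i]
        reliability[out_i] = src.reliability[src_i]
        entries.append((y, d, s))
    calendar = NodeCalendar(entries=tuple(entries),
                            nodes_per_year=stack_a.calendar.nodes_per_year
                            + stack_b.calendar.nodes_per_year)
    return TimeSeriesStack(values=values, reliability=reliability,
                           calendar=calendar,
                           geotransform=stack_a.geotransform,
                           pixel_size_m=stack_a.pixel_size_m)


# ---------------------------------------------------------------------------
# disk round trip

def write_stack(stack: TimeSeriesStack, prefix: str | Path) -> list[Path]:
    """Write a stack as <prefix>.tif / <prefix>.rel.tif / <prefix>.json."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    val_path = prefix.with_suffix(".tif")
    rel_path = prefix.parent / (prefix.name + ".rel.tif")
    meta_path = prefix.with_suffix(".json")
    tifffile.imwrite(val_path, stack.values.astype(np.int16),
                     photometric="minisblack")
    tifffile.imwrite(rel_path, stack.reliability.astype(np.uint8),
                     photometric="minisblack")
    meta = {
        "calendar": stack.calendar.to_dict(),
        "geotransform": list(stack.geotransform),
        "pixel_size_m": stack.pixel_size_m,
    }
    meta_path.write_text(json.dumps(meta))
    return [val_path, rel_path, meta_path]


def read_stack(prefix: str | Path) -> TimeSeriesStack:
    """Read a stack written by :func:`write_stack`; validates band counts."""
    prefix = Path(prefix)
    val_path = prefix.with_suffix(".tif")
    rel_path = prefix.parent / (prefix.name + ".rel.tif")
    meta_path = prefix.with_suffix(".json")
    for p, what in ((val_path, "value raster"),
                    (rel_path, "reliability raster"),
                    (meta_path, "calendar sidecar")):
        if not p.exists():
            raise StackIOError(f"missing {what}: {p}")
    meta = json.loads(meta_path.read_text())
    calendar = NodeCalendar.from_dict(meta["calendar"])
    def _as_cube(a: np.ndarray) -> np.ndarray:
        # single-band TIFFs read back 2-D
        return a[None] if a.ndim == 2 else a

    values = _as_cube(tifffile.imread(val_path))
    reliability = _as_cube(tifffile.imread(rel_path))
    if values.shape[0] != len(calendar):
        raise StackIOError(
            f"band count {values.shape[0]} != calendar length {len(calendar)}")
    return TimeSeriesStack(
        values=values,
        reliability=reliability,
        calendar=calendar,
        geotransform=tuple(meta["geotransform"]),
        pixel_size_m=float(meta["pixel_size_m"]),
    )


# ---------------------------------------------------------------------------
# statistical area tables

def read_area_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV of statistical sown areas (unit_name, year, area_mha)."""
    df = pd.read_csv(path)
    required = {"unit_name", "year", "area_mha"}
    if not required.issubset(df.columns):
        raise StackIOError(f"area table must have columns {sorted(required)}")
    if df.duplicated(["unit_name", "year"]).any():
        raise StackIOError("duplicate (unit_name, year) rows in area table")
    if (df["area_mha"] < 0).any():
        raise StackIOError("negative area in area table")
    return df


def write_area_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
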