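"""Multi-year products: area series, change maps, planting frequency, peaks.

From a per-year stack of categorical maps this module derives the
interannual area series of a target class with year-on-year growth rates,
epoch change maps (gain / loss / stable / absent), the planting-frequency
(probability) raster — the percentage of study years each pixel carried the
target class — and per-year peak NDVI metrics inside a phenological window.

Areas are in Mha; one 250 m pixel is 6.25 ha, so 160,000 pixels make 1 Mha.
"Average growth rate" over a span is the arithmetic mean of the annual
percentage changes in that span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CLASS_CODES, ClassMap

#: change-map codes
CHANGE_CODES = {"absent": 0, "stable": 1, "gain": 2, "loss": 3}

#: default phenological peak windows (DOY) for the two crops of the rotation
WHEAT_WINDOW = (60, 170)
MAIZE_WINDOW = (180, 270)

#: default planting-frequency histogram bin edges (percent, ascending)
FREQUENCY_BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass
class FrequencyRaster:
    """Per-pixel planting frequency in percent of study years."""

    values: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < 0) | (self.values > 100)).any():
            raise ValueError("frequencies must lie in [0, 100]")


def _target_code(class_map: ClassMap, target_class: str | int) -> int:
    code = CLASS_CODES.get(target_class, target_class) \
        if isinstance(target_class, str) else target_class
    if code not in class_map.legend:
        raise ValueError(f"class {target_class!r} not in legend")
    return int(code)


def class_area(class_map: ClassMap, target_class: str | int,
               pixel_size_m: float | None = None) -> float:
    """Mapped area of a class in Mha: n_pixels x pixel_area / 1e10 m^2."""
    px = class_map.pixel_size_m if pixel_size_m is None else pixel_size_m
    if px <= 0:
        raise ValueError("pixel_size_m must be > 0")
    code = _target_code(class_map, target_class)
    n = int((class_map.labels == code).sum())
    return n * px * px / 1e10


def growth_rates(areas: dict[int, float] | pd.Series) -> pd.DataFrame:
    """Annual series with year-on-year growth rate in percent.

    rate_t = (A_t - A_{t-1}) / A_{t-1} x 100; the first year's rate is NaN.
    """
    s = pd.Series(dict(areas)).sort_index() if isinstance(areas, dict) \
        else areas.sort_index()
    if s.size < 2:
        raise ValueError("need at least 2 years")
    prior = s.shift(1)
    if (prior.iloc[1:] == 0).any():
        raise ValueError("zero prior-year area; growth rate undefined")
    rate = (s - prior) / prior * 100.0
    return pd.DataFrame({"year": s.index, "area_mha": s.to_numpy(),
                         "growth_rate_pct": rate.to_numpy()})


def mean_growth_rate(series: pd.DataFrame, start_year: int,
                     end_year: int) -> float:
    """Arithmetic mean of the annual rates attributed to (start, end]."""
    sel = series[(series["year"] > start_year) & (series["year"] <= end_year)]
    if sel.empty:
        raise ValueError("no annual rates in span")
    return float(sel["growth_rate_pct"].mean())


def change_map(map_t1: ClassMap, map_t2: ClassMap,
               target_class: str | int) -> np.ndarray:
    """Per-pixel transition of the target class between two epochs.

    Codes: absent 0 (neither year), stable 1 (both), gain 2 (t2 only),
    loss 3 (t1 only).
    """
    if map_t1.shape != map_t2.shape:
        raise ValueError("maps have different grids")
    code = _target_code(map_t1, target_class)
    in1 = map_t1.labels == code
    in2 = map_t2.labels == code
    out = np.full(map_t1.shape, CHANGE_CODES["absent"], dtype=np.uint8)
    out[in1 & in2] = CHANGE_CODES["stable"]
    out[~in1 & in2] = CHANGE_CODES["gain"]
    out[in1 & ~in2] = CHANGE_CODES["loss"]
    return out


def planting_frequency(maps: list[ClassMap],
                       target_class: str | int) -> FrequencyRaster:
    """Percent of years each pixel is mapped as the target class."""
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    code = _target_code(maps[0], target_class)
    count = np.zeros(shape, dtype=int)
    for m in maps:
        if m.shape != shape:
            raise ValueError("maps have different grids")
        count += (m.labels == code)
    return FrequencyRaster(values=100.0 * count / len(maps),
                           n_years=len(maps))


def frequency_histogram(freq: FrequencyRaster, pixel_size_m: float = 250.0,
                        edges: tuple[float, ...] = FREQUENCY_BIN_EDGES,
                        ) -> pd.DataFrame:
    """Area (Mha) per planting-frequency bin; the bins partition all pixels.

    Bins: exactly 0, then (edges[i], edges[i+1]) open-ended interiors with
    the upper edge owned by the higher bin, and exactly 100 on its own —
    e.g. 0, (0, 20), [20, 40), [40, 60), [60, 80), [80, 100), 100.
    """
    v = freq.values
    px_mha = pixel_size_m * pixel_size_m / 1e10
    rows = [("0", int((v == 0).sum()))]
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (v > lo) if lo == edges[0] else (v >= lo)
        mask &= (v < hi)
        rows.append((f"{lo:g}-{hi:g}", int(mask.sum())))
    rows.append(("100", int((v == 100).sum())))
    return pd.DataFrame(rows, columns=["bin", "n_pixels"]).assign(
        area_mha=lambda d: d["n_pixels"] * px_mha)


def peak_metrics(values: np.ndarray, doys: np.ndarray,
                 window: tuple[int, int] = WHEAT_WINDOW,
                 ) -> tuple[float, int]:
    """Peak smoothed NDVI and its node DOY inside a phenological window.

    The peak is reported at node resolution (the 8-day composite grid); ties
    resolve to the earliest node.
    """
    values = np.asarray(values)
    doys = np.asarray(doys)
    lo, hi = window
    sel = (doys >= lo) & (doys <= hi)
    if not sel.any():
        raise ValueError(f"no nodes inside DOY window {window}")
    i = int(np.argmax(values[sel]))
    return float(values[sel][i]), int(doys[sel][i])
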