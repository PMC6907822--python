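"""Synthetic MODIS-like dual-sensor scenes with known truth.

Generates multi-year 250 m NDVI composite stacks for a five-class
double-cropping landscape so every downstream stage (gap-fill, harmonic
smoothing, classification, accuracy, spatiotemporal products) is testable
without any satellite download.  Per class, an annual NDVI curve is a
baseline plus Gaussian bumps; the winter wheat-summer maize rotation is
bimodal with the first (wheat) peak drawn from DOY 108-123 and the second
(maize) peak from DOY 221-228 — inside the broad DOY 60-170 / 180-270
windows the two crops occupy.  Cloud (any season) and snow (winter only)
contamination strictly depresses the stored value and marks the reliability
code; everything is reproducible from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import CLASS_CODES, CLASS_NAMES, ClassMap
from .timeseries_io import (NDVI_SCALE, RELIABILITY_CLOUD, RELIABILITY_GOOD,
                            RELIABILITY_MARGINAL, RELIABILITY_SNOW,
                            NodeCalendar, SENSOR_A_DOYS, SENSOR_B_DOYS,
                            TimeSeriesStack)

#: true-NDVI clip range before integer scaling
NDVI_TRUE_MIN, NDVI_TRUE_MAX = -0.2, 0.9

#: winter DOY windows eligible for snow contamination
WINTER_DOY_BELOW, WINTER_DOY_ABOVE = 60, 330

#: wheat / maize peak-DOY draw ranges
WHEAT_PEAK_RANGE = (108, 123)
MAIZE_PEAK_RANGE = (221, 228)


@dataclass(frozen=True)
class PhenologyModel:
    """Annual NDVI curve: baseline + Gaussian bumps + observation noise."""

    class_label: str
    baseline_ndvi: float
    peaks: tuple[tuple[float, float, float], ...]   # (peak_doy, peak_ndvi, width_days)
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.class_label == "wheat_maize":
            if len(self.peaks) != 2:
                raise ValueError("wheat_maize needs exactly 2 peaks")
            (d1, _, _), (d2, _, _) = self.peaks
            if not (60 <= d1 <= 170 and 180 <= d2 <= 270):
                raise ValueError(
                    f"wheat_maize peaks {d1}, {d2} outside DOY 60-170 / 180-270")

    def clean_value(self, doy: float) -> float:
        """Noise-free true NDVI at a day of year."""
        v = self.baseline_ndvi
        for peak_doy, peak_ndvi, width in self.peaks:
            v += peak_ndvi * math.exp(-0.5 * ((doy - peak_doy) / width) ** 2)
        return min(max(v, NDVI_TRUE_MIN), NDVI_TRUE_MAX)


def default_models(rng: np.random.Generator | int | None = None,
                   ) -> dict[str, PhenologyModel]:
    """The five-class phenology set; wheat/maize peak DOYs drawn per call."""
    rng = np.random.default_rng(rng)
    wheat_doy = int(rng.integers(WHEAT_PEAK_RANGE[0], WHEAT_PEAK_RANGE[1] + 1))
    maize_doy = int(rng.integers(MAIZE_PEAK_RANGE[0], MAIZE_PEAK_RANGE[1] + 1))
    return {
        "wheat_maize": PhenologyModel(
            "wheat_maize", baseline_ndvi=0.15,
            peaks=((wheat_doy, 0.60, 24.0), (maize_doy, 0.58, 20.0))),
        "one_season": PhenologyModel(
            "one_season", baseline_ndvi=0.18,
            peaks=((190.0, 0.52, 35.0),)),
        "forest_grass": PhenologyModel(
            "forest_grass", baseline_ndvi=0.28,
            peaks=((205.0, 0.42, 55.0),)),
        "water": PhenologyModel(
            "water", baseline_ndvi=-0.08, peaks=(), noise_sd=0.01),
        "built_up": PhenologyModel(
            "built_up", baseline_ndvi=0.10,
            peaks=((200.0, 0.08, 60.0),), noise_sd=0.015),
    }


def curve_at(model: PhenologyModel, doy: int,
             rng: np.random.Generator | int | None = None) -> int:
    """Sample one scaled NDVI integer from the model at a day of year."""
    if not 1 <= doy <= 366:
        raise ValueError(f"doy {doy} out of range 1-366")
    rng = np.random.default_rng(rng)
    v = model.clean_value(doy)
    if model.noise_sd > 0:
        v += rng.normal(0.0, model.noise_sd)
    v = min(max(v, NDVI_TRUE_MIN), NDVI_TRUE_MAX)
    return int(round(v * NDVI_SCALE))


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for one synthetic scene."""

    n_rows: int = 64
    n_cols: int = 64
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "wheat_maize": 0.40, "one_season": 0.15, "forest_grass": 0.20,
        "water": 0.10, "built_up": 0.15})
    patch_scale_px: int = 4
    years: tuple[int, int] = (2004, 2016)
    cloud_prob: float = 0.2
    snow_prob_winter: float = 0.3
    marginal_prob: float = 0.1
    expansion_rate: float = 0.02      # fractional yearly growth of expansion_to
    expansion_from: str = "one_season"
    expansion_to: str = "wheat_maize"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")


def _patchy_class_map(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rectangular patches of size patch_scale_px, classes drawn by fraction."""
    labels = sorted(spec.class_fractions, key=CLASS_CODES.get)
    codes = np.array([CLASS_CODES[c] for c in labels])
    probs = np.array([spec.class_fractions[c] for c in labels])
    ps = max(1, spec.patch_scale_px)
    br = -(-spec.n_rows // ps)
    bc = -(-spec.n_cols // ps)
    block = codes[rng.choice(codes.size, size=(br, bc), p=probs)]
    full = np.repeat(np.repeat(block, ps, axis=0), ps, axis=1)
    return full[:spec.n_rows, :spec.n_cols]


def _sensor_calendar(years: tuple[int, int], sensor: str) -> NodeCalendar:
    grid = SENSOR_A_DOYS if sensor == "A" else SENSOR_B_DOYS
    entries = tuple((yr, d, sensor)
                    for yr in range(years[0], years[1] + 1) for d in grid)
    return NodeCalendar(entries=entries, nodes_per_year=23)


def generate_scene(spec: SceneSpec,
                   models: dict[str, PhenologyModel] | None = None,
                   change: tuple[int, np.ndarray, str] | None = None,
                   n_ref_per_class: int = 30,
                   geotransform: tuple[float, ...] | None = None,
                   ) -> tuple[TimeSeriesStack, TimeSeriesStack,
                              dict[int, ClassMap], pd.DataFrame]:
    """Generate the two single-sensor stacks, truth maps and reference points.

    When ``models`` is None the default set is redrawn each year, so wheat
    and maize peak timing varies between years inside their stated ranges;
    a supplied ``models`` dict is held fixed across years.  ``change``
    optionally converts pixels: from ``change[0]`` onward, pixels where the
    boolean mask ``change[1]`` is True take class ``change[2]``.

    Unless ``spec.expansion_rate`` is 0, the target rotation additionally
    expands each year by converting random ``expansion_from`` pixels, about
    ``expansion_rate`` of its current extent per year — the interannual area
    growth a multi-year cropping record shows.

    Contamination: cloud at any node with ``cloud_prob`` (reliability 3),
    snow only at winter nodes (DOY < 60 or > 330) with ``snow_prob_winter``
    (reliability 2); either depresses the stored value by a draw from
    U(0.2, 0.6) x 10,000.  Clean nodes carry reliability 0, or 1 with
    ``marginal_prob``.  Bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if models is not None:
        missing = set(CLASS_CODES) - set(models)
        if missing:
            raise ValueError(f"models missing classes: {sorted(missing)}")

    base_truth = _patchy_class_map(spec, rng)
    y0, y1 = spec.years
    years = list(range(y0, y1 + 1))
    gt = geotransform or (0.0, 250.0, 0.0, 0.0, 0.0, -250.0)

    truth: dict[int, ClassMap] = {}
    labels = base_truth.copy()
    from_code = CLASS_CODES[spec.expansion_from]
    to_code = CLASS_CODES[spec.expansion_to]
    for yr in years:
        if yr != years[0] and spec.expansion_rate > 0:
            rr, cc = np.nonzero(labels == from_code)
            n_conv = min(rr.size, int(round(
                spec.expansion_rate * (labels == to_code).sum())))
            if n_conv > 0:
                pick = rng.choice(rr.size, size=n_conv, replace=False)
                labels[rr[pick], cc[pick]] = to_code
        if change is not None and yr >= change[0]:
            labels = labels.copy()
            labels[change[1]] = CLASS_CODES[change[2]]
        truth[yr] = ClassMap(labels=labels.copy(), legend=dict(CLASS_NAMES),
                             year=yr, geotransform=gt, pixel_size_m=250.0)

    year_models = {yr: (models if models is not None else default_models(rng))
                   for yr in years}

    stacks = []
    for sensor in ("A", "B"):
        cal = _sensor_calendar(spec.years, sensor)
        n = len(cal)
        values = np.empty((n, spec.n_rows, spec.n_cols), dtype=np.int16)
        reliability = np.empty_like(values, dtype=np.uint8)
        for i, (yr, doy, _) in enumerate(cal.entries):
            mdl = year_models[yr]
            labels = truth[yr].labels
            clean_lut = np.zeros(max(CLASS_CODES.values()) + 1)
            sd_lut = np.zeros_like(clean_lut)
            for name, code in CLASS_CODES.items():
                clean_lut[code] = mdl[name].clean_value(doy)
                sd_lut[code] = mdl[name].noise_sd
            v = clean_lut[labels] + rng.normal(0.0, 1.0, labels.shape) * sd_lut[labels]
            v = np.clip(v, NDVI_TRUE_MIN, NDVI_TRUE_MAX)
            scaled = np.rint(v * NDVI_SCALE)

            rel = np.where(rng.random(labels.shape) < spec.marginal_prob,
                           RELIABILITY_MARGINAL, RELIABILITY_GOOD).astype(np.uint8)
            winter = doy < WINTER_DOY_BELOW or doy > WINTER_DOY_ABOVE
            snow = (rng.random(labels.shape) < spec.snow_prob_winter) if winter \
                else np.zeros(labels.shape, bool)
            cloud = (rng.random(labels.shape) < spec.cloud_prob) & ~snow
            contaminated = snow | cloud
            depression = rng.uniform(0.2, 0.6, labels.shape) * NDVI_SCALE
            scaled = np.where(contaminated,
                              np.maximum(scaled - depression, -NDVI_SCALE),
                              scaled)
            rel[snow] = RELIABILITY_SNOW
            rel[cloud] = RELIABILITY_CLOUD
            values[i] = np.rint(scaled).astype(np.int16)
            reliability[i] = rel
        stacks.append(TimeSeriesStack(values=values, reliability=reliability,
                                      calendar=cal, geotransform=gt,
                                      pixel_size_m=250.0))

    ref_rows = []
    for yr in years:
        labels = truth[yr].labels
        for name in sorted(CLASS_CODES, key=CLASS_CODES.get):
            rr, cc = np.nonzero(labels == CLASS_CODES[name])
            if rr.size == 0:
                continue
            pick = rng.choice(rr.size, size=min(n_ref_per_class, rr.size),
                              replace=False)
            for j in pick:
                x, y = truth[yr].pixel_coords(int(rr[j]), int(cc[j]))
                ref_rows.append({"x": float(x), "y": float(y), "year": yr,
                                 "class_label": name,
                                 "row": int(rr[j]), "col": int(cc[j])})
    ref_points = pd.DataFrame(ref_rows)
    return stacks[0], stacks[1], truth, ref_points
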