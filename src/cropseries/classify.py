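"""Grid-stratified sampling and random-forest classification of NDVI curves.

Every pixel's 46-node smoothed annual curve is the feature vector; the five
land classes of a double-cropping landscape (winter wheat-summer maize
rotation, one-season crop, forest/grass, water, built-up) are separable on
phenology alone — the rotation's bimodal curve (first peak DOY 60-170,
second DOY 180-270) against unimodal or flat alternatives.

Training points are allocated on a coarse grid (default 50 km) so samples
spread across regional growing-condition gradients, then a 100-tree random
forest with sqrt feature selection votes per pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .timeseries_io import TimeSeriesStack

logger = logging.getLogger("cropseries")

#: land-class legend; codes double as the deterministic tie-break order
CLASS_CODES: dict[str, int] = {
    "wheat_maize": 1,
    "one_season": 2,
    "forest_grass": 3,
    "water": 4,
    "built_up": 5,
}
CLASS_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class ClassMap:
    """Per-year categorical raster with its legend and georeferencing."""

    labels: np.ndarray                       # 2-D integer raster
    legend: dict[int, str]
    year: int
    geotransform: tuple[float, float, float, float, float, float] = (
        0.0, 250.0, 0.0, 0.0, 0.0, -250.0)
    pixel_size_m: float = 250.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        unknown = set(np.unique(self.labels)) - set(self.legend)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_coords(self, row: np.ndarray, col: np.ndarray):
        x0, dx, _, y0, _, dy = self.geotransform
        return x0 + (np.asarray(col) + 0.5) * dx, y0 + (np.asarray(row) + 0.5) * dy

    def coords_to_pixel(self, x: np.ndarray, y: np.ndarray):
        x0, dx, _, y0, _, dy = self.geotransform
        col = np.floor((np.asarray(x) - x0) / dx).astype(int)
        row = np.floor((np.asarray(y) - y0) / dy).astype(int)
        return row, col


@dataclass
class SamplePoint:
    """One labelled training/validation point with its annual curve."""

    x: float
    y: float
    year: int
    class_label: str
    feature_vector: np.ndarray | None = None
    row: int | None = None
    col: int | None = None


@dataclass
class Signature:
    """Per-class temporal signature: per-node mean and sample SD."""

    class_label: str
    mean_curve: np.ndarray
    sd_curve: np.ndarray


def grid_allocate(truth: ClassMap, grid_size_m: float = 50_000.0,
                  samples_per_class_per_tile: int = 5,
                  rng: np.random.Generator | int | None = None,
                  ) -> list[SamplePoint]:
    """Stratified sampling on a coarse grid over the map extent.

    The extent is tiled by ``grid_size_m`` squares; within each tile, up to
    ``samples_per_class_per_tile`` pixels of every class present are drawn
    without replacement and labelled from the truth (or interpretation) map.
    """
    if grid_size_m <= 0:
        raise ValueError("grid_size_m must be > 0")
    rows, cols = truth.shape
    if rows == 0 or cols == 0:
        raise ValueError("empty extent")
    rng = np.random.default_rng(rng)
    tile_px = max(1, int(round(grid_size_m / truth.pixel_size_m)))
    samples: list[SamplePoint] = []
    for r0 in range(0, rows, tile_px):
        for c0 in range(0, cols, tile_px):
            tile = truth.labels[r0:r0 + tile_px, c0:c0 + tile_px]
            for code in sorted(np.unique(tile)):
                rr, cc = np.nonzero(tile == code)
                k = min(samples_per_class_per_tile, rr.size)
                pick = rng.choice(rr.size, size=k, replace=False)
                for j in pick:
                    row, col = int(r0 + rr[j]), int(c0 + cc[j])
                    x, y = truth.pixel_coords(row, col)
                    samples.append(SamplePoint(
                        x=float(x), y=float(y), year=truth.year,
                        class_label=truth.legend[int(code)],
                        row=row, col=col))
    return samples


def attach_features(stack: TimeSeriesStack,
                    samples: list[SamplePoint]) -> list[SamplePoint]:
    """Fill each sample's feature vector with its year's annual curve."""
    for s in samples:
        idx = stack.calendar.year_indices(s.year)
        if s.row is None or s.col is None:
            x0, dx, _, y0, _, dy = stack.geotransform
            s.col = int(np.floor((s.x - x0) / dx))
            s.row = int(np.floor((s.y - y0) / dy))
        s.feature_vector = stack.values[idx, s.row, s.col].astype(float)
    return samples


def class_signatures(stack: TimeSeriesStack,
                     samples: list[SamplePoint]) -> list[Signature]:
    """Per-node mean and sample SD of the sampled curves, per class."""
    samples = list(samples)
    if any(s.feature_vector is None for s in samples):
        attach_features(stack, samples)
    by_class: dict[str, list[np.ndarray]] = {}
    for s in samples:
        by_class.setdefault(s.class_label, []).append(s.feature_vector)
    short = [c for c, v in by_class.items() if len(v) < 2]
    if short:
        raise ValueError(f"classes with < 2 samples: {sorted(short)}")
    sigs = []
    for label in sorted(by_class, key=lambda c: CLASS_CODES.get(c, 99)):
        curves = np.vstack(by_class[label])
        sigs.append(Signature(class_label=label,
                              mean_curve=curves.mean(axis=0),
                              sd_curve=curves.std(axis=0, ddof=1)))
    return sigs


def train_classifier(samples: list[SamplePoint], n_trees: int = 100,
                     seed: int = 0) -> RandomForestClassifier:
    """Train the random-forest ensemble on labelled annual curves.

    Each of ``n_trees`` trees grows on a bootstrap sample with
    floor(sqrt(n_features)) candidate features per split; prediction is the
    majority vote.  Deterministic given ``seed``; samples are sorted before
    fitting so permuting their order cannot change the model.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    feats = [s for s in samples if s.feature_vector is not None]
    if not feats:
        raise ValueError("no samples carry feature vectors")
    order = np.lexsort((
        [s.col if s.col is not None else 0 for s in feats],
        [s.row if s.row is not None else 0 for s in feats],
        [s.year for s in feats],
        [CLASS_CODES.get(s.class_label, 99) for s in feats]))
    X = np.vstack([feats[i].feature_vector for i in order])
    y = np.array([CLASS_CODES[feats[i].class_label] for i in order])
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                   random_state=seed, n_jobs=1)
    model.fit(X, y)
    return model


def predict_map(model: RandomForestClassifier, stack: TimeSeriesStack,
                year: int) -> ClassMap:
    """Classify every pixel's annual curve into a categorical raster.

    Vote ties resolve to the lowest class code (class order in the forest's
    probability argmax).
    """
    idx = stack.calendar.year_indices(year)
    n_nodes, rows, cols = stack.shape
    X = stack.values[idx].reshape(len(idx), -1).T.astype(float)
    labels = model.predict(X).reshape(rows, cols)
    legend = {int(c): CLASS_NAMES[int(c)] for c in model.classes_}
    return ClassMap(labels=labels, legend=legend, year=year,
                    geotransform=stack.geotransform,
                    pixel_size_m=stack.pixel_size_m)
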