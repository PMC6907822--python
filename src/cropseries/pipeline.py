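"""End-to-end driver: simulate -> gap-fill -> HANTS -> classify -> assess.

`run_pipeline` executes the whole mapping chain on a synthetic scene and
returns every intermediate and final product in one results dictionary.
The configuration is a plain dict (YAML-friendly); every stochastic stage
derives from the single scene seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import logging
import time
from typing import Any

import numpy as np
import pandas as pd

from . import accuracy as acc
from . import classify as cls
from . import spatiotemporal as st
from .gapfill import fill_stack
from .hants import HantsParams, hants_stack
from .synthetic_data import SceneSpec, generate_scene
from .timeseries_io import interleave_stacks

logger = logging.getLogger("cropseries")

DEFAULT_CONFIG: dict[str, Any] = {
    "scene": {},                      # SceneSpec keyword overrides
    "hants": {},                      # HantsParams keyword overrides
    "grid_size_m": 50_000.0,
    "samples_per_class_per_tile": 5,
    "n_trees": 100,
    "target_class": "wheat_maize",
}


def run_pipeline(config: dict[str, Any] | None = None) -> dict[str, Any]:
    """Run the full chain; returns a dict of products keyed by stage."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    spec = SceneSpec(**cfg["scene"])
    params = HantsParams(**cfg["hants"])
    target = cfg["target_class"]
    timings: dict[str, float] = {}

    def tic(stage: str, t0: float) -> None:
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %-12s %.2f s", stage, timings[stage])

    t0 = time.perf_counter()
    stack_a, stack_b, truth, ref_points = generate_scene(spec)
    tic("simulate", t0)

    t0 = time.perf_counter()
    merged = interleave_stacks(stack_a, stack_b)
    filled = fill_stack(merged)
    tic("gapfill", t0)

    t0 = time.perf_counter()
    smoothed = hants_stack(filled, params, per_year=True)
    tic("hants", t0)

    t0 = time.perf_counter()
    rng = np.random.default_rng(spec.seed + 1)
    samples: list[cls.SamplePoint] = []
    for yr in sorted(truth):
        pts = cls.grid_allocate(truth[yr], cfg["grid_size_m"],
                                cfg["samples_per_class_per_tile"], rng=rng)
        samples.extend(cls.attach_features(smoothed, pts))
    signatures = cls.class_signatures(smoothed, samples)
    model = cls.train_classifier(samples, n_trees=cfg["n_trees"],
                                 seed=spec.seed)
    maps = {yr: cls.predict_map(model, smoothed, yr) for yr in sorted(truth)}
    tic("classify", t0)

    t0 = time.perf_counter()
    reports = {}
    for yr, m in maps.items():
        pts = ref_points[ref_points["year"] == yr]
        reports[yr] = acc.summarize(acc.confusion(m, pts))
    extracted = {yr: st.class_area(m, target) for yr, m in maps.items()}
    true_area = {yr: st.class_area(t, target) for yr, t in truth.items()}
    years = sorted(extracted)
    slope, intercept, r2 = acc.area_regression(
        [extracted[y] for y in years], [true_area[y] for y in years]) \
        if len(years) >= 3 and np.ptp([true_area[y] for y in years]) > 0 \
        else (float("nan"),) * 3
    consistency = {yr: acc.consistency_index(extracted[yr], true_area[yr])
                   for yr in years if true_area[yr] > 0}
    tic("accuracy", t0)

    t0 = time.perf_counter()
    area_series = st.growth_rates(extracted) if len(years) >= 2 else None
    frequency = st.planting_frequency(list(maps.values()), target)
    histogram = st.frequency_histogram(frequency)
    change = st.change_map(maps[years[0]], maps[years[-1]], target) \
        if len(years) >= 2 else None
    tic("spatiotemporal", t0)

    return {
        "config": cfg,
        "stacks": {"a": stack_a, "b": stack_b, "merged": merged,
                   "filled": filled, "smoothed": smoothed},
        "truth": truth,
        "ref_points": ref_points,
        "samples": samples,
        "signatures": signatures,
        "model": model,
        "maps": maps,
        "reports": reports,
        "extracted_area_mha": extracted,
        "true_area_mha": true_area,
        "area_regression": {"slope": slope, "intercept": intercept, "r2": r2},
        "consistency": consistency,
        "area_series": area_series,
        "frequency": frequency,
        "frequency_histogram": histogram,
        "change_map": change,
        "timings": timings,
    }
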