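"""Grid sampling, class signatures and random-forest mapping."""

import numpy as np
import pytest

from cropseries.classify import (CLASS_CODES, CLASS_NAMES, ClassMap,
                                 SamplePoint, attach_features,
                                 class_signatures, grid_allocate, predict_map,
                                 train_classifier)
from cropseries.synthetic_data import SceneSpec, generate_scene
from cropseries.gapfill import fill_stack
from cropseries.hants import hants_stack
from cropseries.timeseries_io import interleave_stacks


def _truth_map(labels, year=2016, pixel_size=250.0):
    gt = (0.0, pixel_size, 0.0, 0.0, 0.0, -pixel_size)
    return ClassMap(labels=labels, legend=dict(CLASS_NAMES), year=year,
                    geotransform=gt, pixel_size_m=pixel_size)


def _toy_samples(n_per_class=50, n_features=46, seed=0):
    """Linearly separable toy: flat curves vs bimodal curves."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_features)
    flat = rng.normal(1000, 50, (n_per_class, n_features))
    bimodal = (4000 * np.exp(-((t - 0.3) / 0.08) ** 2)
               + 4000 * np.exp(-((t - 0.7) / 0.08) ** 2)
               + rng.normal(0, 50, (n_per_class, n_features)))
    samples = []
    for curve in flat:
        samples.append(SamplePoint(0, 0, 2016, "water", curve))
    for curve in bimodal:
        samples.append(SamplePoint(0, 0, 2016, "wheat_maize", curve))
    return samples


class TestGridAllocate:
    def test_four_tiles_for_100km_extent_50km_grid(self):
        # 100 km x 100 km at 250 m = 400 x 400 px; one class per quadrant
        labels = np.ones((400, 400), int)
        labels[:200, 200:] = 2
        labels[200:, :200] = 3
        labels[200:, 200:] = 4
        pts = grid_allocate(_truth_map(labels), grid_size_m=50_000.0,
                            samples_per_class_per_tile=5, rng=0)
        # 4 tiles x 1 class x 5 samples
        assert len(pts) == 20
        assert {p.class_label for p in pts} == {
            "wheat_maize", "one_season", "forest_grass", "water"}

    def test_single_class_truth(self):
        pts = grid_allocate(_truth_map(np.full((10, 10), 4)), rng=1)
        assert all(p.class_label == "water" for p in pts)

    def test_seed_reproducible(self):
        labels = np.random.default_rng(0).integers(1, 6, (20, 20))
        a = grid_allocate(_truth_map(labels), rng=7)
        b = grid_allocate(_truth_map(labels), rng=7)
        assert [(p.row, p.col, p.class_label) for p in a] == \
               [(p.row, p.col, p.class_label) for p in b]

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError):
            grid_allocate(_truth_map(np.ones((0, 5), int)))


class TestSignatures:
    def _stack(self):
        spec = SceneSpec(n_rows=10, n_cols=10, years=(2016, 2016),
                         cloud_prob=0.0, snow_prob_winter=0.0, seed=5)
        a, b, truth, _ = generate_scene(spec)
        return interleave_stacks(a, b), truth[2016]

    def test_identical_curves_zero_sd(self):
        curve = np.arange(46.0)
        samples = [SamplePoint(0, 0, 2016, "water", curve.copy())
                   for _ in range(3)]
        stack, _ = self._stack()
        sigs = class_signatures(stack, samples)
        assert np.all(sigs[0].sd_curve == 0)

    def test_two_sample_mean_and_sample_sd(self):
        samples = [SamplePoint(0, 0, 2016, "water", np.full(46, 4000.0)),
                   SamplePoint(0, 0, 2016, "water", np.full(46, 6000.0))]
        stack, _ = self._stack()
        sig = class_signatures(stack, samples)[0]
        assert np.allclose(sig.mean_curve, 5000)
        assert np.allclose(sig.sd_curve, 1414.2135623)   # sample SD convention

    def test_wheat_signature_peaks_in_wheat_window(self):
        stack, truth = self._stack()
        pts = grid_allocate(truth, samples_per_class_per_tile=10, rng=3)
        sigs = class_signatures(stack, attach_features(stack, pts))
        wm = next(s for s in sigs if s.class_label == "wheat_maize")
        doys = stack.calendar.doys()
        peak_doy = doys[np.argmax(wm.mean_curve)]
        assert 60 <= peak_doy <= 170

    def test_class_with_too_few_samples_reported(self):
        stack, _ = self._stack()
        samples = [SamplePoint(0, 0, 2016, "water", np.zeros(46))]
        with pytest.raises(ValueError, match="water"):
            class_signatures(stack, samples)


class TestRandomForest:
    def test_separable_toy_perfect_training_vote(self):
        samples = _toy_samples()
        model = train_classifier(samples, n_trees=100, seed=0)
        X = np.vstack([s.feature_vector for s in samples])
        y = np.array([CLASS_CODES[s.class_label] for s in samples])
        assert (model.predict(X) == y).all()

    def test_sample_order_does_not_change_predictions(self, rng):
        samples = _toy_samples()
        shuffled = list(samples)
        rng.shuffle(shuffled)
        m1 = train_classifier(samples, seed=0)
        m2 = train_classifier(shuffled, seed=0)
        probe = rng.normal(2000, 500, (20, 46))
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))

    def test_duplicating_class_samples_keeps_recall(self):
        samples = _toy_samples()
        extra = samples + [s for s in samples if s.class_label == "wheat_maize"]
        m1 = train_classifier(samples, seed=0)
        m2 = train_classifier(extra, seed=0)
        wm = np.vstack([s.feature_vector for s in samples
                        if s.class_label == "wheat_maize"])
        code = CLASS_CODES["wheat_maize"]
        assert (m2.predict(wm) == code).mean() >= (m1.predict(wm) == code).mean()

    def test_single_class_training_rejected(self):
        samples = [s for s in _toy_samples() if s.class_label == "water"]
        with pytest.raises(ValueError):
            train_classifier(samples)

    def test_constant_water_scene_maps_all_water(self):
        kw = dict(n_rows=8, n_cols=8, years=(2016, 2016), cloud_prob=0.0,
                  snow_prob_winter=0.0, expansion_rate=0.0)
        mixed = SceneSpec(class_fractions={
            "wheat_maize": 0.5, "one_season": 0.0, "forest_grass": 0.0,
            "water": 0.5, "built_up": 0.0}, seed=2, **kw)
        a, b, truth, _ = generate_scene(mixed)
        train_stack = interleave_stacks(a, b)
        pts = attach_features(train_stack,
                              grid_allocate(truth[2016],
                                            samples_per_class_per_tile=15,
                                            rng=0))
        model = train_classifier(pts, seed=0)

        water_only = {c: (1.0 if c == "water" else 0.0) for c in CLASS_CODES}
        spec = SceneSpec(class_fractions=water_only, seed=9, **kw)
        a, b, _, _ = generate_scene(spec)
        cmap = predict_map(model, interleave_stacks(a, b), 2016)
        assert np.all(cmap.labels == CLASS_CODES["water"])

    def test_end_to_end_single_year_held_out_accuracy(self):
        spec = SceneSpec(n_rows=24, n_cols=24, years=(2016, 2016), seed=17)
        a, b, truth, ref = generate_scene(spec)
        stack = hants_stack(fill_stack(interleave_stacks(a, b)))
        pts = grid_allocate(truth[2016], samples_per_class_per_tile=20, rng=4)
        model = train_classifier(attach_features(stack, pts), seed=0)
        cmap = predict_map(model, stack, 2016)
        held = ref[ref["year"] == 2016]
        pred = cmap.labels[held["row"], held["col"]]
        truth_codes = held["class_label"].map(CLASS_CODES).to_numpy()
        assert (pred == truth_codes).mean() >= 0.9
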