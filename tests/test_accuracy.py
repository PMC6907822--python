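"""Confusion-matrix statistics, consistency index and area regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from cropseries.accuracy import (WHEAT_MAIZE_ANNUAL_ACCURACY, ConfusionMatrix,
                                 area_regression, confusion,
                                 consistency_binning, consistency_index,
                                 summarize)
from cropseries.classify import CLASS_CODES, CLASS_NAMES, ClassMap


def _map(labels, year=2016):
    return ClassMap(labels=np.asarray(labels), legend=dict(CLASS_NAMES),
                    year=year, geotransform=(0, 250.0, 0, 0, 0, -250.0))


def _points(rows, cols, names):
    x = (np.asarray(cols) + 0.5) * 250.0
    y = (np.asarray(rows) + 0.5) * -250.0
    return pd.DataFrame({"x": x, "y": y, "class_label": names,
                         "year": 2016})


class TestConfusion:
    def test_perfect_map_is_diagonal(self):
        labels = np.tile(np.arange(1, 6), (5, 1))
        cmap = _map(labels)
        pts = _points([0, 1, 2, 3, 4], [0, 1, 2, 3, 4],
                      [CLASS_NAMES[c] for c in range(1, 6)])
        cm = confusion(cmap, pts)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.total == 5

    def test_single_cross_error(self):
        labels = np.full((2, 5), CLASS_CODES["water"])
        cmap = _map(labels)
        names = ["water"] * 9 + ["wheat_maize"]     # one reference disagrees
        pts = _points([0] * 5 + [1] * 5, list(range(5)) * 2, names)
        cm = confusion(cmap, pts)
        i_water = sorted(cm.legend).index(CLASS_CODES["water"])
        i_wm = sorted(cm.legend).index(CLASS_CODES["wheat_maize"])
        assert cm.counts[i_water, i_wm] == 1
        assert cm.counts.sum() == 10

    def test_matches_brute_force_tally(self, rng):
        labels = rng.integers(1, 6, (12, 12))
        cmap = _map(labels)
        r = rng.integers(0, 12, 60)
        c = rng.integers(0, 12, 60)
        names = [CLASS_NAMES[int(k)] for k in rng.integers(1, 6, 60)]
        cm = confusion(cmap, _points(r, c, names))
        codes = sorted(cm.legend)
        expected = np.zeros((5, 5), int)
        for rr, cc, name in zip(r, c, names):
            expected[codes.index(int(labels[rr, cc])),
                     codes.index(CLASS_CODES[name])] += 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_point_outside_extent_listed(self):
        cmap = _map(np.full((2, 2), 4))
        pts = _points([0, 5], [0, 0], ["water", "water"])
        with pytest.raises(ValueError, match="outside extent"):
            confusion(cmap, pts)


class TestSummarize:
    def _cm(self, counts):
        legend = {1: "wheat_maize", 2: "one_season"}
        return ConfusionMatrix(counts=np.asarray(counts), legend=legend)

    def test_diagonal_gives_oa_100_kappa_1(self):
        rep = summarize(self._cm([[10, 0], [0, 30]]))
        assert rep.overall_accuracy == 100
        assert rep.kappa == 1

    def test_hand_computed_balanced_matrix(self):
        # p_o = 0.9, p_e = 0.5 -> kappa 0.8
        rep = summarize(self._cm([[45, 5], [5, 45]]))
        assert rep.overall_accuracy == pytest.approx(90.0)
        assert rep.kappa == pytest.approx(0.8)
        assert rep.users_accuracy["wheat_maize"] == pytest.approx(90.0)
        assert rep.producers_accuracy["one_season"] == pytest.approx(90.0)

    def test_uniform_matrix_kappa_zero(self):
        rep = summarize(self._cm([[25, 25], [25, 25]]))
        assert rep.kappa == pytest.approx(0.0)

    def test_empty_column_reported_missing(self):
        rep = summarize(self._cm([[10, 5], [0, 0]]))
        assert np.isnan(rep.users_accuracy["one_season"])
        assert not np.isnan(rep.producers_accuracy["one_season"])

    def test_kappa_range_and_diagonal_iff_one(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, (2, 2))
            if counts.sum() == 0:
                continue
            rep = summarize(self._cm(counts))
            assert -1 <= rep.kappa <= 1 + 1e-12
            off_diag = counts[0, 1] + counts[1, 0]
            if rep.kappa == 1:
                assert off_diag == 0 and np.trace(counts) > 0


class TestConsistency:
    @pytest.mark.parametrize("x,y,c", [
        (3.5, 3.5, 100.0),
        (0.0, 2.0, 0.0),
        (1.2, 1.0, 80.0),
        (2.5, 1.0, -50.0),      # x > 2y goes negative, unclamped
    ])
    def test_examples(self, x, y, c):
        assert consistency_index(x, y) == pytest.approx(c)

    @given(hst.floats(0.01, 100), hst.floats(0.01, 100), hst.floats(0.01, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, y, a):
        assert consistency_index(a * x, a * y) == pytest.approx(
            consistency_index(x, y), abs=1e-8)

    def test_nonpositive_statistical_area_rejected(self):
        with pytest.raises(ValueError):
            consistency_index(1.0, 0.0)

    def test_binning_examples(self):
        assert consistency_binning([100.0] * 13) == {
            ">80": 13, "60-80": 0, "40-60": 0, "20-40": 0, "<20": 0}
        assert consistency_binning([85, 70, 50, 30, 10]) == {
            ">80": 1, "60-80": 1, "40-60": 1, "20-40": 1, "<20": 1}

    def test_bin_counts_sum_to_n_years(self, rng):
        indices = rng.uniform(-50, 100, 13)
        assert sum(consistency_binning(indices).values()) == 13


class TestAreaRegression:
    def test_identity_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        slope, intercept, r2 = area_regression(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_extracted_r2_zero(self):
        slope, _, r2 = area_regression([2, 2, 2, 2], [1, 2, 3, 4])
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0.5, 5, 20)
        y = 1.1 * x + 0.2 + rng.normal(0, 0.3, 20)
        slope, intercept, r2 = area_regression(y, x)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fitted = X @ beta
        ss_res = ((y - fitted) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert intercept == pytest.approx(beta[0], abs=1e-10)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            area_regression([1, 2, 3], [5, 5, 5])


def test_reference_accuracy_series_is_complete():
    df = WHEAT_MAIZE_ANNUAL_ACCURACY
    assert list(df["year"]) == list(range(2004, 2017))
    assert df["users_accuracy_pct"].between(0, 100).all()
    assert df["producers_accuracy_pct"].between(0, 100).all()
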