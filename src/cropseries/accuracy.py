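"""Accuracy assessment: confusion matrices, kappa, consistency index, OLS.

Three complementary checks on a mapped product: (1) point-based
classification accuracy from a confusion matrix (overall accuracy, kappa,
per-class user's and producer's accuracy); (2) the consistency index
c = (1 - |x - y| / y) * 100 comparing a mapped area x against the
corresponding statistical (yearbook) area y, with its conventional binning;
(3) ordinary least squares of mapped against statistical areas (slope,
intercept, R^2).

Rows of the confusion matrix are the mapped class, columns the reference
class, so user's accuracy is a row quantity and producer's a column one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassMap

#: consistency-index bins, highest first; lower edge inclusive except "<20"
CONSISTENCY_BINS = (">80", "60-80", "40-60", "20-40", "<20")

#: published province-scale reference series: per-year user's and producer's
#: accuracy (%) of the winter wheat-summer maize class, 2004-2016, used as a
#: benchmark input for summary statistics.
WHEAT_MAIZE_ANNUAL_ACCURACY = pd.DataFrame({
    "year": list(range(2004, 2017)),
    "users_accuracy_pct": [94.7, 93.8, 96.4, 93.9, 93.2, 93.7, 94.1,
                           93.2, 96.1, 95.7, 91.8, 95.9, 95.8],
    "producers_accuracy_pct": [86.1, 92.1, 92.9, 84.1, 92.8, 91.6, 91.3,
                               92.2, 91.7, 92.2, 84.4, 93.3, 88.4],
})


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                 # k x k; rows mapped, cols reference
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.legend)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k matching the legend")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [self.legend[c] for c in sorted(self.legend)]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class AccuracyReport:
    overall_accuracy: float                    # percent
    kappa: float
    users_accuracy: dict[str, float]           # percent; NaN if row empty
    producers_accuracy: dict[str, float]       # percent; NaN if col empty


def confusion(pred: ClassMap, ref_points: pd.DataFrame) -> ConfusionMatrix:
    """Tally (mapped, reference) pairs at the reference points.

    ``ref_points`` needs columns x, y, class_label (map coordinates).
    Points falling outside the map extent raise, listing the offenders.
    """
    rows, cols = pred.shape
    r, c = pred.coords_to_pixel(ref_points["x"].to_numpy(),
                                ref_points["y"].to_numpy())
    outside = (r < 0) | (r >= rows) | (c < 0) | (c >= cols)
    if outside.any():
        bad = ref_points.loc[outside, ["x", "y"]].to_records(index=False)
        raise ValueError(f"{outside.sum()} reference points outside extent: "
                         f"{list(bad)[:10]}")
    legend = dict(sorted(pred.legend.items()))
    code_to_idx = {code: i for i, code in enumerate(legend)}
    name_to_idx = {name: i for i, (code, name) in enumerate(legend.items())}
    counts = np.zeros((len(legend), len(legend)), dtype=int)
    mapped = pred.labels[r, c]
    for m, ref_name in zip(mapped, ref_points["class_label"]):
        counts[code_to_idx[int(m)], name_to_idx[str(ref_name)]] += 1
    return ConfusionMatrix(counts=counts, legend=legend)


def summarize(cm: ConfusionMatrix) -> AccuracyReport:
    """Overall accuracy, kappa and per-class user's/producer's accuracy.

    OA = trace/total x 100; UA_i = diag_i/rowsum_i x 100;
    PA_i = diag_i/colsum_i x 100; kappa = (p_o - p_e) / (1 - p_e) with
    p_e = sum_i rowsum_i * colsum_i / total^2.  Empty rows or columns make
    the class's UA or PA undefined (NaN).
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    rowsum = counts.sum(axis=1)
    colsum = counts.sum(axis=0)
    p_o = diag.sum() / total
    p_e = float(rowsum @ colsum) / total ** 2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    names = [cm.legend[c] for c in sorted(cm.legend)]
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(rowsum > 0, diag / rowsum * 100.0, np.nan)
        pa = np.where(colsum > 0, diag / colsum * 100.0, np.nan)
    return AccuracyReport(
        overall_accuracy=p_o * 100.0,
        kappa=float(kappa),
        users_accuracy=dict(zip(names, ua)),
        producers_accuracy=dict(zip(names, pa)),
    )


def consistency_index(extracted_area: float, statistical_area: float) -> float:
    """c = (1 - |x - y| / y) * 100; unclamped, so x > 2y goes negative."""
    if statistical_area <= 0:
        raise ValueError("statistical area must be > 0")
    return (1.0 - abs(extracted_area - statistical_area) / statistical_area) * 100.0


def consistency_binning(indices) -> dict[str, int]:
    """Count consistency indices into the conventional report bins.

    Bins: >80 (i.e. (80, 100]), [60, 80), [40, 60), [20, 40), <20 (includes
    any negative values).
    """
    out = {b: 0 for b in CONSISTENCY_BINS}
    for c in indices:
        if c > 80:
            out[">80"] += 1
        elif c >= 60:
            out["60-80"] += 1
        elif c >= 40:
            out["40-60"] += 1
        elif c >= 20:
            out["20-40"] += 1
        else:
            out["<20"] += 1
    return out


def area_regression(extracted, statistical) -> tuple[float, float, float]:
    """OLS of extracted area on statistical area: (slope, intercept, R^2)."""
    x = np.asarray(statistical, dtype=float)
    y = np.asarray(extracted, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired areas")
    if np.ptp(x) == 0:
        raise ValueError("statistical areas have zero variance")
    res = stats.linregress(x, y)
    # constant extracted series: correlation undefined, R^2 is 0 by convention
    r2 = 0.0 if not np.isfinite(res.rvalue) else float(res.rvalue ** 2)
    return float(res.slope), float(res.intercept), r2
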