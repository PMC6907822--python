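"""Harmonic Analysis of Time Series (HANTS), implemented from scratch.

HANTS fits a truncated Fourier series

    y(t) = a0 + sum_{i=1..n_freq} a_i cos(2 pi i t / T) + b_i sin(2 pi i t / T)

to an NDVI series by iterated least squares with one-sided outlier
suppression.  Four control parameters drive the algorithm: the valid data
range (values outside are pre-rejected), the number of frequencies, the fit
error tolerance (FET) and the degree of overdeterminedness (DoD).  With
"low" suppression — the right choice for vegetation indices, where residual
cloud and snow only depress the signal — the point lying furthest *below*
the current curve by more than FET is rejected and the curve refit, until
no accepted point violates the tolerance, the accepted count would drop
below ``2 * n_freq + 1 + dod``, or ``max_iter`` is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .timeseries_io import TimeSeriesStack

logger = logging.getLogger("cropseries")


class HantsError(ValueError):
    """Raised when a series cannot be fit (too few usable points)."""

    def __init__(self, message: str, n_usable: int | None = None):
        super().__init__(message)
        self.n_usable = n_usable


@dataclass(frozen=True)
class HantsParams:
    """Control parameters, on the scaled (x 10,000) NDVI axis.

    Defaults follow the standard configuration for 16-day composite NDVI:
    valid range -2000..9000, 3 frequencies, FET 1000, DoD 8.  The minimum
    number of accepted points for a fit is ``2 * n_freq + 1 + dod`` (15 by
    default).  ``base_period_nodes`` x 8 days sets the fundamental period T
    (368 days for the 46-node annual series).
    """

    valid_min: float = -2000.0
    valid_max: float = 9000.0
    n_freq: int = 3
    fit_error_tolerance: float = 1000.0
    dod: int = 8
    suppression: str = "low"          # {"low", "high", "none"}
    base_period_nodes: int = 46
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.valid_min >= self.valid_max:
            raise ValueError("valid_min must be < valid_max")
        if self.n_freq < 1:
            raise ValueError("n_freq must be >= 1")
        if self.suppression not in ("low", "high", "none"):
            raise ValueError(f"unknown suppression {self.suppression!r}")

    @property
    def min_points(self) -> int:
        return 2 * self.n_freq + 1 + self.dod

    @property
    def base_period_days(self) -> float:
        return self.base_period_nodes * 8.0


@dataclass
class HantsResult:
    smoothed: np.ndarray          # fitted curve at every input node
    coefficients: np.ndarray      # [a0, a1, b1, ..., a_nf, b_nf]
    rejected_mask: np.ndarray     # True where the point was excluded
    converged: bool


def design_matrix(t: np.ndarray, n_freq: int, period_days: float) -> np.ndarray:
    """Fourier design matrix: constant column then cos/sin pairs."""
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t)]
    for i in range(1, n_freq + 1):
        w = 2.0 * np.pi * i * t / period_days
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def hants_fit(values: np.ndarray, doys: np.ndarray,
              params: HantsParams | None = None) -> HantsResult:
    """Fit one series by iterative Fourier least squares with suppression.

    ``doys`` are the node positions in days (they may exceed 366 when
    fitting a multi-year series against an annual period).  Out-of-valid-
    range values are rejected before the first fit.
    """
    params = params or HantsParams()
    y = np.asarray(values, dtype=float)
    t = np.asarray(doys, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("values and doys must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("doys must be strictly increasing")
    n = y.size
    if n < params.min_points:
        raise HantsError(
            f"series length {n} < minimum points {params.min_points}",
            n_usable=n)

    accepted = (y >= params.valid_min) & (y <= params.valid_max)
    n_ok = int(accepted.sum())
    if n_ok < params.min_points:
        raise HantsError(
            f"only {n_ok} in-range points, need {params.min_points}",
            n_usable=n_ok)

    D = design_matrix(t, params.n_freq, params.base_period_days)
    fet = params.fit_error_tolerance
    coef = np.zeros(D.shape[1])
    fitted = np.zeros(n)
    converged = False
    for _ in range(params.max_iter):
        coef, *_ = np.linalg.lstsq(D[accepted], y[accepted], rcond=None)
        fitted = D @ coef
        if params.suppression == "low":
            err = fitted - y            # positive where point sits below curve
        elif params.suppression == "high":
            err = y - fitted
        else:
            err = np.abs(y - fitted)
        err = np.where(accepted, err, -np.inf)
        worst = int(np.argmax(err))
        if err[worst] <= fet:
            converged = True
            break
        if accepted.sum() - 1 < params.min_points:
            break
        accepted[worst] = False
    return HantsResult(smoothed=fitted, coefficients=coef,
                       rejected_mask=~accepted, converged=converged)


def hants_stack(stack: TimeSeriesStack, params: HantsParams | None = None,
                per_year: bool = True) -> TimeSeriesStack:
    """Smooth every pixel of a stack; per calendar year by default.

    Per-year mode fits each year's nodes against the annual base period;
    whole-series mode fits all nodes at once on a continuous day axis with
    the same annual period, capturing 13 repeats of the seasonal cycle.
    Pixels that fail to fit (too few in-range points) or do not converge
    keep their input (gap-filled) values; their count is logged.
    """
    params = params or HantsParams()
    cal = stack.calendar
    if per_year and cal.nodes_per_year < params.min_points:
        raise HantsError(
            f"{cal.nodes_per_year} nodes/year < minimum {params.min_points}")

    years = cal.years
    y0 = years[0]
    doys = cal.doys()
    if per_year:
        windows = [(cal.year_indices(yr), doys[cal.year_indices(yr)].astype(float))
                   for yr in years]
    else:
        yr_index = np.array([yr - y0 for yr, _, _ in cal.entries])
        t_all = yr_index * params.base_period_days + doys
        windows = [(np.arange(len(cal)), t_all.astype(float))]

    out = stack.copy()
    n_nodes, rows, cols = stack.shape
    flat_in = stack.values.reshape(n_nodes, -1).astype(float)
    flat_out = flat_in.copy()
    n_failed = 0
    for idx, t in windows:
        D = design_matrix(t, params.n_freq, params.base_period_days)
        Y = flat_in[idx]
        # batch first pass: pixels that are fully in range and already
        # within tolerance need no iteration
        in_range = (Y >= params.valid_min) & (Y <= params.valid_max)
        all_ok = in_range.all(axis=0)
        coefs, *_ = np.linalg.lstsq(D, Y, rcond=None)
        fit0 = D @ coefs
        if params.suppression == "low":
            err0 = fit0 - Y
        elif params.suppression == "high":
            err0 = Y - fit0
        else:
            err0 = np.abs(Y - fit0)
        clean = all_ok & (err0.max(axis=0) <= params.fit_error_tolerance)
        flat_out[np.ix_(idx, np.flatnonzero(clean))] = fit0[:, clean]
        for pix in np.flatnonzero(~clean):
            try:
                res = hants_fit(Y[:, pix], t, params)
            except HantsError:
                n_failed += 1
                continue
            if not res.converged:
                n_failed += 1
                continue
            flat_out[idx, pix] = res.smoothed
    if n_failed:
        logger.warning("hants_stack: %d pixel-window fits kept input values",
                       n_failed)
    out.values = np.rint(flat_out).astype(stack.values.dtype).reshape(
        n_nodes, rows, cols)
    return out
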