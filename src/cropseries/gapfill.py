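"""Replace cloud/snow-flagged nodes by linear interpolation in time.

Nodes whose pixel-reliability code marks snow/ice (2), cloud (3) or fill
(255) get their value replaced by linearly interpolating between the nearest
temporally adjacent nodes with good (0) or marginal (1) codes.  Codes 0 and
1 are kept untouched.  Because the merged calendar is equally spaced (8
days), interpolating in node-index time equals interpolating in DOY time;
the series is treated as one continuous multi-year record, so interpolation
may cross the December/January boundary.  Leading and trailing flagged runs
are filled by constant extension of the nearest good value.
"""

from __future__ import annotations

import logging

import numpy as np

from .timeseries_io import FLAGGED_CODES, TimeSeriesStack

logger = logging.getLogger("cropseries")


class GapfillError(ValueError):
    """Raised when a series has no usable anchor nodes."""


def fill_series(values: np.ndarray, reliability: np.ndarray,
                flag_codes: tuple[int, ...] = FLAGGED_CODES,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Fill one pixel's series; returns (filled values, replaced mask).

    Interpolation anchors are exclusively the nodes *not* in ``flag_codes``;
    flagged values never contribute, however plausible they look.
    """
    values = np.asarray(values)
    reliability = np.asarray(reliability)
    if values.shape != reliability.shape or values.ndim != 1:
        raise ValueError("values and reliability must be equal-length 1-D")
    if values.size < 2:
        raise ValueError("need at least 2 nodes")
    flagged = np.isin(reliability, flag_codes)
    if flagged.all():
        raise GapfillError("every node is flagged; series unusable")
    if not flagged.any():
        return values.copy(), flagged
    idx = np.arange(values.size)
    good = ~flagged
    # np.interp extends the edges with the nearest anchor value
    filled = values.astype(float).copy()
    filled[flagged] = np.interp(idx[flagged], idx[good],
                                values[good].astype(float))
    if np.issubdtype(values.dtype, np.integer):
        filled = np.rint(filled)
    return filled.astype(values.dtype), flagged


def fill_stack(stack: TimeSeriesStack,
               flag_codes: tuple[int, ...] = FLAGGED_CODES) -> TimeSeriesStack:
    """Apply :func:`fill_series` to every pixel independently.

    The reliability cube is returned unchanged (quality marks are retained).
    Pixels flagged at every node cannot be filled; they keep their values
    and their count is logged rather than raising.
    """
    out = stack.copy()
    n_nodes = stack.n_nodes
    vals = stack.values.reshape(n_nodes, -1)
    rels = stack.reliability.reshape(n_nodes, -1)
    filled = out.values.reshape(n_nodes, -1)
    flagged = np.isin(rels, flag_codes)
    n_unfillable = 0
    idx = np.arange(n_nodes, dtype=float)
    for p in np.flatnonzero(flagged.any(axis=0)):
        col_flag = flagged[:, p]
        if col_flag.all():
            n_unfillable += 1
            continue
        good = ~col_flag
        interp = np.interp(idx[col_flag], idx[good], vals[good, p].astype(float))
        filled[col_flag, p] = np.rint(interp).astype(stack.values.dtype)
    if n_unfillable:
        logger.warning("fill_stack: %d pixels flagged at every node left "
                       "unfilled", n_unfillable)
    return out
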