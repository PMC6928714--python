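"""Sliding (weighted) percentile kernels shared by activity labeling and features.

The weighted percentile of a window is the smallest value whose normalized
cumulative weight, with values sorted ascending, reaches q/100.  With uniform
weights this reduces exactly to the nearest-rank (inverted CDF) percentile,
which is why the unweighted statistic is implemented as a degenerate kernel.

NaN entries mark epochs that are unusable (inactive or off-wrist); they carry
zero weight, so windows shrink around them and at the series edges.  A window
with no usable value yields NaN.
"""

from __future__ import annotations

import numpy as np

# Relative tolerance on the cumulative-weight threshold so that mathematically
# exact rational hits (e.g. q=10 over 10 equally weighted points) land on the
# intended rank despite binary floating point.
_CUM_RTOL = 1e-9


def triangular_weights(window_epochs: int) -> np.ndarray:
    """Linear kernel, maximal at the window center, declining symmetrically
    toward zero one step past each edge (so edge epochs keep positive weight)."""
    if window_epochs < 1 or window_epochs % 2 == 0:
        raise ValueError("window_epochs must be a positive odd integer")
    half = window_epochs // 2
    offsets = np.abs(np.arange(window_epochs) - half)
    return 1.0 - offsets / (half + 1.0)


def sliding_weighted_percentile(
    values: np.ndarray,
    window_epochs: int,
    q: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted moving percentile of ``values`` over a centered window.

    Parameters
    ----------
    values
        1-D float array; NaN marks unusable entries.
    window_epochs
        Odd window length in epochs.
    q
        Percentile in (0, 100).
    weights
        Kernel of length ``window_epochs``; defaults to uniform (the plain
        nearest-rank moving percentile).
    """
    if not 0 < q < 100:
        raise ValueError(f"q must lie in (0, 100), got {q}")
    if window_epochs < 1 or window_epochs % 2 == 0:
        raise ValueError("window_epochs must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if weights is None:
        weights = np.ones(window_epochs)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (window_epochs,):
            raise ValueError("weights must match window_epochs")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")

    n = values.size
    if n == 0:
        return np.empty(0)
    half = window_epochs // 2
    padded = np.concatenate([np.full(half, np.nan), values, np.full(half, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, window_epochs)

    # Sort each window ascending; NaN sorts last so its weight can be zeroed.
    order = np.argsort(windows, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(windows, order, axis=1)
    w = np.broadcast_to(weights, windows.shape)
    sorted_w = np.take_along_axis(w, order, axis=1).copy()
    sorted_w[np.isnan(sorted_vals)] = 0.0

    cum = np.cumsum(sorted_w, axis=1)
    total = cum[:, -1]
    out = np.full(n, np.nan)
    usable = total > 0
    if not np.any(usable):
        return out
    threshold = (q / 100.0) * total[usable]
    tol = _CUM_RTOL * total[usable]
    reached = cum[usable] >= (threshold - tol)[:, None]
    idx = np.argmax(reached, axis=1)
    out[usable] = sorted_vals[usable, idx]
    return out


def brute_force_weighted_percentile(
    window_values: np.ndarray, window_weights: np.ndarray, q: float
) -> float:
    """Direct single-window reference: explicit sort and cumulative-weight scan.

    Kept here (rather than in tests) for reuse as a documented definition; the
    test suite carries its own independent re-implementation as the oracle.
    """
    vals = np.asarray(window_values, dtype=float)
    wts = np.asarray(window_weights, dtype=float).copy()
    wts[np.isnan(vals)] = 0.0
    keep = wts > 0
    vals, wts = vals[keep], wts[keep]
    if vals.size == 0:
        return float("nan")
    order = np.argsort(vals, kind="stable")
    vals, wts = vals[order], wts[order]
    cum = np.cumsum(wts)
    total = cum[-1]
    threshold = (q / 100.0) * total - _CUM_RTOL * total
    return float(vals[np.searchsorted(cum, threshold, side="left")])
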