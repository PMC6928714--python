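"""Engineered per-epoch features from the bradykinesia/tremor epoch stream.

The candidate features are 30-min (15-epoch) moving percentiles of BKS — plain
and linearly weighted — the moving median of tremor amplitude, and the
log10(1 + x) transform of the weighted moving tremor median that brings tremor
onto the same logarithmic scaling as BKS.  The refined predictor set used by
the severity model is BKS_M10P, BKS_M25P and TA_WM50P_Log.

Also here: the smoothed weekly BKS series, the across-day median of usable BKS
aligned on each day's first-dose acknowledgement, lightly smoothed; its trough
in the post-dose search window defines the effect time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._percentiles import sliding_weighted_percentile, triangular_weights
from .epoch_store import EPOCH_MINUTES, Recording

#: Default feature window: 15 epochs = 30 minutes.
FEATURE_WINDOW_EPOCHS = 15

#: BKS percentile grid used by the candidate feature set.
BKS_PERCENTILES = (10, 25, 50, 75, 90)

#: All candidate feature columns, named as in the field's convention
#: (M = moving, WM = weighted moving, trailing number = percentile).
FEATURE_COLUMNS = (
    ["BK"]
    + [f"BKS_M{q}P" for q in BKS_PERCENTILES]
    + [f"BKS_WM{q}P" for q in BKS_PERCENTILES]
    + ["TA_M50P", "TA_WM50P", "TA_WM50P_Log"]
)

#: The refined predictor set feeding the severity classifiers.
SELECTED_FEATURES = ("BKS_M10P", "BKS_M25P", "TA_WM50P_Log")


def moving_percentile(
    series: np.ndarray, window_epochs: int = FEATURE_WINDOW_EPOCHS, q: float = 50.0
) -> np.ndarray:
    """Nearest-rank percentile of usable values in a centered window.

    ``series`` uses NaN for unusable (inactive / off-wrist) epochs; windows
    shrink at edges and around exclusions, and an all-unusable window yields
    NaN.
    """
    return sliding_weighted_percentile(series, window_epochs, q, weights=None)


def weighted_moving_percentile(
    series: np.ndarray,
    window_epochs: int = FEATURE_WINDOW_EPOCHS,
    q: float = 50.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Triangular-kernel weighted moving percentile (see `_percentiles`).

    The kernel is maximal at the window center and declines linearly and
    symmetrically toward zero; substituting uniform weights reproduces
    :func:`moving_percentile` exactly.
    """
    if weights is None:
        weights = triangular_weights(window_epochs)
    return sliding_weighted_percentile(series, window_epochs, q, weights)


def log_tremor(ta: float | np.ndarray) -> float | np.ndarray:
    """log10(1 + tremor amplitude); the +1 keeps the feature finite and
    non-negative for tremor-free (zero-amplitude) epochs."""
    arr = np.asarray(ta, dtype=float)
    if np.any(arr < 0):
        raise ValueError("tremor amplitude must be >= 0")
    out = np.log10(1.0 + arr)
    return float(out) if np.isscalar(ta) else out


@dataclass
class WeeklySeries:
    """Across-day median BKS aligned on first-dose acknowledgements.

    ``offsets`` are minutes relative to the acknowledgement epoch start on the
    2-min grid; ``values`` are smoothed BKS (NaN where no day contributes);
    ``n_days_contributing`` counts days with a usable epoch at each offset.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_days_contributing: np.ndarray

    def window(self, start: float, end: float) -> "WeeklySeries":
        keep = (self.offsets >= start) & (self.offsets <= end)
        return WeeklySeries(
            self.offsets[keep], self.values[keep], self.n_days_contributing[keep]
        )


class EmptySeriesError(ValueError):
    """No acknowledged first dose (or no alignment time) to build the series."""


def smoothed_weekly_series(
    recording: Recording,
    activity: np.ndarray,
    align_times: list[float] | None = None,
    offset_range: tuple[int, int] = (-240, 480),
    smooth_window: int = 5,
) -> WeeklySeries:
    """Dose-aligned weekly BKS profile.

    For each grid offset, take the median across days of the usable BKS at
    (alignment + offset), then smooth with a centered ``smooth_window``-point
    moving average (1 disables smoothing).  ``align_times`` defaults to the
    acknowledgement times of the first-of-day doses.
    """
    if align_times is None:
        align_times = [
            e.acknowledgement_min for e in recording.first_of_day_events()
        ]
    if not align_times:
        raise EmptySeriesError(
            f"{recording.subject_id}: no acknowledged first-of-day dose"
        )
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")

    bks = recording.epochs["bks"].to_numpy(dtype=float).copy()
    bks[np.asarray(activity) != "active"] = np.nan
    ts = recording.epochs["timestamp_min"].to_numpy()
    t0, t_end = int(ts[0]), int(ts[-1])

    offsets = np.arange(offset_range[0], offset_range[1] + 1, EPOCH_MINUTES)
    stacked = np.full((len(align_times), offsets.size), np.nan)
    for d, ack in enumerate(align_times):
        anchor = (int(ack) // EPOCH_MINUTES) * EPOCH_MINUTES
        times = anchor + offsets
        valid = (times >= t0) & (times <= t_end)
        idx = (times[valid] - t0) // EPOCH_MINUTES
        stacked[d, valid] = bks[idx]

    n_days = np.sum(~np.isnan(stacked), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        median = np.nanmedian(stacked, axis=0)

        if smooth_window == 1:
            smoothed = median
        else:
            half = smooth_window // 2
            padded = np.concatenate(
                [np.full(half, np.nan), median, np.full(half, np.nan)]
            )
            win = np.lib.stride_tricks.sliding_window_view(padded, smooth_window)
            smoothed = np.nanmean(win, axis=1)
            smoothed[n_days == 0] = np.nan
    return WeeklySeries(offsets, smoothed, n_days)


def featurize(
    recording: Recording,
    activity: np.ndarray,
    window_epochs: int = FEATURE_WINDOW_EPOCHS,
) -> pd.DataFrame:
    """Compute the full candidate feature table for a recording.

    Returns one row per epoch with a ``usable`` flag (active epochs only feed
    the model); moving statistics are computed from usable neighbors only, so
    off-wrist and inactive epochs never influence any feature value.
    """
    activity = np.asarray(activity)
    usable = activity == "active"
    bks = recording.epochs["bks"].to_numpy(dtype=float).copy()
    ta = recording.epochs["tremor_amplitude"].to_numpy(dtype=float).copy()
    bks[~usable] = np.nan
    ta[~usable] = np.nan

    tri = triangular_weights(window_epochs)
    out = pd.DataFrame(
        {
            "subject_id": recording.subject_id,
            "timestamp_min": recording.epochs["timestamp_min"].to_numpy(),
            "usable": usable,
            "BK": bks,
        }
    )
    for q in BKS_PERCENTILES:
        out[f"BKS_M{q}P"] = sliding_weighted_percentile(bks, window_epochs, q)
        out[f"BKS_WM{q}P"] = sliding_weighted_percentile(bks, window_epochs, q, tri)
    out["TA_M50P"] = sliding_weighted_percentile(ta, window_epochs, 50.0)
    out["TA_WM50P"] = sliding_weighted_percentile(ta, window_epochs, 50.0, tri)
    with np.errstate(invalid="ignore"):
        out["TA_WM50P_Log"] = np.log10(1.0 + out["TA_WM50P"].to_numpy())
    return out
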