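"""Dose-time (DT) and effect-time (ET) windows and weekly aggregates.

DT is the 5 epochs (10 min) centered on the epoch containing the
acknowledgement of the first reminder of the day.  ET is located once per
recording as the trough — the point of peak levodopa effect, i.e. least
bradykinesia — of the smoothed weekly BKS series within the 46–90 min
post-acknowledgement search window, and the same offset is applied to every
day's acknowledgement.  Inactive and off-wrist epochs are removed from both
windows, so up to 5 epochs per day and 30 per 6-day week are pooled into the
weekly aggregate mean and standard deviation of each feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epoch_store import EPOCH_MINUTES, DoseEvent, Recording
from .features import WeeklySeries, smoothed_weekly_series

#: Epochs per dose window (10 minutes).
DT_WINDOW_EPOCHS = 5
#: Default ET search window, minutes after the acknowledgement.
ET_SEARCH_MIN = 46
ET_SEARCH_MAX = 90


class WindowError(ValueError):
    """A dose window could not be formed (out of span / no usable series)."""


@dataclass
class WindowSummary:
    """Weekly aggregate over one kind of dose window (DT or ET)."""

    kind: str
    per_day_epochs: list[list[int]]  # usable epoch timestamps per day
    weekly_mean: pd.Series
    weekly_sd: pd.Series
    n_epochs_total: int
    et_latency: float | None = None  # minutes; ET windows only


def _centered_candidates(anchor_min: float, n_epochs: int = DT_WINDOW_EPOCHS) -> np.ndarray:
    """Timestamps of the ``n_epochs`` grid epochs centered on the epoch
    containing ``anchor_min``."""
    start = (int(anchor_min) // EPOCH_MINUTES) * EPOCH_MINUTES
    half = n_epochs // 2
    return start + EPOCH_MINUTES * np.arange(-half, half + 1)


def _usable_in(recording: Recording, activity: np.ndarray, candidates: np.ndarray) -> list[int]:
    ts = recording.epochs["timestamp_min"].to_numpy()
    t0, t_end = int(ts[0]), int(ts[-1])
    out = []
    for t in candidates:
        if t < t0 or t > t_end:
            continue
        idx = (t - t0) // EPOCH_MINUTES
        if activity[idx] == "active":
            out.append(int(t))
    return out


def extract_dt(
    recording: Recording,
    dose: DoseEvent,
    activity: np.ndarray,
    n_epochs: int = DT_WINDOW_EPOCHS,
) -> list[int]:
    """Usable epoch timestamps of the day's DT window (possibly empty).

    An empty result marks the day's DT unavailable; an acknowledgement outside
    the recording span is an error.
    """
    if dose.acknowledgement_min is None:
        raise WindowError("dose has no acknowledgement")
    t0, t_end = recording.span_min
    if not (t0 <= dose.acknowledgement_min < t_end):
        raise WindowError(
            f"acknowledgement at {dose.acknowledgement_min} min is outside the recording"
        )
    candidates = _centered_candidates(dose.acknowledgement_min, n_epochs)
    return _usable_in(recording, activity, candidates)


def find_et(
    recording: Recording,
    activity: np.ndarray,
    weekly: WeeklySeries | None = None,
    align_times: list[float] | None = None,
    search_start: float = ET_SEARCH_MIN,
    search_end: float = ET_SEARCH_MAX,
    n_epochs: int = DT_WINDOW_EPOCHS,
) -> tuple[int, list[list[int]]]:
    """Locate the effect time and its per-day usable windows.

    Returns ``(et_offset, per_day_windows)`` where ``et_offset`` is the grid
    offset (minutes after the acknowledgement epoch) of the minimum of the
    smoothed weekly BKS series within the closed search window — earliest
    offset on ties — and ``per_day_windows`` lists the usable epoch
    timestamps of the 5-epoch window centered at each day's acknowledgement
    plus that offset.
    """
    if align_times is None:
        align_times = [e.acknowledgement_min for e in recording.first_of_day_events()]
    if weekly is None:
        weekly = smoothed_weekly_series(recording, activity, align_times=align_times)
    sub = weekly.window(search_start, search_end)
    if sub.offsets.size == 0 or np.all(np.isnan(sub.values)):
        raise WindowError("smoothed weekly series has no data in the ET search window")
    et_offset = int(sub.offsets[np.nanargmin(sub.values)])

    windows = []
    for ack in align_times:
        anchor = (int(ack) // EPOCH_MINUTES) * EPOCH_MINUTES
        candidates = _centered_candidates(anchor + et_offset, n_epochs)
        windows.append(_usable_in(recording, activity, candidates))
    return et_offset, windows


def weekly_aggregate(
    per_day_windows: list[list[int]],
    feature_table: pd.DataFrame,
    feature_cols: list[str],
    kind: str,
    et_latency: float | None = None,
) -> WindowSummary:
    """Pool the usable window epochs of all days and aggregate each feature.

    Mean and sample SD (n-1 denominator; SD is 0 for a single epoch pool of
    identical values and NaN for a pool of one) over the pooled epochs.
    """
    pooled = sorted(t for day in per_day_windows for t in day)
    if not pooled:
        raise WindowError(f"{kind}: no usable epochs to aggregate")
    rows = feature_table.set_index("timestamp_min").loc[pooled, feature_cols]
    return WindowSummary(
        kind=kind,
        per_day_epochs=[sorted(day) for day in per_day_windows],
        weekly_mean=rows.mean(),
        weekly_sd=rows.std(ddof=1),
        n_epochs_total=len(pooled),
        et_latency=et_latency,
    )
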