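"""Data model and I/O for wrist-sensor epoch streams, dose events and clinical labels.

The wearable logger produces one bradykinesia score (BKS) and one tremor
amplitude per 2-minute epoch while worn; an off-wrist epoch is unavailable for
analysis.  A recording spans several days (typically six) on a regular epoch
grid aligned to midnight, with timestamps expressed in minutes since the start
of the recording and each epoch covering the half-open interval [t, t+2).

Activity labeling follows the device convention: an epoch whose linearly
weighted moving median of BKS exceeds 40 is attributed to inactivity or sleep
and excluded from analysis; off-wrist epochs are excluded outright; everything
else is active.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._percentiles import sliding_weighted_percentile, triangular_weights

GROUPS = ("PwP", "control")
SCALE_VERSIONS = ("UPDRS", "MDS-UPDRS")

#: Minutes per epoch on the device grid.
EPOCH_MINUTES = 2
#: Minutes per calendar day; day boundaries sit at multiples of this.
DAY_MINUTES = 1440

#: Default inactivity rule: weighted moving median of BKS above this is
#: inactivity/sleep.
INACTIVE_BKS_THRESHOLD = 40.0
#: Default window (epochs) for the activity moving median; 30 min, matching
#: the feature windows.
ACTIVITY_WINDOW_EPOCHS = 15

EPOCH_CSV_COLUMNS = [
    "subject_id",
    "group",
    "timestamp_min",
    "bks",
    "tremor_amplitude",
    "off_wrist",
]

CLINICAL_CSV_COLUMNS = [
    "subject_id",
    "updrs_off_raw",
    "updrs_on_raw",
    "scale_version",
    "disease_duration_years",
    "first_dose_led_mg",
]


class SchemaError(ValueError):
    """Malformed input file (missing columns, bad rows)."""


@dataclass(frozen=True)
class DoseEvent:
    """A medication reminder and its (optional) acknowledgement, in minutes
    since recording start."""

    reminder_min: float
    acknowledgement_min: float | None
    first_of_day: bool = False

    def __post_init__(self) -> None:
        if (
            self.acknowledgement_min is not None
            and self.acknowledgement_min < self.reminder_min
        ):
            raise ValueError(
                "acknowledgement_min must be >= reminder_min "
                f"({self.acknowledgement_min} < {self.reminder_min})"
            )


@dataclass(frozen=True)
class ClinicalLabels:
    """Per-subject clinic-visit labels (raw, unadjusted scale totals)."""

    updrs_off_raw: float
    updrs_on_raw: float
    scale_version: str
    disease_duration_years: float | None = None
    first_dose_led_mg: float | None = None

    def __post_init__(self) -> None:
        if self.scale_version not in SCALE_VERSIONS:
            raise ValueError(f"unknown scale_version {self.scale_version!r}")
        if self.updrs_off_raw < 0 or self.updrs_on_raw < 0:
            raise ValueError("UPDRS III totals must be non-negative")


@dataclass
class Recording:
    """One subject's epoch stream plus dose events and optional clinical labels.

    ``epochs`` holds one row per epoch with columns ``timestamp_min`` (int,
    strictly increasing on the 2-min grid), ``bks``, ``tremor_amplitude``
    (>= 0; zero means no tremor) and ``off_wrist`` (bool).
    """

    subject_id: str
    group: str
    epochs: pd.DataFrame
    dose_events: list[DoseEvent] = field(default_factory=list)
    clinical: ClinicalLabels | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        ts = self.epochs["timestamp_min"].to_numpy()
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError(f"{self.subject_id}: timestamps not strictly increasing")
        ta = self.epochs["tremor_amplitude"].to_numpy(dtype=float)
        if np.any(ta < 0):
            raise ValueError(f"{self.subject_id}: tremor_amplitude must be >= 0")
        first_days = [
            int(d.reminder_min // DAY_MINUTES)
            for d in self.dose_events
            if d.first_of_day
        ]
        if len(first_days) != len(set(first_days)):
            raise ValueError(
                f"{self.subject_id}: more than one first-of-day dose on a calendar day"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def span_min(self) -> tuple[int, int]:
        ts = self.epochs["timestamp_min"]
        return int(ts.iloc[0]), int(ts.iloc[-1]) + EPOCH_MINUTES

    def first_of_day_events(self) -> list[DoseEvent]:
        """Acknowledged first-of-day doses in chronological order."""
        events = [
            d
            for d in self.dose_events
            if d.first_of_day and d.acknowledgement_min is not None
        ]
        return sorted(events, key=lambda d: d.reminder_min)

    def epoch_index_of(self, minute: float) -> int | None:
        """Positional index of the epoch whose [t, t+2) interval contains
        ``minute``, or None if outside the recording."""
        ts = self.epochs["timestamp_min"].to_numpy()
        start = (int(minute) // EPOCH_MINUTES) * EPOCH_MINUTES
        idx = np.searchsorted(ts, start)
        if idx < len(ts) and ts[idx] == start:
            return int(idx)
        return None


def label_activity(
    recording: Recording,
    window_epochs: int = ACTIVITY_WINDOW_EPOCHS,
    inactive_threshold: float = INACTIVE_BKS_THRESHOLD,
) -> np.ndarray:
    """Label each epoch ``active``, ``inactive`` or ``off_wrist``.

    An epoch is inactive iff the linearly weighted moving median of BKS over
    the centered window exceeds ``inactive_threshold``; off-wrist epochs are
    labeled off_wrist regardless of BKS and never contribute to the median.
    """
    if window_epochs % 2 == 0:
        raise ValueError("window_epochs must be odd")
    if not np.isfinite(inactive_threshold):
        raise ValueError("inactive_threshold must be finite")
    bks = recording.epochs["bks"].to_numpy(dtype=float).copy()
    off = recording.epochs["off_wrist"].to_numpy(dtype=bool)
    bks[off] = np.nan
    wm_median = sliding_weighted_percentile(
        bks, window_epochs, 50.0, triangular_weights(window_epochs)
    )
    labels = np.full(len(bks), "active", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[wm_median > inactive_threshold] = "inactive"
    labels[off] = "off_wrist"
    return labels


# -- file I/O --------------------------------------------------------------


def write_epochs(
    recordings: list[Recording],
    epoch_csv: str | Path,
    dose_json: str | Path | None = None,
    clinical_csv: str | Path | None = None,
) -> None:
    """Write a cohort to the epoch CSV plus optional dose-event JSON and
    clinical CSV companions."""
    frames = []
    for rec in recordings:
        df = rec.epochs.copy()
        df.insert(0, "subject_id", rec.subject_id)
        df.insert(1, "group", rec.group)
        df["off_wrist"] = df["off_wrist"].astype(int)
        frames.append(df[EPOCH_CSV_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(epoch_csv, index=False)

    if dose_json is not None:
        doses = {
            rec.subject_id: [
                {
                    "reminder_min": d.reminder_min,
                    "acknowledgement_min": d.acknowledgement_min,
                    "first_of_day": d.first_of_day,
                }
                for d in rec.dose_events
            ]
            for rec in recordings
        }
        Path(dose_json).write_text(json.dumps(doses, indent=1, sort_keys=True))

    if clinical_csv is not None:
        rows = []
        for rec in recordings:
            if rec.clinical is None:
                continue
            c = rec.clinical
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "updrs_off_raw": c.updrs_off_raw,
                    "updrs_on_raw": c.updrs_on_raw,
                    "scale_version": c.scale_version,
                    "disease_duration_years": c.disease_duration_years,
                    "first_dose_led_mg": c.first_dose_led_mg,
                }
            )
        pd.DataFrame(rows, columns=CLINICAL_CSV_COLUMNS).to_csv(
            clinical_csv, index=False
        )


def read_epochs(
    epoch_csv: str | Path,
    dose_json: str | Path | None = None,
    clinical_csv: str | Path | None = None,
) -> list[Recording]:
    """Read a cohort written by :func:`write_epochs`.

    Raises :class:`SchemaError` naming the offending column or CSV row for
    malformed input; the write -> read round trip is the identity.
    """
    df = pd.read_csv(epoch_csv, float_precision="round_trip")
    missing = [c for c in EPOCH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"epoch CSV missing required columns: {missing}")

    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        row = int(df.index[bad_group][0]) + 2  # 1-based incl. header
        raise SchemaError(f"row {row}: unknown group {df.loc[bad_group].iloc[0]['group']!r}")
    bad_ta = df["tremor_amplitude"].astype(float) < 0
    if bad_ta.any():
        row = int(df.index[bad_ta][0]) + 2
        raise SchemaError(f"row {row}: tremor_amplitude must be >= 0")

    doses: dict = {}
    if dose_json is not None:
        doses = json.loads(Path(dose_json).read_text())
    clinical: dict[str, ClinicalLabels] = {}
    if clinical_csv is not None:
        cdf = pd.read_csv(clinical_csv, float_precision="round_trip")
        cmissing = [c for c in CLINICAL_CSV_COLUMNS if c not in cdf.columns]
        if cmissing:
            raise SchemaError(f"clinical CSV missing required columns: {cmissing}")
        for _, r in cdf.iterrows():
            clinical[str(r["subject_id"])] = ClinicalLabels(
                updrs_off_raw=float(r["updrs_off_raw"]),
                updrs_on_raw=float(r["updrs_on_raw"]),
                scale_version=str(r["scale_version"]),
                disease_duration_years=(
                    float(r["disease_duration_years"])
                    if pd.notna(r["disease_duration_years"])
                    else None
                ),
                first_dose_led_mg=(
                    float(r["first_dose_led_mg"])
                    if pd.notna(r["first_dose_led_mg"])
                    else None
                ),
            )

    recordings = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        ts = sub["timestamp_min"].to_numpy()
        if np.any(np.diff(ts) <= 0):
            raise SchemaError(f"subject {subject_id}: non-monotone timestamps")
        epochs = pd.DataFrame(
            {
                "timestamp_min": ts.astype(int),
                "bks": sub["bks"].to_numpy(dtype=float),
                "tremor_amplitude": sub["tremor_amplitude"].to_numpy(dtype=float),
                "off_wrist": sub["off_wrist"].to_numpy().astype(bool),
            }
        )
        events = [
            DoseEvent(
                reminder_min=float(d["reminder_min"]),
                acknowledgement_min=(
                    None
                    if d["acknowledgement_min"] is None
                    else float(d["acknowledgement_min"])
                ),
                first_of_day=bool(d["first_of_day"]),
            )
            for d in doses.get(str(subject_id), [])
        ]
        recordings.append(
            Recording(
                subject_id=str(subject_id),
                group=str(sub["group"].iloc[0]),
                epochs=epochs,
                dose_events=events,
                clinical=clinical.get(str(subject_id)),
            )
        )
    return recordings
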