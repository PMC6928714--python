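"""Per-subject levodopa-response estimation from a recording plus a trained
severity model, with the exclusion flags that sharpen the classification.

For each subject the per-epoch MFSL predictions over the pooled usable DT
epochs are averaged into MFSL_DT, likewise MFSL_ET at the effect time, and the
sensor-side levodopa response is abs-delta = MFSL_DT - MFSL_ET with
%-delta = abs-delta / MFSL_DT x 100.  Controls are processed with a nominal
dose time (10:00 for response estimation) and UPDRS III fixed at 0.

Three exclusion heuristics flag subjects whose comparison with the clinical
levodopa challenge test is unreliable:

* uncertain — the clinical improvement falls in the 11–14 point zone between
  a clearly insignificant (<= 10) and clearly meaningful (> 14) response;
* already ON — morning severity is in the treated range (MFSL_DT < 3) yet the
  daytime severity estimate (mean + 1 SD of per-epoch MFSL from 46 min
  post-dose to 18:00) exceeds MFSL_DT by more than 1 level;
* variable — day-to-day variability in amplitude (SD of per-epoch MFSL > 1
  for both the DT and ET pools) or in latency to peak effect (SD of the
  per-day trough latencies above a configurable bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dose_windows, features
from .epoch_store import DAY_MINUTES, EPOCH_MINUTES, ClinicalLabels, Recording, label_activity
from .features import SELECTED_FEATURES
from .severity_model import SeverityModel, adjust_updrs

#: Nominal control dose-time clock minutes: 07:00 when building the model,
#: 10:00 when estimating the levodopa response.
CONTROL_DT_TRAIN_MIN = 420
CONTROL_DT_LDCT_MIN = 600


@dataclass(frozen=True)
class UncertainZone:
    """Clinically uncertain UPDRS III improvement band (inclusive)."""

    lower: float = 11.0
    upper: float = 14.0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")


@dataclass(frozen=True)
class LdctConfig:
    """Window and flag parameters of the response pipeline."""

    dt_epochs: int = dose_windows.DT_WINDOW_EPOCHS
    et_search: tuple[float, float] = (dose_windows.ET_SEARCH_MIN, dose_windows.ET_SEARCH_MAX)
    feature_window_epochs: int = features.FEATURE_WINDOW_EPOCHS
    activity_window_epochs: int = 15
    inactive_threshold: float = 40.0
    smooth_window: int = 5
    uncertain_zone: UncertainZone = UncertainZone()
    control_dt_min: int = CONTROL_DT_LDCT_MIN
    daytime_start_after_dose_min: float = 46.0
    daytime_end_min: float = 1080.0  # 18:00, resolved against each day's midnight
    already_on_gate_level: float = 3.0
    already_on_margin: float = 1.0
    latency_sd_threshold_min: float = 11.0  # quarter of the ET search window


@dataclass
class LdctResult:
    """Per-subject sensor-side levodopa response and exclusion flags."""

    subject_id: str
    group: str
    mfsl_dt: float | None = None
    mfsl_et: float | None = None
    abs_delta_pkg: float | None = None
    pct_delta_pkg: float | None = None
    flag_uncertain: bool | None = None
    flag_already_on: bool | None = None
    flag_variable_amplitude: bool | None = None
    flag_variable_latency: bool | None = None
    abs_delta_updrs: float | None = None
    pct_delta_updrs: float | None = None
    classification: str | None = None
    et_latency: float | None = None
    n_dt_epochs: int = 0
    n_et_epochs: int = 0
    reason: str | None = None


def estimate_mfsl_at(epoch_mfsl: np.ndarray) -> float:
    """Mean per-epoch MFSL over the pooled usable window epochs."""
    arr = np.asarray(epoch_mfsl, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no usable epochs with complete features")
    return float(arr.mean())


def compute_lr(mfsl_dt: float, mfsl_et: float) -> tuple[float, float | None]:
    """Sensor levodopa response: absolute and percent MFSL improvement.

    The percent response is undefined (None) when MFSL_DT is 0."""
    abs_delta = mfsl_dt - mfsl_et
    if mfsl_dt == 0:
        return abs_delta, None
    return abs_delta, 100.0 * abs_delta / mfsl_dt


def classify_lr(abs_delta_updrs: float, zone: UncertainZone = UncertainZone()) -> str:
    """Classify a clinical UPDRS III improvement: > upper is meaningful,
    within [lower, upper] uncertain, below lower insignificant."""
    if not np.isfinite(abs_delta_updrs):
        raise ValueError("abs_delta_updrs must be finite")
    if abs_delta_updrs > zone.upper:
        return "meaningful"
    if abs_delta_updrs >= zone.lower:
        return "uncertain"
    return "insignificant"


def clinical_delta(labels: ClinicalLabels) -> tuple[float, float | None]:
    """Clinical levodopa response from the OFF/ON totals, on the adjusted
    (MDS-equivalent) scale; percent is undefined when the OFF total is 0."""
    off = adjust_updrs(labels.updrs_off_raw, labels.scale_version)
    on = adjust_updrs(labels.updrs_on_raw, labels.scale_version)
    abs_delta = off - on
    return abs_delta, (100.0 * abs_delta / off if off > 0 else None)


def _nominal_control_acks(recording: Recording, clock_min: float) -> list[float]:
    t0, t_end = recording.span_min
    first_day = t0 // DAY_MINUTES
    last_day = (t_end - 1) // DAY_MINUTES
    acks = [
        day * DAY_MINUTES + clock_min
        for day in range(first_day, last_day + 1)
    ]
    return [a for a in acks if t0 <= a < t_end]


def subject_windows(
    recording: Recording,
    config: LdctConfig = LdctConfig(),
    control_dt_min: float | None = None,
):
    """Shared per-subject preparation: activity labels, feature table,
    alignment times, DT windows, ET offset and windows.

    Returns a dict; raises the underlying window errors when DT anchoring is
    impossible (no acknowledged first dose for a PwP).
    """
    activity = label_activity(
        recording, config.activity_window_epochs, config.inactive_threshold
    )
    table = features.featurize(recording, activity, config.feature_window_epochs)
    if recording.group == "control":
        clock = config.control_dt_min if control_dt_min is None else control_dt_min
        align = _nominal_control_acks(recording, clock)
    else:
        align = [e.acknowledgement_min for e in recording.first_of_day_events()]
    if not align:
        raise dose_windows.WindowError(
            f"{recording.subject_id}: no acknowledged first-of-day dose"
        )
    weekly = features.smoothed_weekly_series(
        recording, activity, align_times=align, smooth_window=config.smooth_window
    )
    dt_windows = []
    for ack in align:
        candidates = dose_windows._centered_candidates(ack, config.dt_epochs)
        dt_windows.append(dose_windows._usable_in(recording, activity, candidates))
    et_offset, et_windows = dose_windows.find_et(
        recording,
        activity,
        weekly=weekly,
        align_times=align,
        search_start=config.et_search[0],
        search_end=config.et_search[1],
        n_epochs=config.dt_epochs,
    )
    return {
        "activity": activity,
        "features": table,
        "align_times": align,
        "weekly": weekly,
        "dt_windows": dt_windows,
        "et_offset": et_offset,
        "et_windows": et_windows,
    }


def _predict_at(model: SeverityModel, table: pd.DataFrame, timestamps: list[int]) -> np.ndarray:
    rows = table.set_index("timestamp_min").loc[timestamps]
    return model.predict_mfsl(rows.reset_index())


def flag_already_on(
    recording: Recording,
    model: SeverityModel,
    prep: dict,
    mfsl_dt: float,
    config: LdctConfig = LdctConfig(),
) -> bool | None:
    """Already-ON heuristic: morning severity in the treated range but the
    daytime estimate (pooled per-epoch MFSL mean + 1 SD, 46 min post-dose to
    18:00) more than 1 level worse."""
    if mfsl_dt >= config.already_on_gate_level:
        return False
    activity = prep["activity"]
    ts = recording.epochs["timestamp_min"].to_numpy()
    pool: list[int] = []
    for ack in prep["align_times"]:
        day_start = (int(ack) // DAY_MINUTES) * DAY_MINUTES
        lo = ack + config.daytime_start_after_dose_min
        hi = day_start + config.daytime_end_min
        mask = (ts >= lo) & (ts < hi) & (np.asarray(activity) == "active")
        pool.extend(int(t) for t in ts[mask])
    if not pool:
        return None
    preds = _predict_at(model, prep["features"], pool)
    preds = preds[np.isfinite(preds)]
    if preds.size == 0:
        return None
    sd = float(np.std(preds, ddof=1)) if preds.size > 1 else 0.0
    daytime = float(np.mean(preds)) + sd
    return bool(daytime > mfsl_dt + config.already_on_margin)


def _per_day_trough_latencies(
    recording: Recording, prep: dict, config: LdctConfig
) -> list[float]:
    latencies = []
    for ack in prep["align_times"]:
        try:
            day_series = features.smoothed_weekly_series(
                recording,
                prep["activity"],
                align_times=[ack],
                smooth_window=config.smooth_window,
            )
        except features.EmptySeriesError:
            continue
        sub = day_series.window(*config.et_search)
        if sub.offsets.size == 0 or np.all(np.isnan(sub.values)):
            continue
        latencies.append(float(sub.offsets[np.nanargmin(sub.values)]))
    return latencies


def flag_variability(
    recording: Recording,
    model: SeverityModel,
    prep: dict,
    config: LdctConfig = LdctConfig(),
) -> tuple[bool | None, bool | None]:
    """(variable_amplitude, variable_latency).

    Amplitude: SD of the per-epoch MFSL exceeds 1 level in *both* the pooled
    DT and pooled ET windows.  Latency: SD of the per-day trough latencies
    exceeds the configured bandwidth; undefined with fewer than 2 days.
    """
    dt_pool = [t for day in prep["dt_windows"] for t in day]
    et_pool = [t for day in prep["et_windows"] for t in day]
    amplitude: bool | None = None
    if len(dt_pool) >= 2 and len(et_pool) >= 2:
        sd_dt = float(np.nanstd(_predict_at(model, prep["features"], dt_pool), ddof=1))
        sd_et = float(np.nanstd(_predict_at(model, prep["features"], et_pool), ddof=1))
        amplitude = bool(sd_dt > 1.0 and sd_et > 1.0)
    latency: bool | None = None
    if recording.first_of_day_events():  # latency to peak is a dose property
        latencies = _per_day_trough_latencies(recording, prep, config)
        if len(latencies) >= 2:
            latency = bool(np.std(latencies, ddof=1) > config.latency_sd_threshold_min)
    return amplitude, latency


def run_ldct(
    recording: Recording,
    model: SeverityModel,
    config: LdctConfig = LdctConfig(),
) -> LdctResult:
    """Complete per-subject result; a missing DT or ET yields a result with
    the response left missing and a reason code instead of an exception."""
    result = LdctResult(subject_id=recording.subject_id, group=recording.group)

    if recording.clinical is not None:
        result.abs_delta_updrs, result.pct_delta_updrs = clinical_delta(recording.clinical)
        result.classification = classify_lr(result.abs_delta_updrs, config.uncertain_zone)
        result.flag_uncertain = result.classification == "uncertain"

    try:
        prep = subject_windows(recording, config)
    except (dose_windows.WindowError, features.EmptySeriesError) as exc:
        result.reason = str(exc)
        return result

    dt_pool = [t for day in prep["dt_windows"] for t in day]
    et_pool = [t for day in prep["et_windows"] for t in day]
    result.n_dt_epochs = len(dt_pool)
    result.n_et_epochs = len(et_pool)
    result.et_latency = float(prep["et_offset"])
    if not dt_pool:
        result.reason = "DT unavailable"
        return result
    if not et_pool:
        result.reason = "ET unavailable"
        return result

    dt_preds = _predict_at(model, prep["features"], dt_pool)
    et_preds = _predict_at(model, prep["features"], et_pool)
    if not np.isfinite(dt_preds).any():
        result.reason = "DT unavailable"
        return result
    if not np.isfinite(et_preds).any():
        result.reason = "ET unavailable"
        return result
    result.mfsl_dt = estimate_mfsl_at(dt_preds)
    result.mfsl_et = estimate_mfsl_at(et_preds)
    result.abs_delta_pkg, result.pct_delta_pkg = compute_lr(result.mfsl_dt, result.mfsl_et)

    result.flag_already_on = flag_already_on(recording, model, prep, result.mfsl_dt, config)
    result.flag_variable_amplitude, result.flag_variable_latency = flag_variability(
        recording, model, prep, config
    )
    return result


def run_cohort(
    recordings: list[Recording],
    model: SeverityModel,
    config: LdctConfig = LdctConfig(),
) -> pd.DataFrame:
    """Per-subject results table for a cohort (one row per subject)."""
    rows = []
    for rec in recordings:
        r = run_ldct(rec, model, config)
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "mfsl_dt": r.mfsl_dt,
                "mfsl_et": r.mfsl_et,
                "abs_delta_pkg": r.abs_delta_pkg,
                "pct_delta_pkg": r.pct_delta_pkg,
                "abs_delta_updrs": r.abs_delta_updrs,
                "pct_delta_updrs": r.pct_delta_updrs,
                "classification": r.classification,
                "flag_uncertain": r.flag_uncertain,
                "flag_already_on": r.flag_already_on,
                "flag_variable_amplitude": r.flag_variable_amplitude,
                "flag_variable_latency": r.flag_variable_latency,
                "et_latency": r.et_latency,
                "n_dt_epochs": r.n_dt_epochs,
                "n_et_epochs": r.n_et_epochs,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def collect_window_samples(
    recordings: list[Recording],
    config: LdctConfig = LdctConfig(),
    control_dt_min: float = CONTROL_DT_TRAIN_MIN,
    feature_cols: tuple[str, ...] = SELECTED_FEATURES,
) -> pd.DataFrame:
    """Epoch-level training samples: one row per usable DT/ET window epoch.

    DT epochs carry the subject's adjusted UPDRS_OFF, ET epochs the adjusted
    UPDRS_ON; control epochs (nominal 07:00 dose time) carry 0.  Subjects
    whose DT or ET cannot be formed are skipped.
    """
    rows = []
    for rec in recordings:
        try:
            prep = subject_windows(rec, config, control_dt_min=control_dt_min)
        except (dose_windows.WindowError, features.EmptySeriesError):
            continue
        if rec.group == "control":
            updrs_dt = updrs_et = 0.0
        else:
            if rec.clinical is None:
                continue
            updrs_dt = adjust_updrs(rec.clinical.updrs_off_raw, rec.clinical.scale_version)
            updrs_et = adjust_updrs(rec.clinical.updrs_on_raw, rec.clinical.scale_version)
        table = prep["features"].set_index("timestamp_min")
        for kind, windows, updrs in (
            ("DT", prep["dt_windows"], updrs_dt),
            ("ET", prep["et_windows"], updrs_et),
        ):
            pooled = [t for day in windows for t in day]
            if not pooled:
                continue
            feats = table.loc[pooled, list(feature_cols)]
            for t, (_, feat) in zip(pooled, feats.iterrows()):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "kind": kind,
                        "timestamp_min": t,
                        "updrs": updrs,
                        "et_offset": prep["et_offset"],
                        **feat.to_dict(),
                    }
                )
    return pd.DataFrame(rows)
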