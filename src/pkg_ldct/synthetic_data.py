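"""Synthetic wrist-sensor cohorts with known ground truth.

The proprietary clinical recordings behind this kind of study cannot be
redistributed, so every downstream stage is exercised on simulated cohorts
that emulate their salient structure: 6-day recordings at 2-min resolution;
a bradykinesia score (BKS) that rises linearly with untreated UPDRS III
severity and dips after the first morning levodopa dose, with the trough at a
per-day latency drawn from a truncated normal over the 46–90 min effect-time
search support; bout-like sleep and daytime inactivity with high BKS;
off-wrist gaps; tremor-amplitude bursts; day-to-day variability in response
amplitude and latency; control subjects with low flat BKS and no doses; and
"already ON" subjects whose morning severity sits at their treated level
while their untreated severity reappears later in the day.

All timestamps live on a regular 2-min grid aligned to midnight.  Identical
(config, seed) pairs produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epoch_store import DAY_MINUTES, ClinicalLabels, DoseEvent, Recording


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Cohort sizes, clinical score distributions, the first-dose size, the
    already-ON fraction and the response-latency distribution follow the
    published cohort (151 PwP / 174 controls; UPDRS_OFF 48 +- 13; improvement
    22 +- 11 points; first dose 164 +- 79 mg; 19% already ON; time to peak
    45 +- 19 min truncated to the 46-90 min search support).  The BKS link,
    noise and bout parameters are free choices documented in the methods note.
    """

    n_pwp: int = 151
    n_controls: int = 174
    n_days: int = 6
    epoch_minutes: int = 2
    seed: int = 0
    # monotone UPDRS -> BKS link with additive Gaussian noise
    bks_link_slope: float = 0.4
    bks_link_intercept: float = 4.0
    noise_sd: float = 4.0
    subject_offset_sd: float = 1.5
    # epoch exclusion processes
    inactivity_rate: float = 0.15
    offwrist_rate: float = 0.05
    inactivity_mean_bout_epochs: float = 10.0
    offwrist_mean_bout_epochs: float = 15.0
    # clinical truth distributions
    updrs_off_mean: float = 48.0
    updrs_off_sd: float = 13.0
    delta_mean: float = 22.0
    delta_sd: float = 11.0
    first_dose_mean_mg: float = 164.0
    first_dose_sd_mg: float = 79.0
    # dose response
    frac_already_on: float = 0.19
    latency_mean: float = 45.0
    latency_sd: float = 19.0
    latency_support: tuple[float, float] = (46.0, 90.0)
    latency_day_sd: float = 6.0
    amplitude_cv: float = 0.25
    day_baseline_sd: float = 2.0  # BKS units; day-to-day baseline fluctuation
    frac_high_variability: float = 0.15
    variability_multiplier: float = 3.0
    effect_width_min: float = 22.0
    # daily structure (clock minutes)
    wake_mean_min: float = 390.0  # 06:30
    wake_sd_min: float = 20.0
    sleep_start_min: float = 1380.0  # 23:00
    sleep_bks_mean: float = 55.0
    sleep_bks_sd: float = 5.0
    # tremor bursts
    tremor_prevalence: float = 0.6
    tremor_occupancy: float = 0.25
    tremor_mean_bout_epochs: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_pwp", "n_controls"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.epoch_minutes <= 0:
            raise ConfigurationError("epoch_minutes must be positive")
        for name in (
            "inactivity_rate",
            "offwrist_rate",
            "frac_already_on",
            "frac_high_variability",
            "tremor_prevalence",
            "tremor_occupancy",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.latency_support
        if not lo < hi:
            raise ConfigurationError("latency_support must be an increasing pair")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth behind one simulated recording."""

    subject_id: str
    group: str
    updrs_off: float
    updrs_on: float
    disease_duration: float
    response_latency_mean: float
    response_latency_sd: float
    response_amplitude_cv: float
    already_on: bool
    first_dose_mg: float


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int | None = None,
):
    """Truncated-normal draw(s); parameters are of the parent normal."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def bout_mask(
    rng: np.random.Generator,
    n: int,
    allowed: np.ndarray,
    occupancy: float,
    mean_bout_epochs: float,
) -> np.ndarray:
    """Two-state Markov bout process with the given stationary occupancy and
    geometric bout lengths, restricted to ``allowed`` epochs.

    Sleep is bout-like rather than i.i.d., and the inactivity detector uses a
    moving median, so exclusion processes must be contiguous to be detected.
    """
    if occupancy <= 0:
        return np.zeros(n, dtype=bool)
    p_exit = 1.0 / mean_bout_epochs
    p_enter = min(1.0, occupancy * p_exit / max(1e-12, 1.0 - occupancy))
    mask = np.zeros(n, dtype=bool)
    state = rng.random() < occupancy
    u = rng.random(n)
    for i in range(n):
        if not allowed[i]:
            state = False
            continue
        if u[i] < (p_exit if state else p_enter):
            state = not state
        mask[i] = state
    return mask


def _ramp(tod: np.ndarray, start: float, end: float) -> np.ndarray:
    """0 before ``start``, 1 after ``end``, linear in between."""
    return np.clip((tod - start) / (end - start), 0.0, 1.0)


def _simulate_recording(
    config: SimulationConfig, rng: np.random.Generator, truth: SubjectTruth
) -> Recording:
    step = config.epoch_minutes
    n = config.n_days * DAY_MINUTES // step
    ts = np.arange(n) * step
    tod = ts % DAY_MINUTES
    day = ts // DAY_MINUTES

    wake = np.clip(
        rng.normal(config.wake_mean_min, config.wake_sd_min, config.n_days), 300, 540
    )
    wake = (wake // step) * step
    asleep = (tod < wake[day]) | (tod >= config.sleep_start_min)

    # untreated-state severity trajectory (UPDRS III units)
    if truth.group == "control":
        base = np.zeros(n)
    elif truth.already_on:
        # treated in the morning, usual severity re-emerging by early afternoon
        base = truth.updrs_on + (truth.updrs_off - truth.updrs_on) * _ramp(
            tod, 660.0, 780.0
        )
    else:
        base = np.full(n, truth.updrs_off)

    dose_events: list[DoseEvent] = []
    effect = np.zeros(n)
    if truth.group == "PwP":
        lo, hi = config.latency_support
        for d in range(config.n_days):
            day_start = d * DAY_MINUTES
            reminder = day_start + wake[d] + 30.0
            ack = reminder + rng.uniform(0.0, 6.0)
            dose_events.append(
                DoseEvent(
                    reminder_min=float(reminder),
                    acknowledgement_min=float(ack),
                    first_of_day=True,
                )
            )
            latency = float(
                truncated_normal(
                    rng, truth.response_latency_mean, truth.response_latency_sd, lo, hi
                )
            )
            day_amp = float(
                np.clip(rng.normal(1.0, truth.response_amplitude_cv), 0.1, 2.0)
            )
            sev_at_ack = base[min(int(ack // step), n - 1)]
            amplitude = max(sev_at_ack - truth.updrs_on, 0.0) * day_amp
            tau = ts - ack
            in_day = (tau > -30) & (tau < 360)
            effect[in_day] += amplitude * np.exp(
                -((tau[in_day] - latency) ** 2) / (2.0 * config.effect_width_min**2)
            )

    severity = np.clip(base - effect, 0.0, None)
    bks = (
        config.bks_link_intercept
        + config.bks_link_slope * severity
        + rng.normal(0.0, config.noise_sd, n)
    )
    # per-subject measurement idiosyncrasy
    bks += rng.normal(0.0, config.subject_offset_sd)
    if truth.group == "PwP":
        # day-to-day baseline fluctuation, amplified in high-variability
        # subjects (multiplier inferred from the subject's latency SD)
        mult = truth.response_latency_sd / config.latency_day_sd if config.latency_day_sd else 1.0
        day_offsets = rng.normal(0.0, config.day_baseline_sd * mult, config.n_days)
        bks += day_offsets[day]

    # sleep and daytime inactivity bouts present as high, sleep-like BKS
    inactive = bout_mask(
        rng, n, ~asleep, config.inactivity_rate, config.inactivity_mean_bout_epochs
    )
    rest = asleep | inactive
    bks[rest] = rng.normal(config.sleep_bks_mean, config.sleep_bks_sd, int(rest.sum()))
    bks = np.clip(bks, 0.0, None)

    off_wrist = bout_mask(
        rng, n, np.ones(n, dtype=bool), config.offwrist_rate, config.offwrist_mean_bout_epochs
    )

    ta = np.zeros(n)
    if truth.group == "PwP":
        tremulous = rng.random() < config.tremor_prevalence
        if tremulous:
            burst = bout_mask(
                rng, n, ~rest, config.tremor_occupancy, config.tremor_mean_bout_epochs
            )
            nb = int(burst.sum())
            if nb:
                scale = 0.3 + 0.02 * severity[burst]
                ta[burst] = np.exp(rng.normal(np.log(scale), 0.6, nb))

    epochs = pd.DataFrame(
        {
            "timestamp_min": ts.astype(int),
            "bks": bks,
            "tremor_amplitude": ta,
            "off_wrist": off_wrist,
        }
    )

    if truth.group == "PwP":
        scale_version = "UPDRS" if rng.random() < 2.0 / 3.0 else "MDS-UPDRS"
        if scale_version == "UPDRS":
            off_raw = max(truth.updrs_off - 7.0, 0.0)
            on_raw = max(truth.updrs_on - 7.0, 0.0)
        else:
            off_raw, on_raw = truth.updrs_off, truth.updrs_on
        clinical = ClinicalLabels(
            updrs_off_raw=off_raw,
            updrs_on_raw=on_raw,
            scale_version=scale_version,
            disease_duration_years=truth.disease_duration,
            first_dose_led_mg=truth.first_dose_mg,
        )
    else:
        clinical = ClinicalLabels(
            updrs_off_raw=0.0,
            updrs_on_raw=0.0,
            scale_version="MDS-UPDRS",
            disease_duration_years=None,
            first_dose_led_mg=None,
        )

    return Recording(
        subject_id=truth.subject_id,
        group=truth.group,
        epochs=epochs,
        dose_events=dose_events,
        clinical=clinical,
    )


def _draw_pwp_truth(config: SimulationConfig, rng: np.random.Generator, idx: int) -> SubjectTruth:
    lo, hi = config.latency_support
    updrs_off = float(
        np.clip(rng.normal(config.updrs_off_mean, config.updrs_off_sd), 20.0, 80.0)
    )
    delta = float(np.clip(rng.normal(config.delta_mean, config.delta_sd), 4.0, updrs_off - 2.0))
    updrs_on = updrs_off - delta
    # already ON requires the treated-range mechanism: morning severity below
    # the level-3 gate, i.e. an ON score under 35
    already_on = (rng.random() < config.frac_already_on) and (updrs_on < 35.0)
    high_var = rng.random() < config.frac_high_variability
    mult = config.variability_multiplier if high_var else 1.0
    return SubjectTruth(
        subject_id=f"pwp{idx:04d}",
        group="PwP",
        updrs_off=updrs_off,
        updrs_on=updrs_on,
        disease_duration=float(np.clip(rng.normal(10.0, 5.0), 1.0, 25.0)),
        response_latency_mean=float(
            truncated_normal(rng, config.latency_mean, config.latency_sd, lo, hi)
        ),
        response_latency_sd=config.latency_day_sd * mult,
        response_amplitude_cv=config.amplitude_cv * mult,
        already_on=bool(already_on),
        first_dose_mg=float(
            np.clip(
                rng.normal(config.first_dose_mean_mg, config.first_dose_sd_mg), 50.0, 400.0
            )
        ),
    )


def _control_truth(idx: int) -> SubjectTruth:
    return SubjectTruth(
        subject_id=f"ctl{idx:04d}",
        group="control",
        updrs_off=0.0,
        updrs_on=0.0,
        disease_duration=0.0,
        response_latency_mean=0.0,
        response_latency_sd=0.0,
        response_amplitude_cv=0.0,
        already_on=False,
        first_dose_mg=0.0,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[Recording], list[SubjectTruth]]:
    """Generate one recording per subject plus the underlying truth.

    PwP recordings carry exactly one acknowledged first-of-day dose per day;
    controls carry none.  Reproducible bit-for-bit from (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    recordings, truths = [], []
    for i in range(config.n_pwp):
        truth = _draw_pwp_truth(config, rng, i)
        recordings.append(_simulate_recording(config, rng, truth))
        truths.append(truth)
    for i in range(config.n_controls):
        truth = _control_truth(i)
        recordings.append(_simulate_recording(config, rng, truth))
        truths.append(truth)
    return recordings, truths


def simulate_controls_day(config: SimulationConfig) -> Recording:
    """A single control recording (no dose events), spanning ``n_days`` so
    that the nominal dose-time clock epochs all exist on the grid."""
    rng = np.random.default_rng(config.seed)
    return _simulate_recording(config, rng, _control_truth(0))
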