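"""End-to-end orchestration: simulate -> featurize -> select -> train ->
predict -> evaluate, with deterministic seeding and a run manifest.

A single global seed fans out to per-stage child seeds via
``numpy.random.SeedSequence(seed).generate_state(...)`` (each reduced modulo
2**31), so stages reproduce identically whether run inside ``run_pipeline``
or standalone with the seeds recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, evaluation, feature_selection
from .epoch_store import Recording, read_epochs, write_epochs
from .features import FEATURE_COLUMNS, SELECTED_FEATURES
from .ldct_pipeline import (
    CONTROL_DT_TRAIN_MIN,
    LdctConfig,
    collect_window_samples,
    run_cohort,
)
from .severity_model import SeverityModel, SplitSpec, build_training_set, train
from .synthetic_data import SimulationConfig, SubjectTruth, simulate_cohort

logger = logging.getLogger(__name__)

#: Candidate features whose MI is tabulated (all engineered features).
MI_CANDIDATES = tuple(c for c in FEATURE_COLUMNS)
#: Refined candidate set entering the JMIM ranking.
JMIM_CANDIDATES = (
    "BKS_M10P",
    "BKS_M25P",
    "BKS_M50P",
    "BKS_WM75P",
    "BKS_M90P",
    "TA_WM50P_Log",
)


@dataclass
class RunConfig:
    """Everything a full deterministic run needs."""

    out_dir: Path
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    ldct: LdctConfig = field(default_factory=LdctConfig)
    model_family: str = "logistic"
    mi_neighbors: int = 6


def child_seeds(seed: int, n: int = 4) -> list[int]:
    """Documented fan-out of the global seed to per-stage child seeds."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


# -- stages ----------------------------------------------------------------


def stage_simulate(sim: SimulationConfig, out_dir: Path) -> tuple[list[Recording], list[SubjectTruth]]:
    recordings, truths = simulate_cohort(sim)
    write_epochs(
        recordings,
        out_dir / "epochs.csv",
        out_dir / "doses.json",
        out_dir / "clinical.csv",
    )
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(
        out_dir / "truth.csv", index=False
    )
    logger.info(
        "simulated %d recordings (%d PwP, %d controls)",
        len(recordings),
        sim.n_pwp,
        sim.n_controls,
    )
    return recordings, truths


def stage_windows(
    recordings: list[Recording],
    ldct: LdctConfig,
    out_dir: Path | None = None,
    control_dt_min: float = CONTROL_DT_TRAIN_MIN,
) -> pd.DataFrame:
    """Epoch-level window samples with all candidate features, plus the
    per-subject weekly window-summary CSV."""
    samples = collect_window_samples(
        recordings, ldct, control_dt_min=control_dt_min, feature_cols=MI_CANDIDATES
    )
    if out_dir is not None:
        samples.to_csv(out_dir / "window_samples.csv", index=False)
        summaries = []
        for (sid, kind), sub in samples.groupby(["subject_id", "kind"], sort=True):
            row = {
                "subject_id": sid,
                "kind": kind,
                "n_epochs_total": len(sub),
                "et_latency_min": float(sub["et_offset"].iloc[0]) if kind == "ET" else np.nan,
            }
            for col in MI_CANDIDATES:
                row[f"weekly_mean_{col}"] = sub[col].mean()
                row[f"weekly_sd_{col}"] = sub[col].std(ddof=1)
            summaries.append(row)
        pd.DataFrame(summaries).to_csv(out_dir / "window_summaries.csv", index=False)
    logger.info("collected %d window-epoch samples", len(samples))
    return samples


def stage_select(
    labeled: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    out_dir: Path | None = None,
) -> tuple[pd.DataFrame, feature_selection.JmimRanking]:
    """MI relevance table and JMIM ranking on the window-epoch samples.

    Classes with fewer than k+1 samples are set aside (logged) rather than
    aborting the run.
    """
    counts = labeled["mfsl"].value_counts()
    thin = counts[counts < k + 1].index.tolist()
    if thin:
        logger.warning("dropping thin classes %s from MI estimation", thin)
    usable = labeled[~labeled["mfsl"].isin(thin)].dropna(subset=list(MI_CANDIDATES))
    y = usable["mfsl"].to_numpy()

    mi_rows = [
        dataclasses.asdict(
            feature_selection.mi_continuous_discrete(
                usable[colname].to_numpy(), y, k, colname, seed
            )
        )
        for colname in MI_CANDIDATES
    ]
    mi_table = pd.DataFrame(mi_rows)
    ranking = feature_selection.jmim_rank(
        {c: usable[c].to_numpy() for c in JMIM_CANDIDATES}, y, k, seed
    )
    if out_dir is not None:
        mi_table.to_csv(out_dir / "mi_table.csv", index=False)
        pd.DataFrame(
            {"rank": range(1, len(ranking.order) + 1), "feature": ranking.order, "score": ranking.scores}
        ).to_csv(out_dir / "jmim_ranking.csv", index=False)
    logger.info("JMIM ranking: %s", " > ".join(ranking.order))
    return mi_table, ranking


def stage_train(
    labeled: pd.DataFrame,
    family: str,
    split: SplitSpec,
    out_dir: Path | None = None,
) -> SeverityModel:
    model = train(labeled, model_family=family, split=split, features=SELECTED_FEATURES)
    if out_dir is not None:
        model.save(out_dir / "model")
        model.training_report.to_csv(out_dir / "training_report.csv", index=False)
    logger.info(
        "trained %s family; held-out ROC AUC per classifier: %s",
        family,
        np.round(model.training_report["test_roc_auc"].to_numpy(), 3),
    )
    return model


def stage_predict(
    recordings: list[Recording],
    model: SeverityModel,
    ldct: LdctConfig,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    results = run_cohort(recordings, model, ldct)
    if out_dir is not None:
        results.to_csv(out_dir / "results.csv", index=False)
    n_missing = int(results["abs_delta_pkg"].isna().sum())
    logger.info("predicted %d subjects (%d without a usable response)", len(results), n_missing)
    return results


def stage_evaluate(
    results: pd.DataFrame, out_dir: Path | None = None
) -> dict[str, evaluation.ScenarioTable]:
    tables = {
        kind: evaluation.scenario_table(results, kind) for kind in ("abs", "pct")
    }
    if out_dir is not None:
        for kind, tab in tables.items():
            tab.to_csv(out_dir / f"scenario_{kind}.csv")
    for kind, tab in tables.items():
        logger.info("%s-score scenario ROC AUC: %s", kind, tab.table.loc["roc_auc"].round(3).to_dict())
    return tables


# -- full run --------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage into ``config.out_dir`` and write a manifest.

    Re-running with an identical config reproduces byte-identical CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed)
    sim = dataclasses.replace(config.simulation, seed=seeds[0])
    split = dataclasses.replace(config.split, seed=seeds[1])

    recordings, _truths = stage_simulate(sim, out)
    samples = stage_windows(recordings, config.ldct, out)
    labeled = build_training_set(samples)
    stage_select(labeled, k=config.mi_neighbors, seed=seeds[2], out_dir=out)
    model = stage_train(labeled, config.model_family, split, out)
    results = stage_predict(recordings, model, config.ldct, out)
    stage_evaluate(results, out)

    outputs = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "child_seeds": seeds,
        "model_family": config.model_family,
        "et_search_min": list(config.ldct.et_search),
        "config_sha256": hashlib.sha256(
            json.dumps(
                {
                    "simulation": dataclasses.asdict(sim),
                    "split": dataclasses.asdict(split),
                    "ldct": dataclasses.asdict(config.ldct),
                    "model_family": config.model_family,
                },
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %d outputs in %s", len(outputs), out)
    return manifest


def load_cohort(
    epoch_csv: str | Path,
    dose_json: str | Path | None = None,
    clinical_csv: str | Path | None = None,
) -> list[Recording]:
    """Thin re-export of :func:`pkg_ldct.epoch_store.read_epochs`."""
    return read_epochs(epoch_csv, dose_json, clinical_csv)
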