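"""ROC / PR evaluation of the sensor-derived levodopa response and the
exclusion-scenario tables.

Per-subject scores (abs-delta or %-delta of the sensor MFSL) are evaluated
against the binary clinical levodopa-response class: class 1 when the UPDRS
III improvement is clinically meaningful, class 0 when insignificant, with
control subjects augmenting class 0.  Subjects in the uncertain improvement
zone keep their intermediate scores in the "all" scenario (counted with class
1, since their improvement exceeds the insignificance bound) and drop out in
the uncertain-excluding scenarios.

PR AUC is the mean of the two one-vs-rest average precisions (class 1 scored
as-is, class 0 with negated scores), matching step-wise precision
integration; ROC AUC is the usual trapezoid, equal to the pairwise
concordance probability with ties counted one-half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

#: Exclusion scenarios in cumulative order.
SCENARIOS = (
    "all",
    "exclude_already_on",
    "exclude_uncertain",
    "exclude_on_and_uncertain",
    "exclude_on_uncertain_variable",
)


class UndefinedAUCError(ValueError):
    """AUC is undefined because only one class is present."""


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("both classes must be present")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (pairwise concordance with ties as 1/2)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Class-averaged precision-recall AUC (average precision of each class
    one-vs-rest, class 0 evaluated on negated scores)."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ap1 = average_precision_score(labels, scores)
    ap0 = average_precision_score(1 - labels, -scores)
    return float(0.5 * (ap1 + ap0))


@dataclass
class ScenarioTable:
    """AUCs and class supports per exclusion scenario (one column each)."""

    score_kind: str
    table: pd.DataFrame  # index: metric/support rows, columns: SCENARIOS

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _scenario_mask(results: pd.DataFrame, scenario: str) -> np.ndarray:
    keep = np.ones(len(results), dtype=bool)
    # unavailable flags (None/NaN) never exclude a subject
    on = results["flag_already_on"].eq(True).to_numpy()
    uncertain = (results["classification"] == "uncertain").to_numpy()
    variable = (
        results["flag_variable_amplitude"].eq(True).to_numpy()
        | results["flag_variable_latency"].eq(True).to_numpy()
    )
    if scenario in ("exclude_already_on", "exclude_on_and_uncertain", "exclude_on_uncertain_variable"):
        keep &= ~on
    if scenario in ("exclude_uncertain", "exclude_on_and_uncertain", "exclude_on_uncertain_variable"):
        keep &= ~uncertain
    if scenario == "exclude_on_uncertain_variable":
        keep &= ~variable
    return keep


def scenario_table(results: pd.DataFrame, score_kind: str = "abs") -> ScenarioTable:
    """Recompute ROC / PR AUC within each exclusion scenario's retained
    subjects and report per-class supports split by group.

    ``results`` is the per-subject results table produced by the pipeline
    (one row per subject with scores, classification and flags); rows with a
    missing score are dropped from every scenario.
    """
    if score_kind not in ("abs", "pct"):
        raise ValueError("score_kind must be 'abs' or 'pct'")
    col = "abs_delta_pkg" if score_kind == "abs" else "pct_delta_pkg"
    base = results.dropna(subset=[col]).reset_index(drop=True)

    rows = {}
    for scenario in SCENARIOS:
        keep = _scenario_mask(base, scenario)
        sub = base[keep]
        # class 1 = meaningful improvement; uncertain subjects (present only
        # in non-excluding scenarios) also exceed the insignificance bound.
        label = sub["classification"].isin(["meaningful", "uncertain"]).to_numpy(int)
        scores = sub[col].to_numpy(dtype=float)
        is_control = (sub["group"] == "control").to_numpy()
        cell = {
            "n": len(sub),
            "support_class1_pwp": int(((label == 1) & ~is_control).sum()),
            "support_class0_pwp": int(((label == 0) & ~is_control).sum()),
            "support_class0_controls": int(((label == 0) & is_control).sum()),
        }
        try:
            cell["roc_auc"] = roc_auc(scores, label)
            cell["pr_auc"] = pr_auc(scores, label)
        except UndefinedAUCError:
            cell["roc_auc"] = np.nan
            cell["pr_auc"] = np.nan
        rows[scenario] = cell

    table = pd.DataFrame(rows)[list(SCENARIOS)]
    return ScenarioTable(score_kind=score_kind, table=table)
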