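"""The 6-level motor-function severity model (MFSL) and its classifier bank.

UPDRS III totals (older-scale totals corrected by +7 points) are binned into
six ordinal motor function severity levels: level 0 below 10 points, then
12.5-point increments, with every score of 60 or more in level 5.  The
multi-class problem is decomposed into 5 binary threshold classifiers
("is the severity at or above level k?"); an epoch's MFSL estimate is the
number of classifiers voting above-threshold, an integer in [0, 5].

Training uses a subject-grouped split (no subject contributes samples to both
train and test) drawing ~30% of each binary class's samples per classifier,
with 10-fold cross-validated hyperparameter tuning on the train side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import SELECTED_FEATURES
from . import evaluation

MODEL_FAMILIES = ("logistic", "pca_logistic", "svc_rbf", "gradient_boosting")
_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MfslBinning:
    """Ordinal binning of UPDRS III into severity levels."""

    level0_upper: float = 10.0
    increment: float = 12.5
    n_levels: int = 6

    def __post_init__(self) -> None:
        if self.level0_upper <= 0 or self.increment <= 0 or self.n_levels < 2:
            raise ValueError("binning parameters must be positive (n_levels >= 2)")


def ordinal_thresholds(binning: MfslBinning = MfslBinning()) -> list[float]:
    """UPDRS III decision thresholds of the n_levels - 1 binary classifiers.

    Defaults give [10, 22.5, 35, 47.5, 60]."""
    return [
        binning.level0_upper + binning.increment * k
        for k in range(binning.n_levels - 1)
    ]


def adjust_updrs(raw_total: float, scale_version: str) -> float:
    """Correct an older-scale UPDRS III total onto the MDS scale (+7 points);
    MDS-scale totals pass through unchanged."""
    if raw_total < 0:
        raise ValueError("UPDRS III total must be non-negative")
    if scale_version == "UPDRS":
        return raw_total + 7.0
    if scale_version == "MDS-UPDRS":
        return float(raw_total)
    raise ValueError(f"unknown scale_version {scale_version!r}")


def updrs_to_mfsl(score: float, binning: MfslBinning = MfslBinning()) -> int:
    """Severity level of an (adjusted) UPDRS III score; boundary scores are
    assigned upward (a score equal to a threshold belongs to the level above)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    thresholds = ordinal_thresholds(binning)
    return int(np.searchsorted(thresholds, score, side="right"))


@dataclass(frozen=True)
class SplitSpec:
    """Subject-grouped train/test split and CV protocol."""

    test_fraction: float = 0.30
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


class TrainingError(RuntimeError):
    """A classifier could not be trained (e.g. a side of the threshold empty)."""


def build_training_set(
    samples: pd.DataFrame,
    binning: MfslBinning = MfslBinning(),
) -> pd.DataFrame:
    """Attach the MFSL class label to window-epoch samples.

    ``samples`` carries one row per usable DT/ET window epoch with the
    subject's (adjusted) ``updrs`` score for that window — UPDRS_OFF for DT
    epochs, UPDRS_ON for ET epochs, 0 for control epochs.
    """
    out = samples.copy()
    out["mfsl"] = [updrs_to_mfsl(s, binning) for s in out["updrs"]]
    return out


def grouped_split_mask(
    samples: pd.DataFrame,
    positive: np.ndarray,
    split: SplitSpec,
    classifier_index: int,
) -> np.ndarray:
    """Boolean test mask: subject-disjoint, ~test_fraction of each binary
    class's samples in test.

    Subjects are stratified by their (has-positive, has-negative) sample
    pattern and a seeded ``test_fraction`` share of each stratum goes to test,
    which preserves each class's sample share in expectation while keeping
    groups intact.  The split varies across classifiers (seeded per index).
    """
    rng = np.random.default_rng([split.seed, classifier_index])
    subj = samples["subject_id"].to_numpy()
    pattern = pd.DataFrame({"subject_id": subj, "pos": positive}).groupby(
        "subject_id"
    )["pos"].agg(["any", "all"])
    test_subjects: set = set()
    for _, stratum in pattern.groupby(["any", "all"]):
        ids = np.array(sorted(stratum.index))
        rng.shuffle(ids)
        n_test = int(round(split.test_fraction * len(ids)))
        test_subjects.update(ids[:n_test])
    return np.isin(subj, sorted(test_subjects))


def _make_pipeline(family: str, n_features: int, seed: int):
    if family == "logistic":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
        grid = {"clf__C": [0.01, 0.1, 1.0, 10.0]}
    elif family == "pca_logistic":
        # Unsupervised reduction of the two collinear BKS percentile features
        # (first two feature columns) to their first principal component.
        reduce = ColumnTransformer(
            [
                ("pca", Pipeline([("s", StandardScaler()), ("p", PCA(n_components=1))]), [0, 1]),
                ("rest", "passthrough", list(range(2, n_features))),
            ]
        )
        est = Pipeline(
            [
                ("reduce", reduce),
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
        grid = {"clf__C": [0.01, 0.1, 1.0, 10.0]}
    elif family == "svc_rbf":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="rbf", random_state=seed))]
        )
        grid = {"clf__C": [1.0, 10.0], "clf__gamma": ["scale", 0.1]}
    elif family == "gradient_boosting":
        est = Pipeline([("clf", GradientBoostingClassifier(random_state=seed))])
        grid = {"clf__max_depth": [2, 3]}
    else:
        raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")
    return est, grid


def _cv_mean(search: GridSearchCV, metric: str, n_folds: int) -> float:
    """Mean CV score of the selected candidate, ignoring degenerate folds."""
    scores = [
        search.cv_results_[f"split{i}_test_{metric}"][search.best_index_]
        for i in range(n_folds)
    ]
    finite = [s for s in scores if np.isfinite(s)]
    return float(np.mean(finite)) if finite else float("nan")


def _decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return estimator.decision_function(X)
    return estimator.predict_proba(X)[:, 1]


@dataclass
class SeverityModel:
    """Trained 5-classifier bank plus the binning that defines its thresholds."""

    binning: MfslBinning
    features: tuple[str, ...]
    model_family: str
    classifiers: list = field(default_factory=list)
    training_report: pd.DataFrame | None = None

    @property
    def thresholds(self) -> list[float]:
        return ordinal_thresholds(self.binning)

    def predict_mfsl(self, feature_rows: pd.DataFrame) -> np.ndarray:
        """Per-epoch MFSL estimate: the number of classifiers voting
        above-threshold (0–5).  Rows with a missing feature yield NaN."""
        X = feature_rows[list(self.features)].to_numpy(dtype=float)
        out = np.full(len(X), np.nan)
        complete = np.all(np.isfinite(X), axis=1)
        if complete.any():
            votes = np.zeros(int(complete.sum()))
            for clf in self.classifiers:
                votes += clf.predict(X[complete]).astype(float)
            out[complete] = votes
        return out

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema_version": _SCHEMA_VERSION,
            "binning": {
                "level0_upper": self.binning.level0_upper,
                "increment": self.binning.increment,
                "n_levels": self.binning.n_levels,
            },
            "features": list(self.features),
            "model_family": self.model_family,
            "thresholds": self.thresholds,
        }
        (directory / "model.json").write_text(json.dumps(manifest, indent=1))
        joblib.dump(self.classifiers, directory / "classifiers.joblib")
        if self.training_report is not None:
            self.training_report.to_csv(directory / "training_report.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "SeverityModel":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        if manifest["schema_version"] != _SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        report_path = directory / "training_report.csv"
        return cls(
            binning=MfslBinning(**manifest["binning"]),
            features=tuple(manifest["features"]),
            model_family=manifest["model_family"],
            classifiers=joblib.load(directory / "classifiers.joblib"),
            training_report=pd.read_csv(report_path) if report_path.exists() else None,
        )


def train(
    labeled_samples: pd.DataFrame,
    model_family: str = "logistic",
    split: SplitSpec = SplitSpec(),
    features: tuple[str, ...] = SELECTED_FEATURES,
    binning: MfslBinning = MfslBinning(),
) -> SeverityModel:
    """Fit the 5 threshold classifiers with grouped CV hyperparameter tuning.

    ``labeled_samples`` is the output of :func:`build_training_set`, one row
    per usable window epoch with the selected feature columns, ``subject_id``
    and ``mfsl``.  The training report records per-classifier CV and held-out
    ROC / PR AUC.
    """
    df = labeled_samples.dropna(subset=list(features)).reset_index(drop=True)
    mfsl = df["mfsl"].to_numpy()
    X_all = df[list(features)].to_numpy(dtype=float)
    thresholds = ordinal_thresholds(binning)

    classifiers, report_rows = [], []
    for k, threshold in enumerate(thresholds, start=1):
        y = (mfsl >= k).astype(int)
        if y.min() == y.max():
            raise TrainingError(
                f"classifier {k}: only one class present at threshold {threshold}"
            )
        test_mask = grouped_split_mask(df, y.astype(bool), split, k)
        train_idx, test_idx = ~test_mask, test_mask
        y_train = y[train_idx]
        if y_train.min() == y_train.max():
            raise TrainingError(f"classifier {k}: train side has a single class")
        groups = df.loc[train_idx, "subject_id"].to_numpy()
        # keep every CV fold two-class: never split finer than the number of
        # subjects carrying the minority class
        subj_pos = pd.Series(y_train == 1).groupby(groups).any()
        subj_neg = pd.Series(y_train == 0).groupby(groups).any()
        n_folds = max(
            2,
            min(
                split.cv_folds,
                len(np.unique(groups)),
                int(subj_pos.sum()),
                int(subj_neg.sum()),
            ),
        )
        cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=split.seed)
        est, grid = _make_pipeline(model_family, len(features), split.seed)
        search = GridSearchCV(
            est,
            grid,
            scoring={"roc_auc": "roc_auc", "pr_auc": "average_precision"},
            refit="roc_auc",
            cv=cv,
            n_jobs=1,
            error_score=np.nan,
        )
        search.fit(X_all[train_idx], y_train, groups=groups)
        best = search.best_estimator_
        classifiers.append(best)

        row = {
            "classifier": k,
            "threshold": threshold,
            "n_train": int(train_idx.sum()),
            "n_test": int(test_idx.sum()),
            "cv_roc_auc": _cv_mean(search, "roc_auc", n_folds),
            "cv_pr_auc": _cv_mean(search, "pr_auc", n_folds),
            "test_roc_auc": np.nan,
            "test_pr_auc": np.nan,
        }
        y_test = y[test_idx]
        if test_idx.any() and y_test.min() != y_test.max():
            scores = _decision_scores(best, X_all[test_idx])
            row["test_roc_auc"] = evaluation.roc_auc(scores, y_test)
            row["test_pr_auc"] = evaluation.pr_auc(scores, y_test)
        report_rows.append(row)

    return SeverityModel(
        binning=binning,
        features=tuple(features),
        model_family=model_family,
        classifiers=classifiers,
        training_report=pd.DataFrame(report_rows),
    )


def predict_epoch_mfsl(model: SeverityModel, feature_rows: pd.DataFrame) -> np.ndarray:
    """Per-epoch MFSL estimates in [0, 5]; see :meth:`SeverityModel.predict_mfsl`."""
    return model.predict_mfsl(feature_rows)
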