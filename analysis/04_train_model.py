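"""Train the 5-classifier ordinal severity bank.

Each binary classifier separates window epochs below vs at-or-above one of
the UPDRS III thresholds (10, 22.5, 35, 47.5, 60) using the selected feature
trio, with a subject-grouped 30% test split and 10-fold grouped CV tuning of
the L2 strength.  Logistic regression is the default family; pass another
family name (pca_logistic, svc_rbf, gradient_boosting) as argv[1] to compare.
"""

import sys

import pandas as pd

import _common
from pkg_ldct.severity_model import build_training_set
from pkg_ldct.workbench import stage_train


def main() -> None:
    log = _common.setup("04_train_model")
    family = sys.argv[1] if len(sys.argv) > 1 else "logistic"
    samples = pd.read_csv(_common.OUT / "window_samples.csv")
    labeled = build_training_set(samples)
    model = stage_train(labeled, family, _common.split_spec(), _common.OUT)
    _common.publish("training_report.csv")
    log.info("training report (%s):\n%s", family, model.training_report.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
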