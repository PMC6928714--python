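"""Evaluate the sensor-side response against the clinical classification.

ROC and class-averaged PR AUC of abs-delta (and %-delta) against the binary
clinically-meaningful-improvement label, recomputed under the cumulative
exclusion scenarios.  The headline finding to look for: the AUC rises from
the all-subjects column to the fully excluded column as the heuristics remove
subjects whose sensor week cannot represent their levodopa challenge test.
"""

import pandas as pd

import _common
from pkg_ldct.workbench import stage_evaluate


def main() -> None:
    log = _common.setup("06_evaluate")
    results = pd.read_csv(_common.OUT / "results.csv")
    tables = stage_evaluate(results, _common.OUT)
    _common.publish("scenario_abs.csv", "scenario_pct.csv")
    abs_table = tables["abs"].table
    log.info("abs-delta scenario table:\n%s", abs_table.round(3).to_string())
    chain = ["all", "exclude_already_on", "exclude_on_and_uncertain", "exclude_on_uncertain_variable"]
    aucs = abs_table.loc["roc_auc", chain].astype(float).round(3).tolist()
    log.info("cumulative-exclusion ROC AUC progression: %s", " -> ".join(map(str, aucs)))


if __name__ == "__main__":
    main()
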