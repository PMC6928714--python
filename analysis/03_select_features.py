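"""Score candidate features and rank the refined set with JMIM.

Mutual information (6-nearest-neighbor estimator, nats) of each candidate
feature with the six severity classes, then the greedy joint-MI ranking that
rewards relevance while suppressing redundancy.  The expected outcome — and
what the severity model uses — is the trio BKS_M10P, BKS_M25P, TA_WM50P_Log.
"""

import pandas as pd

import _common
from pkg_ldct.severity_model import build_training_set
from pkg_ldct.workbench import stage_select


def main() -> None:
    log = _common.setup("03_select_features")
    samples = pd.read_csv(_common.OUT / "window_samples.csv")
    labeled = build_training_set(samples)
    mi_table, ranking = stage_select(
        labeled, k=6, seed=_common.selection_seed(), out_dir=_common.OUT
    )
    _common.publish("mi_table.csv", "jmim_ranking.csv")
    top = mi_table.sort_values("mi", ascending=False).head(5)
    log.info("top marginal MI (nats): %s", dict(zip(top["feature_name"], top["mi"].round(2))))
    log.info("JMIM order: %s", " > ".join(ranking.order))


if __name__ == "__main__":
    main()
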