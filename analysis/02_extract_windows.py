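"""Label activity, engineer features and extract dose/effect-time windows.

For every subject: the 5 epochs centered on each day's first-dose
acknowledgement (dose time, DT) and on the trough of the smoothed weekly BKS
series 46-90 min post-dose (effect time, ET), keeping only active on-wrist
epochs.  Writes the epoch-level window samples (with all candidate features)
and the per-subject weekly aggregates.
"""

import pandas as pd

import _common
from pkg_ldct.epoch_store import read_epochs
from pkg_ldct.features import SELECTED_FEATURES
from pkg_ldct.workbench import stage_windows


def main() -> None:
    log = _common.setup("02_extract_windows")
    recordings = read_epochs(
        _common.OUT / "epochs.csv", _common.OUT / "doses.json", _common.OUT / "clinical.csv"
    )
    samples = stage_windows(recordings, _common.ldct_config(), _common.OUT)
    summaries = pd.read_csv(_common.OUT / "window_summaries.csv")
    keep = ["subject_id", "kind", "n_epochs_total", "et_latency_min"] + [
        f"weekly_{stat}_{feat}" for feat in SELECTED_FEATURES for stat in ("mean", "sd")
    ]
    _common.RESULTS.mkdir(parents=True, exist_ok=True)
    summaries[keep].to_csv(_common.RESULTS / "window_summaries.csv", index=False)
    per_kind = samples.groupby("kind").size()
    per_subject = samples.groupby(["subject_id", "kind"]).size()
    log.info(
        "window epochs: %d DT + %d ET from %d subjects (max 30 per subject/kind; "
        "median %d)",
        per_kind.get("DT", 0),
        per_kind.get("ET", 0),
        samples["subject_id"].nunique(),
        int(per_subject.median()),
    )


if __name__ == "__main__":
    main()
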