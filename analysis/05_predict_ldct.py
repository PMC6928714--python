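"""Estimate each subject's levodopa response from the sensor data.

Applies the trained severity bank to the pooled DT and ET epochs, averages
the per-epoch severity votes into MFSL_DT and MFSL_ET, and derives the
absolute and percent response plus the three exclusion flags (uncertain
clinical improvement, already ON, excess day-to-day variability).
"""

import _common
from pkg_ldct.epoch_store import read_epochs
from pkg_ldct.severity_model import SeverityModel
from pkg_ldct.workbench import stage_predict


def main() -> None:
    log = _common.setup("05_predict_ldct")
    recordings = read_epochs(
        _common.OUT / "epochs.csv", _common.OUT / "doses.json", _common.OUT / "clinical.csv"
    )
    model = SeverityModel.load(_common.OUT / "model")
    results = stage_predict(recordings, model, _common.ldct_config(), _common.OUT)
    _common.publish("results.csv")
    pwp = results[results["group"] == "PwP"]
    log.info(
        "PwP with usable response: %d/%d; flags: %d already ON, %d variable amplitude, "
        "%d variable latency",
        pwp["abs_delta_pkg"].notna().sum(),
        len(pwp),
        pwp["flag_already_on"].eq(True).sum(),
        pwp["flag_variable_amplitude"].eq(True).sum(),
        pwp["flag_variable_latency"].eq(True).sum(),
    )


if __name__ == "__main__":
    main()
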