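"""Generate the synthetic study cohort.

151 people with Parkinson's and 174 controls, six days of 2-min epochs each,
with known ground-truth UPDRS III OFF/ON, response latency and the planted
already-ON / high-variability subgroups.  Writes the epoch CSV, dose-event
JSON, clinical CSV and truth table under results/pipeline/.
"""

import pandas as pd

import _common
from pkg_ldct.workbench import stage_simulate


def main() -> None:
    log = _common.setup("01_simulate")
    sim = _common.simulation_config()
    recordings, truths = stage_simulate(sim, _common.OUT)
    _common.publish("truth.csv", "clinical.csv")
    truth = pd.DataFrame([t.__dict__ for t in truths])
    pwp = truth[truth["group"] == "PwP"]
    log.info(
        "cohort: %d PwP (UPDRS_OFF %.0f +- %.0f, improvement %.0f +- %.0f, "
        "%.0f%% already ON) and %d controls",
        len(pwp),
        pwp["updrs_off"].mean(),
        pwp["updrs_off"].std(),
        (pwp["updrs_off"] - pwp["updrs_on"]).mean(),
        (pwp["updrs_off"] - pwp["updrs_on"]).std(),
        100 * pwp["already_on"].mean(),
        (truth["group"] == "control").sum(),
    )


if __name__ == "__main__":
    main()
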