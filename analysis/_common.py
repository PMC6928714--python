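"""Shared configuration of the numbered analysis drivers.

Every driver works under ``scratch/pipeline`` (bulky intermediates: the raw
epoch stream, window samples, the model bundle) and publishes its small
summary tables to ``results/``.  Stage seeds derive from one global study
seed, so running the scripts 01..06 in order reproduces exactly what
``pkg-ldct run-all`` writes.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

from pkg_ldct.ldct_pipeline import LdctConfig
from pkg_ldct.severity_model import SplitSpec
from pkg_ldct.synthetic_data import SimulationConfig
from pkg_ldct.workbench import child_seeds

STUDY_SEED = 1
_ROOT = Path(__file__).resolve().parent.parent
OUT = _ROOT / "scratch" / "pipeline"
RESULTS = _ROOT / "results"

_SEEDS = child_seeds(STUDY_SEED)


def publish(*names: str) -> None:
    """Copy small per-stage summary tables from the work area to results/."""
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name in names:
        shutil.copy2(OUT / name, RESULTS / name)


def simulation_config() -> SimulationConfig:
    return SimulationConfig(seed=_SEEDS[0])  # defaults: 151 PwP, 174 controls


def split_spec() -> SplitSpec:
    return SplitSpec(seed=_SEEDS[1])


def selection_seed() -> int:
    return _SEEDS[2]


def ldct_config() -> LdctConfig:
    return LdctConfig()


def setup(name: str) -> logging.Logger:
    OUT.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    return logging.getLogger(name)
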