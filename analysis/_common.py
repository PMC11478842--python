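"""Shared helpers for the numbered analysis scripts.

The study family is a deterministic simulated plastome set (five Plantago-
like species, two accessions of the barcoding target P_lanceolata, one
species carrying an IR expansion). Scripts regenerate it on demand so each
one can be run on its own; results go to results/, bulky sequence exports
to scratch/.
"""

from pathlib import Path

from plastomarker.simulate import SimulationConfig, simulate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 17
TARGET_SPECIES = "P_lanceolata"

_cache = {}


def study_config() -> SimulationConfig:
    return SimulationConfig.compact(
        seed=STUDY_SEED, ir_expansion=("P_maritima", 1200)
    )


def study_dataset():
    if "ds" not in _cache:
        _cache["ds"] = simulate(study_config())
    return _cache["ds"]


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
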