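"""Shared paths and constants for the numbered analysis drivers."""

from pathlib import Path

SEED = 17
ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "analysis" / "data"
OUT_DIR = ROOT / "results" / "analysis"

COHORTS = {"cohort1": 242, "cohort2": 188, "cohort3": 139}


def data_path(name: str) -> Path:
    return DATA_DIR / name


def out_path(name: str) -> Path:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    return OUT_DIR / name
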