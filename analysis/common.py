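"""Shared settings for the analysis scripts.

The cohorts are synthetic stand-ins generated at fixed seeds, so every
script can regenerate its inputs deterministically.  Problem sizes are
desk-scale: 120 trial eyes (~1000 fields) and 61 control eyes.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 20210830

N_EYES = 120
N_CONTROL_EYES = 61
CONTROL_VISITS = 9

K_RANGE = range(2, 13)
FOLDS = 10

COHORT_CSV = SCRATCH / "cohort.csv"
CONTROLS_CSV = SCRATCH / "controls.csv"
MODEL_JSON = RESULTS / "model.json"


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)


def make_cohorts():
    """Regenerate both cohorts at the fixed seeds (cheap, deterministic)."""
    from vfarch.synthetic import generate_cohort, generate_controls

    cohort, gt = generate_cohort(n_eyes=N_EYES, seed=SEED)
    controls = generate_controls(
        n_eyes=N_CONTROL_EYES, visits_per_eye=CONTROL_VISITS, seed=SEED + 1
    )
    return cohort, gt, controls
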