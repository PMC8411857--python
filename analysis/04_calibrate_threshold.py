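"""Calibrate the meaningful-weight threshold on the normal-control cohort.

Decomposes every control field into the fitted model's archetypes, computes
per-archetype mean weights and mean weight changes with 95% CIs across
eyes, and derives the threshold (ceil of the largest abnormal upper CI plus
a 2-point margin).  Writes results/calibration.csv and
results/threshold.json.
"""

import json

from common import CONTROLS_CSV, MODEL_JSON, RESULTS, ensure_dirs, make_cohorts
from vfarch import vf_data
from vfarch.aa import load_model
from vfarch.calibration import calibrate


def main() -> None:
    ensure_dirs()
    model = load_model(MODEL_JSON)
    if CONTROLS_CSV.exists():
        controls = vf_data.read_cohort(CONTROLS_CSV)
    else:
        _, _, controls = make_cohorts()

    cal = calibrate(controls, model, margin=2.0)
    cal.to_frame().to_csv(RESULTS / "calibration.csv", index=False)
    (RESULTS / "threshold.json").write_text(
        json.dumps(
            {
                "threshold": cal.threshold,
                "max_abnormal_upper": cal.max_abnormal_upper,
                "margin": cal.margin,
                "normal_archetype_ids": list(cal.normal_archetype_ids),
                "n_eyes": cal.n_eyes,
            },
            indent=1,
        )
    )
    print(cal.to_frame().round(3).to_string(index=False))
    print(
        f"normal archetypes {cal.normal_archetype_ids}; max abnormal upper CI "
        f"{cal.max_abnormal_upper:.2f}% -> threshold {cal.threshold}%"
    )


if __name__ == "__main__":
    main()
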