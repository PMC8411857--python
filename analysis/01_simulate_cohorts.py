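"""Generate the synthetic trial-like and control cohorts and summarize them.

Writes the full cohort CSVs under scratch/ and a one-row-per-cohort summary
(field counts, reliability, baseline MD distribution) to
results/cohort_summary.csv.
"""

import numpy as np
import pandas as pd

from common import COHORT_CSV, CONTROLS_CSV, RESULTS, ensure_dirs, make_cohorts
from vfarch import vf_data


def main() -> None:
    ensure_dirs()
    cohort, gt, controls = make_cohorts()
    vf_data.write_cohort(cohort, COHORT_CSV)
    vf_data.write_cohort(controls, CONTROLS_CSV)

    rows = []
    for name, series in (("trial", cohort), ("controls", controls)):
        fields = [f for s in series for f in s.fields]
        base_md = [f.md for f in fields if f.visit == "baseline"]
        rows.append(
            {
                "cohort": name,
                "n_eyes": len(series),
                "n_fields": len(fields),
                "n_unreliable": sum(not f.reliable for f in fields),
                "baseline_md_mean": float(np.mean(base_md)),
                "baseline_md_min": float(np.min(base_md)),
                "baseline_md_max": float(np.max(base_md)),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(summary.to_string(index=False))
    n_fail = gt.table.drop_duplicates("eye_id")["is_failure"].sum()
    print(f"planted treatment failures: {n_fail} of {len(cohort)} eyes")


if __name__ == "__main__":
    main()
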