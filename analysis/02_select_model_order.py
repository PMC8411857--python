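"""Model-order selection: RSS and 10-fold CV curves over k = 2..12.

Fits archetype models to every reliable field of the trial cohort and
writes the curve to results/rss_curve.csv together with the elbow pick
(results/selected_k.json).  The fitting set is the unaveraged reliable
fields, mirroring the convention of fitting on all tests and curating only
for the downstream analyses.
"""

import json
import time

from common import COHORT_CSV, FOLDS, K_RANGE, RESULTS, SEED, ensure_dirs, make_cohorts
from vfarch import vf_data
from vfarch.selection import rss_curve, select_k_elbow


def main() -> None:
    ensure_dirs()
    if COHORT_CSV.exists():
        cohort = vf_data.read_cohort(COHORT_CSV)
    else:
        cohort, _, _ = make_cohorts()
    reliable = [vf_data.filter_reliable(s) for s in cohort]
    fields = [f for s in reliable for f in s.fields]
    X = vf_data.td_matrix(fields)
    print(f"fitting k = {min(K_RANGE)}..{max(K_RANGE)} on {X.shape[0]} fields")

    t0 = time.time()
    curve = rss_curve(
        X, k_values=K_RANGE, folds=FOLDS, seed=SEED,
        n_restarts=2, max_iter=100, tol=1e-5, cv_n_restarts=1, cv_max_iter=40,
    )
    k = select_k_elbow(curve)
    print(f"done in {time.time() - t0:.0f}s; CV elbow selects k = {k}")

    curve.to_frame().to_csv(RESULTS / "rss_curve.csv", index=False)
    (RESULTS / "selected_k.json").write_text(
        json.dumps({"selected_k": k, "seed": SEED, "folds": FOLDS})
    )
    print(curve.to_frame().to_string(index=False))


if __name__ == "__main__":
    main()
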