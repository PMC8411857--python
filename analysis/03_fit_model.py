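"""Fit the final archetype model at the selected order.

Reads results/selected_k.json (falling back to k = 8 if step 02 has not
run), fits with restarts on all reliable fields, and writes
results/model.json plus the archetype TD maps (results/archetypes.csv).
"""

import json

from common import COHORT_CSV, MODEL_JSON, RESULTS, SEED, ensure_dirs, make_cohorts
from vfarch import vf_data
from vfarch.aa import export_archetype_grid, fit_archetypes, serialize_model


def main() -> None:
    ensure_dirs()
    sel = RESULTS / "selected_k.json"
    k = json.loads(sel.read_text())["selected_k"] if sel.exists() else 8
    if COHORT_CSV.exists():
        cohort = vf_data.read_cohort(COHORT_CSV)
    else:
        cohort, _, _ = make_cohorts()
    fields = [f for s in (vf_data.filter_reliable(s) for s in cohort) for f in s.fields]
    X = vf_data.td_matrix(fields)

    model = fit_archetypes(X, k, seed=SEED, n_restarts=5, max_iter=200)
    serialize_model(model, MODEL_JSON)
    export_archetype_grid(model, RESULTS / "archetypes.csv")

    print(f"k = {model.k} archetypes fit on {model.n_fit} fields, RSS {model.rss:.1f}")
    for j in range(model.k):
        print(
            f"  AT{j+1}: relative weight {100 * model.relative_weight[j]:5.2f}%, "
            f"average TD {model.average_td[j]:6.2f} dB"
        )


if __name__ == "__main__":
    main()
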