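"""Synthetic cohorts with known ground truth.

Generates two kinds of data: a papilledema-trial-like cohort (mild
baseline loss, replicate baseline tests, six months of follow-up with
improvement or treatment-failure worsening) and a normal-control cohort
(repeated normal tests over a nominal year).  Every field is composed as a
Dirichlet-weighted convex mixture of hand-authored prototype TD patterns
plus iid Gaussian noise, so the planted mixing weights are available for
recovery testing.

The prototypes mimic the qualitative defect patterns reported for
papilledema — blind-spot enlargement, partial arcuate loss respecting the
horizontal midline, nasal step, hemianopic loss, and general depression —
but are stylized shapes, not estimates of any fitted archetype.  Because
the surrogate MD is linear in the mixing weights, baseline severity is
controlled exactly by blending the drawn weights toward a corrective
prototype until the target MD is met.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grid
from .errors import ComputationError, ValidationError
from .vf_data import (
    EyeSeries,
    VisualField,
    surrogate_md,
    surrogate_psd,
)

PROTOTYPE_NAMES: tuple[str, ...] = (
    "normal",
    "general_depression_mild",
    "general_depression_severe",
    "blind_spot_enlargement",
    "arcuate_superior",
    "arcuate_inferior",
    "nasal_defect",
    "hemianopia_temporal",
)

#: feature tag of each prototype (controlled vocabulary shared with scoring)
PROTOTYPE_TAGS: dict[str, str] = {
    "normal": "normal",
    "general_depression_mild": "general_depression_mild",
    "general_depression_severe": "general_depression_severe",
    "blind_spot_enlargement": "blind_spot_enlargement",
    "arcuate_superior": "arcuate_superior",
    "arcuate_inferior": "arcuate_inferior",
    "nasal_defect": "nasal_defect",
    "hemianopia_temporal": "hemianopia",
}


def _build_prototypes() -> dict[str, np.ndarray]:
    xy = grid.coordinates()
    x, y = xy[:, 0], xy[:, 1]
    n = grid.N_LOCATIONS
    protos: dict[str, np.ndarray] = {}

    protos["normal"] = np.zeros(n)
    protos["general_depression_mild"] = np.full(n, -3.0)
    # severe loss deepens with eccentricity (and keeps the library affinely
    # independent: a second uniform map would be parallel to the mild one)
    ecc = np.hypot(x, y)
    protos["general_depression_severe"] = -16.0 - 8.0 * (ecc / ecc.max())

    # deep loss at the blind spot spreading to its immediate surround
    bs = np.zeros(n)
    for bx, by in grid.BLIND_SPOT_COORDS:
        dist = np.hypot(x - bx, y - by)
        bs = np.minimum(bs, np.where(dist < 1e-9, -30.0, np.where(dist <= 6.5, -12.0, np.where(dist <= 10.0, -4.0, 0.0))))
    protos["blind_spot_enlargement"] = bs

    # nerve-fiber-bundle arc: loss along a ~14 degree radius arc, one hemifield only
    r = np.hypot(x - 2.0, y)
    arc = -22.0 * np.exp(-(((r - 14.0) / 5.0) ** 2))
    arc[np.abs(arc) < 1.0] = 0.0
    sup = np.where(y > 0, arc, 0.0)
    inf = np.where(y < 0, arc, 0.0)
    protos["arcuate_superior"] = sup
    protos["arcuate_inferior"] = inf

    # nasal step: graded loss confined to the nasal (negative x) hemifield
    protos["nasal_defect"] = np.where(x <= -9, -15.0, np.where(x < 0, -5.0, 0.0))

    # hemianopic loss respecting the vertical midline
    protos["hemianopia_temporal"] = np.where(x > 0, -25.0, 0.0)

    for name, p in protos.items():
        assert p.min() >= -35.0 and p.max() <= 5.0, name
    return protos


_PROTOTYPES = _build_prototypes()


def prototype_matrix(names: tuple[str, ...] = PROTOTYPE_NAMES) -> np.ndarray:
    """(len(names), 54) matrix of prototype TD maps in canonical order."""
    return np.array([_PROTOTYPES[n] for n in names])


def prototype_mds(names: tuple[str, ...] = PROTOTYPE_NAMES) -> np.ndarray:
    return np.array([surrogate_md(_PROTOTYPES[n]) for n in names])


@dataclass
class GroundTruth:
    """Planted mixing weights and generation parameters per field."""

    table: pd.DataFrame  # eye_id, visit, replicate, md_target, w_<prototype>...
    prototype_names: tuple[str, ...]

    def weights(self) -> np.ndarray:
        cols = [f"w_{n}" for n in self.prototype_names]
        return self.table[cols].to_numpy(dtype=float)


def generate_mixture_matrix(
    n_fields: int,
    prototype_names: tuple[str, ...] = (
        "general_depression_mild",
        "blind_spot_enlargement",
        "arcuate_superior",
        "nasal_defect",
    ),
    dirichlet_alpha: float = 0.3,
    noise_sd_db: float = 1.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain planted-mixture matrix for recovery experiments.

    Returns ``(X, W, P)``: fields (n, 54), planted simplex weights
    (n, len(prototypes)) and the prototype matrix P.
    """
    rng = np.random.default_rng(seed)
    P = prototype_matrix(prototype_names)
    W = rng.dirichlet([dirichlet_alpha] * len(prototype_names), size=n_fields)
    X = W @ P + rng.normal(0.0, noise_sd_db, size=(n_fields, P.shape[1]))
    return np.clip(X, -40.0, 10.0), W, P


def _blend_to_md(w: np.ndarray, md_target: float, proto_md: np.ndarray) -> np.ndarray:
    """Move weight mass toward a corrective prototype until MD hits target.

    MD is linear in the mixing weights, so the blend parameter has a closed
    form and the result stays on the simplex.
    """
    md0 = float(w @ proto_md)
    if abs(md0 - md_target) < 1e-9:
        return w
    # corrective prototype: severe depression to go down, normal to go up
    target_idx = (
        PROTOTYPE_NAMES.index("general_depression_severe")
        if md_target < md0
        else PROTOTYPE_NAMES.index("normal")
    )
    md_e = proto_md[target_idx]
    if abs(md_e - md0) < 1e-12:
        raise ComputationError("cannot reach target MD: corrective prototype coincides")
    t = (md_target - md0) / (md_e - md0)
    t = float(np.clip(t, 0.0, 1.0))
    w2 = (1 - t) * w
    w2[target_idx] += t
    return w2


def _noisy_field(
    td_clean: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    td = td_clean + rng.normal(0.0, noise_sd, size=td_clean.shape)
    return np.clip(td, -40.0, 10.0)


def _reliability(rng: np.random.Generator, unreliable: bool) -> tuple[float, float]:
    if unreliable:
        if rng.random() < 0.5:
            return float(rng.uniform(0.35, 0.60)), float(rng.uniform(0.0, 0.10))
        return float(rng.uniform(0.0, 0.25)), float(rng.uniform(0.16, 0.30))
    return float(rng.uniform(0.0, 0.25)), float(rng.uniform(0.0, 0.10))


def _expert_label(w: np.ndarray) -> str:
    tags = [
        PROTOTYPE_TAGS[PROTOTYPE_NAMES[j]]
        for j in np.argsort(w)[::-1]
        if w[j] >= 0.25
    ]
    if not tags:
        tags = [PROTOTYPE_TAGS[PROTOTYPE_NAMES[int(np.argmax(w))]]]
    return "+".join(tags)


def generate_cohort(
    n_eyes: int = 150,
    visits: tuple[str, ...] = ("baseline", "m1", "m2", "m3", "m4", "m5", "m6"),
    dirichlet_alpha: float = 0.3,
    noise_sd_db: float = 1.5,
    md_range: tuple[float, float] | None = (-7.0, -2.0),
    seed: int | None = 0,
    failure_fraction: float = 0.04,
    unreliable_fraction: float = 0.025,
    improvement_rate_range: tuple[float, float] = (0.05, 0.30),
    max_tries: int = 100,
) -> tuple[list[EyeSeries], GroundTruth]:
    """Trial-like cohort: mild baseline loss, follow-up, failures.

    Per eye: baseline mixing weights are a Dirichlet draw blended to a
    target MD inside ``md_range`` (every baseline replicate's surrogate MD
    is required to land in range, noise included); two baseline replicates
    and, following the trial schedule, one test at months 1–5 and two at
    month 6.  Most eyes improve (weights drift toward the normal prototype
    at a per-eye rate); a ``failure_fraction`` subset worsens toward severe
    depression steeply enough to trip the confirmed-MD-drop failure rule.
    A small fraction of fields carries failing reliability indices.
    """
    if n_eyes < 1:
        raise ValidationError("n_eyes must be >= 1")
    if noise_sd_db < 0:
        raise ValidationError("noise_sd_db must be >= 0")
    rng = np.random.default_rng(seed)
    P = prototype_matrix()
    proto_md = prototype_mds()
    n_proto = len(PROTOTYPE_NAMES)
    e_normal = np.eye(n_proto)[PROTOTYPE_NAMES.index("normal")]

    month_of = {v: (0 if v == "baseline" else int(v[1:])) for v in visits}
    reps_of = {v: (2 if v in ("baseline", "m6") else 1) for v in visits}

    series_list: list[EyeSeries] = []
    gt_rows: list[dict] = []
    for i in range(n_eyes):
        eye_rng = np.random.default_rng(rng.integers(2**31 - 1))
        laterality = "OD" if i % 2 == 0 else "OS"
        eye_id = f"iih{i + 1:03d}-{laterality}"
        arm = "acetazolamide" if eye_rng.random() < 0.5 else "placebo"
        is_failure = eye_rng.random() < failure_fraction

        # baseline weights with severity inside the inclusion window
        w0 = None
        md_target = None
        for _ in range(max_tries):
            cand = eye_rng.dirichlet([dirichlet_alpha] * n_proto)
            if md_range is not None:
                lo, hi = md_range
                pad = 0.08 * (hi - lo)
                md_target = float(eye_rng.uniform(lo + pad, hi - pad))
                cand = _blend_to_md(cand, md_target, proto_md)
                if not (lo <= cand @ proto_md <= hi):
                    continue
            w0 = cand
            break
        if w0 is None:
            raise ComputationError(
                f"could not reach md_range={md_range} within {max_tries} draws"
            )

        rate = float(eye_rng.uniform(*improvement_rate_range))
        failure_month = int(eye_rng.integers(2, 6)) if is_failure else None
        base_md = float(w0 @ proto_md)
        if is_failure:
            drop_needed = (2.0 if base_md <= -3.5 else 3.0) + 0.8
            w_fail = _blend_to_md(w0, base_md - drop_needed, proto_md)

        fields: list[VisualField] = []
        baseline_guard_used = False
        for v in visits:
            m = month_of[v]
            if is_failure:
                frac = min(m / failure_month, 1.0)
                w_m = (1 - frac) * w0 + frac * w_fail
            else:
                shrink = (1 - rate) ** m
                w_m = shrink * w0 + (1 - shrink) * e_normal
            td_clean = w_m @ P
            for rep in range(reps_of[v]):
                unreliable = eye_rng.random() < unreliable_fraction
                if v == "baseline" and not baseline_guard_used:
                    unreliable = False  # keep at least one reliable baseline
                    baseline_guard_used = True
                for attempt in range(max_tries):
                    td = _noisy_field(td_clean, eye_rng, noise_sd_db)
                    if v != "baseline" or md_range is None:
                        break
                    if md_range[0] <= surrogate_md(td) <= md_range[1]:
                        break
                else:
                    raise ComputationError(
                        f"eye {eye_id}: baseline noise draw never met md_range"
                    )
                fl, fp = _reliability(eye_rng, unreliable)
                fields.append(
                    VisualField(
                        eye_id=eye_id,
                        laterality=laterality,
                        visit=v,
                        td=td,
                        md=surrogate_md(td),
                        psd=surrogate_psd(td),
                        fixation_loss_rate=fl,
                        false_positive_rate=fp,
                        expert_label=_expert_label(w0),
                        arm=arm,
                    )
                )
                gt_rows.append(
                    {
                        "eye_id": eye_id,
                        "visit": v,
                        "replicate": rep,
                        "md_target": md_target,
                        "is_failure": is_failure,
                        "failure_month": failure_month,
                        "improvement_rate": rate,
                        **{f"w_{n}": w for n, w in zip(PROTOTYPE_NAMES, w_m)},
                    }
                )
        series_list.append(EyeSeries(eye_id=eye_id, fields=fields))
    gt = GroundTruth(table=pd.DataFrame(gt_rows), prototype_names=PROTOTYPE_NAMES)
    return series_list, gt


def generate_controls(
    n_eyes: int = 61,
    visits_per_eye: int = 9,
    noise_sd_db: float = 1.5,
    seed: int | None = 0,
) -> list[EyeSeries]:
    """Normal-control cohort: repeated normal fields over a nominal year.

    Every field is the normal prototype (zero TD) plus noise; reliability
    indices always pass the filters.
    """
    if n_eyes < 1 or visits_per_eye < 1:
        raise ValidationError("n_eyes and visits_per_eye must be >= 1")
    rng = np.random.default_rng(seed)
    visits = ["baseline"] + [f"m{i}" for i in range(1, visits_per_eye)]
    series_list = []
    for i in range(n_eyes):
        eye_rng = np.random.default_rng(rng.integers(2**31 - 1))
        laterality = "OD" if i % 2 == 0 else "OS"
        eye_id = f"ctl{i + 1:03d}-{laterality}"
        fields = []
        for v in visits:
            td = _noisy_field(np.zeros(grid.N_LOCATIONS), eye_rng, noise_sd_db)
            fields.append(
                VisualField(
                    eye_id=eye_id,
                    laterality=laterality,
                    visit=v,
                    td=td,
                    md=surrogate_md(td),
                    psd=surrogate_psd(td),
                    fixation_loss_rate=float(eye_rng.uniform(0.0, 0.15)),
                    false_positive_rate=float(eye_rng.uniform(0.0, 0.08)),
                    expert_label="normal",
                )
            )
        series_list.append(EyeSeries(eye_id=eye_id, fields=fields))
    return series_list


def export_prototypes(path) -> None:
    """Prototype CSV in the cohort td_01..td_54 layout."""
    cols = [f"td_{i:02d}" for i in range(1, grid.N_LOCATIONS + 1)]
    df = pd.DataFrame(prototype_matrix(), columns=cols)
    df.insert(0, "prototype", PROTOTYPE_NAMES)
    df.to_csv(path, index=False)
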