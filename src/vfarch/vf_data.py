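"""Visual-field data model, CSV I/O, and cohort curation.

A :class:`VisualField` is one eye/visit observation: the 54 total-deviation
(TD) values of a 24-2 test in dB plus global indices and reliability
metadata.  An :class:`EyeSeries` is the longitudinal record of one eye.

Curation implements the trial-style rules this package targets:

* reliability — a field is unreliable when fixation losses reach 33% or
  false positives reach 15%, and unreliable fields are dropped;
* replicate averaging — multiple reliable fields at one visit are replaced
  by their pointwise mean TD map;
* treatment failure — an MD drop from baseline of ≥2 dB (baseline MD
  ≤ −3.5 dB) or ≥3 dB (baseline MD above −3.5 dB), confirmed on the next
  available test, marks the eye a treatment failure; the failure-visit
  field is then carried forward through the six-month outcome window.

MD and PSD for averaged or synthetic fields are simple surrogates (mean and
sample SD of the non-blind-spot TD values); the instrument's proprietary
variance-weighted formulas are not reproduced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import grid
from .errors import ValidationError

logger = logging.getLogger(__name__)

FIXATION_LOSS_CUTOFF = 0.33
FALSE_POSITIVE_CUTOFF = 0.15

TD_MIN, TD_MAX = -40.0, 10.0

#: fixed ordinal visit labels; ties within a visit broken by file order
VISIT_ORDER: tuple[str, ...] = ("baseline",) + tuple(f"m{i}" for i in range(1, 13)) + ("fail",)
_VISIT_RANK = {v: i for i, v in enumerate(VISIT_ORDER)}

_TD_COLS = [f"td_{i:02d}" for i in range(1, grid.N_LOCATIONS + 1)]
_META_COLS = [
    "eye_id",
    "laterality",
    "visit",
    "fixation_loss_rate",
    "false_positive_rate",
    "md",
    "psd",
    "expert_label",
    "arm",
]
COHORT_COLUMNS = _META_COLS + _TD_COLS


def visit_rank(visit: str) -> int:
    try:
        return _VISIT_RANK[visit]
    except KeyError:
        raise ValidationError(f"unknown visit label {visit!r}; expected one of {VISIT_ORDER}")


def surrogate_md(td: np.ndarray) -> float:
    """Unweighted mean of the non-blind-spot TD values (dB)."""
    return float(np.mean(np.asarray(td)[grid.non_blind_spot_indices()]))


def surrogate_psd(td: np.ndarray) -> float:
    """Sample standard deviation of the non-blind-spot TD values (dB)."""
    return float(np.std(np.asarray(td)[grid.non_blind_spot_indices()], ddof=1))


@dataclass
class VisualField:
    """One 24-2 field: TD vector in canonical right-eye orientation plus metadata."""

    eye_id: str
    laterality: str  # "OD" | "OS"
    visit: str
    td: np.ndarray  # 54 TD values, dB, canonical order
    md: float
    psd: float
    fixation_loss_rate: float = 0.0
    false_positive_rate: float = 0.0
    expert_label: str | None = None
    arm: str | None = None

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=float)
        if self.td.shape != (grid.N_LOCATIONS,):
            raise ValidationError(
                f"td must have {grid.N_LOCATIONS} entries, got shape {self.td.shape} "
                f"(eye {self.eye_id}, visit {self.visit})"
            )
        if not np.all(np.isfinite(self.td)):
            raise ValidationError(f"non-finite td values (eye {self.eye_id}, visit {self.visit})")

    @property
    def reliable(self) -> bool:
        return (
            self.fixation_loss_rate < FIXATION_LOSS_CUTOFF
            and self.false_positive_rate < FALSE_POSITIVE_CUTOFF
        )


@dataclass
class EyeSeries:
    """Ordered longitudinal record of one eye."""

    eye_id: str
    fields: list[VisualField] = dc_field(default_factory=list)
    failure_status: str = "none"  # none | treatment_failure | performance_failure
    failure_visit: str | None = None

    def __post_init__(self) -> None:
        self.fields = sorted(self.fields, key=lambda f: visit_rank(f.visit))

    @property
    def baseline_md(self) -> float:
        """Mean MD over baseline fields (reliable ones if any exist)."""
        base = [f for f in self.fields if f.visit == "baseline"]
        if not base:
            raise ValidationError(f"eye {self.eye_id}: no baseline field")
        reliable = [f for f in base if f.reliable]
        use = reliable or base
        return float(np.mean([f.md for f in use]))

    def visits(self) -> list[str]:
        seen: list[str] = []
        for f in self.fields:
            if f.visit not in seen:
                seen.append(f.visit)
        return seen


# ---------------------------------------------------------------------------
# CSV I/O


def _fields_to_frame(fields: Iterable[VisualField], unmirror_os: bool = True) -> pd.DataFrame:
    perm = grid.mirror_permutation()
    rows = []
    for f in fields:
        td = f.td[perm] if (unmirror_os and f.laterality == "OS") else f.td
        row = {
            "eye_id": f.eye_id,
            "laterality": f.laterality,
            "visit": f.visit,
            "fixation_loss_rate": f.fixation_loss_rate,
            "false_positive_rate": f.false_positive_rate,
            "md": f.md,
            "psd": f.psd,
            "expert_label": f.expert_label if f.expert_label is not None else "",
            "arm": f.arm if f.arm is not None else "",
        }
        row.update({c: v for c, v in zip(_TD_COLS, td)})
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(series: Sequence[EyeSeries], path: str | Path, mirror_os: bool = True) -> None:
    """Write a cohort CSV (one row per field, RFC-4180, '.' decimals).

    OS fields are written back in their native left-eye orientation when
    ``mirror_os`` is set, so a read/write round trip is the identity.
    """
    fields = [f for s in series for f in s.fields]
    _fields_to_frame(fields, unmirror_os=mirror_os).to_csv(path, index=False)


def read_cohort(path: str | Path, mirror_os: bool = True) -> list[EyeSeries]:
    """Read a cohort CSV into per-eye series.

    OS rows are mirrored into right-eye orientation at load (configurable).
    Malformed rows are reported with their file line numbers.
    """
    df = pd.read_csv(
        path,
        dtype={"eye_id": str, "laterality": str, "visit": str},
        float_precision="round_trip",
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV {path}: missing required columns {missing}")

    perm = grid.mirror_permutation()
    errors: list[str] = []
    by_eye: dict[str, list[VisualField]] = {}
    for pos, (idx, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1
        eye_id, visit = str(row["eye_id"]), str(row["visit"])
        try:
            td = row[_TD_COLS].to_numpy(dtype=float)
        except (TypeError, ValueError):
            errors.append(f"line {line} (eye {eye_id}, visit {visit}): non-numeric td entry")
            continue
        if not np.all(np.isfinite(td)):
            errors.append(f"line {line} (eye {eye_id}, visit {visit}): missing/non-finite td entry")
            continue
        if np.any(td < TD_MIN) or np.any(td > TD_MAX):
            errors.append(
                f"line {line} (eye {eye_id}, visit {visit}): td outside [{TD_MIN}, {TD_MAX}] dB"
            )
            continue
        laterality = str(row["laterality"]).upper()
        if laterality not in ("OD", "OS"):
            errors.append(f"line {line} (eye {eye_id}, visit {visit}): laterality must be OD or OS")
            continue
        if mirror_os and laterality == "OS":
            td = td[perm]
        md = row["md"]
        psd = row["psd"]
        try:
            vf = VisualField(
                eye_id=eye_id,
                laterality=laterality,
                visit=visit,
                td=td,
                md=float(md) if pd.notna(md) else surrogate_md(td),
                psd=float(psd) if pd.notna(psd) else surrogate_psd(td),
                fixation_loss_rate=float(row["fixation_loss_rate"]),
                false_positive_rate=float(row["false_positive_rate"]),
                expert_label=str(row["expert_label"]) if _present(row["expert_label"]) else None,
                arm=str(row["arm"]) if _present(row["arm"]) else None,
            )
            visit_rank(visit)  # validate label
        except ValidationError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        by_eye.setdefault(eye_id, []).append(vf)
    if errors:
        raise ValidationError("cohort CSV errors:\n" + "\n".join(errors))
    return [EyeSeries(eye_id=e, fields=fs) for e, fs in by_eye.items()]


def _present(value) -> bool:
    return pd.notna(value) and str(value) != ""


# ---------------------------------------------------------------------------
# Curation operations


def filter_reliable(series: EyeSeries) -> EyeSeries:
    """Drop unreliable fields; logs (and warns on empty result)."""
    kept = [f for f in series.fields if f.reliable]
    removed = len(series.fields) - len(kept)
    if removed:
        logger.info("eye %s: removed %d unreliable field(s)", series.eye_id, removed)
    if not kept and series.fields:
        warnings.warn(f"eye {series.eye_id}: all {removed} fields unreliable", stacklevel=2)
    return EyeSeries(
        eye_id=series.eye_id,
        fields=kept,
        failure_status=series.failure_status,
        failure_visit=series.failure_visit,
    )


def average_replicates(fields: Sequence[VisualField]) -> VisualField:
    """Pointwise-mean field over replicate tests at one visit.

    MD/PSD are recomputed from the averaged TD map via the surrogate
    formulas; reliability rates are averaged.
    """
    if not fields:
        raise ValidationError("average_replicates: empty input")
    eye_ids = {f.eye_id for f in fields}
    visits = {f.visit for f in fields}
    if len(eye_ids) > 1 or len(visits) > 1:
        raise ValidationError(
            f"average_replicates: mixed eyes {eye_ids} or visits {visits}"
        )
    if len(fields) == 1:
        return fields[0]
    td = np.mean([f.td for f in fields], axis=0)
    first = fields[0]
    return VisualField(
        eye_id=first.eye_id,
        laterality=first.laterality,
        visit=first.visit,
        td=td,
        md=surrogate_md(td),
        psd=surrogate_psd(td),
        fixation_loss_rate=float(np.mean([f.fixation_loss_rate for f in fields])),
        false_positive_rate=float(np.mean([f.false_positive_rate for f in fields])),
        expert_label=next((f.expert_label for f in fields if f.expert_label), None),
        arm=first.arm,
    )


def _md_drop_threshold(baseline_md: float) -> float:
    """Required MD drop (dB) for treatment failure, by baseline stratum."""
    return 2.0 if baseline_md <= -3.5 else 3.0


def detect_treatment_failure(series: EyeSeries) -> tuple[bool, str | None]:
    """Two-stratum confirmed-MD-drop treatment-failure rule.

    An eye fails at the first post-baseline visit whose MD drop from
    baseline meets the stratum threshold (≥2 dB when baseline MD ≤ −3.5 dB,
    else ≥3 dB) *and* whose next available test confirms a drop of the same
    magnitude.  Returns ``(failed, visit)``.
    """
    baseline_md = series.baseline_md
    threshold = _md_drop_threshold(baseline_md)
    per_visit: list[tuple[str, float]] = []
    for visit in series.visits():
        if visit == "baseline":
            continue
        vfields = [f for f in series.fields if f.visit == visit and f.reliable]
        if vfields:
            per_visit.append((visit, float(np.mean([f.md for f in vfields]))))
    for i, (visit, md) in enumerate(per_visit):
        if baseline_md - md >= threshold:
            if i + 1 < len(per_visit):
                _, md_next = per_visit[i + 1]
                if baseline_md - md_next >= threshold:
                    return True, visit
            # no later test: worsening never confirmed
    return False, None


def curate_outcome_window(series: EyeSeries, outcome_visit: str = "m6") -> EyeSeries:
    """Restrict a series to the outcome window and resolve failures.

    Drops visits after the outcome visit; for treatment failures the
    failure-visit field is substituted for every later visit through the
    outcome visit (fields recorded after confirmation are excluded); for
    performance failures only reliable fields are retained (the confirmatory
    tests — the unconfirmed worsening tests are the unreliable ones);
    unreliable fields are removed and replicates averaged, leaving one field
    per visit.
    """
    max_rank = visit_rank(outcome_visit)
    reliable = filter_reliable(series)
    kept = [f for f in reliable.fields if visit_rank(f.visit) <= max_rank]

    if series.failure_status == "treatment_failure":
        if series.failure_visit is None:
            raise ValidationError(f"eye {series.eye_id}: treatment failure without failure_visit")
        f_rank = visit_rank(series.failure_visit)
        failure_fields = [f for f in kept if f.visit == series.failure_visit]
        if not failure_fields:
            raise ValidationError(
                f"eye {series.eye_id}: no reliable field at failure visit {series.failure_visit}"
            )
        failure_field = average_replicates(failure_fields)
        kept = [f for f in kept if visit_rank(f.visit) <= f_rank]
        for v in VISIT_ORDER:
            r = visit_rank(v)
            if f_rank < r <= max_rank and v.startswith("m"):
                kept.append(replace(failure_field, visit=v, td=failure_field.td.copy()))

    averaged: list[VisualField] = []
    for visit in EyeSeries(eye_id=series.eye_id, fields=kept).visits():
        group = [f for f in kept if f.visit == visit]
        averaged.append(average_replicates(group))
    return EyeSeries(
        eye_id=series.eye_id,
        fields=averaged,
        failure_status=series.failure_status,
        failure_visit=series.failure_visit,
    )


def td_matrix(fields: Sequence[VisualField], include_blind_spot: bool = True) -> np.ndarray:
    """Stack fields into an (n, 54) — or (n, 52) — data matrix for fitting."""
    cols = grid.grid_indices(include_blind_spot)
    return np.array([f.td[cols] for f in fields], dtype=float)
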