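"""Control-cohort calibration of the meaningful-weight threshold.

Decomposing repeated visual fields from healthy eyes against a
disease-fitted archetype model shows how much weight normal fluctuation
alone places on each abnormal archetype.  The meaningful-weight threshold
is set just above the largest upper 95% confidence limit — over abnormal
archetypes, pooling mean weights and mean weight changes — plus a safety
margin that accounts for multiplicity across archetypes.

Statistics are computed across *eyes*: each eye's weights are first
averaged over its visits so repeated testing of one eye does not shrink
the confidence intervals.  Weight change is baseline-anchored by default
(mean absolute difference between each follow-up visit and the eye's first
visit); consecutive-visit differences are available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .aa import ArchetypeModel, decompose_matrix
from .errors import ValidationError
from .vf_data import EyeSeries, td_matrix, visit_rank

#: archetypes whose average TD is at least this (dB) count as "normal"
NORMAL_AVG_TD_CUTOFF = -1.0

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ControlCalibration:
    """Per-archetype control statistics and the derived threshold."""

    mean_weight: np.ndarray  # (k,) percent
    weight_ci95: np.ndarray  # (k, 2) percent
    mean_abs_change: np.ndarray  # (k,) percent
    change_ci95: np.ndarray  # (k, 2) percent
    n_eyes: int
    normal_archetype_ids: tuple[int, ...] = ()  # 1-based ids excluded from the max
    max_abnormal_upper: float | None = None  # percent
    margin: float | None = None  # percentage points
    threshold: int | None = None  # percent

    def to_frame(self) -> pd.DataFrame:
        k = len(self.mean_weight)
        return pd.DataFrame(
            {
                "archetype": np.arange(1, k + 1),
                "mean_weight": self.mean_weight,
                "weight_ci_lo": self.weight_ci95[:, 0],
                "weight_ci_hi": self.weight_ci95[:, 1],
                "mean_abs_change": self.mean_abs_change,
                "change_ci_lo": self.change_ci95[:, 0],
                "change_ci_hi": self.change_ci95[:, 1],
                "is_normal": [
                    (i + 1) in self.normal_archetype_ids for i in range(k)
                ],
            }
        )


def decompose_controls(
    controls: Sequence[EyeSeries],
    model: ArchetypeModel,
    include_blind_spot: bool = True,
) -> pd.DataFrame:
    """Weight table (eye_id, visit, w_1..w_k in percent) for all control fields."""
    if not controls:
        raise ValidationError("empty control cohort")
    rows = []
    for series in controls:
        fields = [f for f in series.fields if f.reliable]
        if not fields:
            continue
        W = decompose_matrix(td_matrix(fields, include_blind_spot), model)
        for f, w in zip(fields, W):
            rows.append({"eye_id": f.eye_id, "visit": f.visit, **{f"w_{j+1}": w[j] for j in range(model.k)}})
    if not rows:
        raise ValidationError("control cohort has no reliable fields")
    return pd.DataFrame(rows)


def weight_statistics(
    table: pd.DataFrame,
    change: str = "baseline_anchored",
    bootstrap: int = 0,
    seed: int | None = 0,
) -> ControlCalibration:
    """Mean weights and weight changes with 95% CIs across eyes.

    Per eye, weights are averaged over visits; the per-eye change is the
    mean absolute difference between each follow-up visit's weights and
    the eye's first (baseline) visit — or between consecutive visits with
    ``change="consecutive"``.  CIs are normal-approximation means ± 1.96·SE
    across eyes, or percentile bootstrap when ``bootstrap`` > 0.
    """
    w_cols = [c for c in table.columns if c.startswith("w_")]
    k = len(w_cols)
    eye_means, eye_changes = [], []
    for _, g in table.groupby("eye_id", sort=True):
        g = g.sort_values("visit", key=lambda s: s.map(visit_rank), kind="stable")
        W = g[w_cols].to_numpy(dtype=float)
        eye_means.append(W.mean(axis=0))
        if W.shape[0] >= 2:
            if change == "consecutive":
                diffs = np.abs(np.diff(W, axis=0))
            elif change == "baseline_anchored":
                diffs = np.abs(W[1:] - W[0])
            else:
                raise ValidationError(f"unknown change mode {change!r}")
            eye_changes.append(diffs.mean(axis=0))
    eye_means = np.array(eye_means)
    if eye_means.shape[0] < 2:
        raise ValidationError("need at least 2 eyes to form confidence intervals")
    eye_changes = np.array(eye_changes) if eye_changes else np.zeros((0, k))

    mean_w, ci_w = _mean_ci(eye_means, bootstrap, seed)
    if eye_changes.shape[0] >= 2:
        mean_c, ci_c = _mean_ci(eye_changes, bootstrap, seed)
    else:
        mean_c = np.zeros(k)
        ci_c = np.zeros((k, 2))
    return ControlCalibration(
        mean_weight=mean_w,
        weight_ci95=ci_w,
        mean_abs_change=mean_c,
        change_ci95=ci_c,
        n_eyes=eye_means.shape[0],
    )


def _mean_ci(
    samples: np.ndarray, bootstrap: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    mean = samples.mean(axis=0)
    n = samples.shape[0]
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(n, size=(bootstrap, n))
        boot_means = samples[idx].mean(axis=1)
        lo = np.percentile(boot_means, 2.5, axis=0)
        hi = np.percentile(boot_means, 97.5, axis=0)
    else:
        se = samples.std(axis=0, ddof=1) / math.sqrt(n)
        lo, hi = mean - _Z95 * se, mean + _Z95 * se
    return mean, np.column_stack([lo, hi])


def normal_archetype_ids(
    model: ArchetypeModel, explicit: Sequence[int] | None = None
) -> tuple[int, ...]:
    """1-based ids of archetypes treated as normal (excluded from the max).

    By default, archetypes whose average TD is ≥ −1 dB — patterns
    indistinguishable from a healthy field.  An explicit list overrides.
    """
    if explicit is not None:
        return tuple(sorted(int(i) for i in explicit))
    return tuple(
        i + 1 for i in range(model.k) if model.average_td[i] >= NORMAL_AVG_TD_CUTOFF
    )


def derive_threshold(
    cal: ControlCalibration,
    margin: float = 2.0,
    normal_ids: Sequence[int] | None = None,
) -> ControlCalibration:
    """Meaningful-weight threshold from control CIs.

    threshold = ceil(max upper 95% CI over abnormal archetypes, pooling
    weight and change intervals) + margin (percentage points, default 2).
    Returns the calibration with threshold fields filled in.
    """
    if margin < 0:
        raise ValidationError("margin must be nonnegative")
    normal = tuple(normal_ids) if normal_ids is not None else cal.normal_archetype_ids
    k = len(cal.mean_weight)
    abnormal = [j for j in range(k) if (j + 1) not in normal]
    if not abnormal:
        raise ValidationError("no abnormal archetypes to calibrate against")
    uppers = np.concatenate(
        [cal.weight_ci95[abnormal, 1], cal.change_ci95[abnormal, 1]]
    )
    max_upper = float(np.max(uppers))
    cal.normal_archetype_ids = normal
    cal.max_abnormal_upper = max_upper
    cal.margin = float(margin)
    cal.threshold = int(math.ceil(math.ceil(max_upper) + margin))
    return cal


def calibrate(
    controls: Sequence[EyeSeries],
    model: ArchetypeModel,
    margin: float = 2.0,
    normal_ids: Sequence[int] | None = None,
    change: str = "baseline_anchored",
    bootstrap: int = 0,
    seed: int | None = 0,
    include_blind_spot: bool = True,
) -> ControlCalibration:
    """End-to-end: decompose controls, compute CIs, derive the threshold."""
    table = decompose_controls(controls, model, include_blind_spot)
    cal = weight_statistics(table, change=change, bootstrap=bootstrap, seed=seed)
    cal.normal_archetype_ids = normal_archetype_ids(model, normal_ids)
    return derive_threshold(cal, margin=margin, normal_ids=cal.normal_archetype_ids)
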