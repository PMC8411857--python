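"""Meaningful-weight calls, dominant archetypes, the AT Sum composite, and
cohort-level report tables.

The AT Sum score condenses a field's full decomposition into one number in
[−100, 100]: weights of normal / less-abnormal archetypes (those with
higher average TD) enter with a positive sign, weights of more-abnormal
archetypes with a negative sign, and the signed percentages are summed.
Lower values mean worse field function; unlike MD the score weighs every
regional deficit equally rather than favoring low-variance central points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .aa import ArchetypeModel, Decomposition
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: controlled vocabulary for archetype / expert feature tags
FEATURE_TAGS = frozenset(
    {
        "normal",
        "general_depression_mild",
        "general_depression_severe",
        "blind_spot_enlargement",
        "arcuate_superior",
        "arcuate_inferior",
        "nasal_defect",
        "hemianopia",
        "quadrant_defect",
    }
)


@dataclass
class SignAssignment:
    """Per-archetype ±1 signs for the AT Sum composite."""

    signs: np.ndarray  # (k,) of +1/-1
    rule: str = "median_split"

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValidationError("signs must be +1 or -1 for every archetype")


@dataclass
class ATSumScore:
    value: float
    field_ref: str = ""


def meaningful_archetypes(d: Decomposition, threshold: float) -> set[int]:
    """1-based ids of archetypes with weight at or above the threshold (%)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    return {j + 1 for j in range(len(d.weights)) if d.weights[j] >= threshold}


def dominant_archetype(d: Decomposition) -> int | None:
    """1-based id of the unique archetype carrying ≥50% weight, else None."""
    at_half = np.flatnonzero(d.weights >= 50.0)
    if at_half.size == 1:
        return int(at_half[0]) + 1
    if at_half.size > 1:  # exactly 50/50
        logger.info("field %s: tie at 50/50, no dominant archetype", d.field_ref)
    return None


def assign_signs(
    model: ArchetypeModel,
    rule: str = "median_split",
    explicit_positive: Sequence[int] | None = None,
) -> SignAssignment:
    """Signs for the AT Sum: + for higher-average-TD archetypes.

    ``median_split`` ranks archetypes by average TD and marks the top half
    positive (for odd k the median archetype is positive).  An explicit
    1-based list of positive ids overrides.
    """
    k = model.k
    if rule == "explicit":
        if explicit_positive is None:
            raise ValidationError("explicit sign rule needs a list of positive ids")
        pos = set(int(i) for i in explicit_positive)
        if not pos.issubset(set(range(1, k + 1))):
            raise ValidationError(f"explicit positive ids {sorted(pos)} outside 1..{k}")
        signs = np.array([1 if (j + 1) in pos else -1 for j in range(k)])
        return SignAssignment(signs=signs, rule="explicit")
    if rule != "median_split":
        raise ValidationError(f"unknown sign rule {rule!r}")
    # rank by average TD descending, stable in index
    order = sorted(range(k), key=lambda j: (-model.average_td[j], j))
    n_pos = (k + 1) // 2
    signs = np.full(k, -1, dtype=int)
    signs[[order[i] for i in range(n_pos)]] = 1
    return SignAssignment(signs=signs, rule="median_split")


def at_sum(d: Decomposition, signs: SignAssignment) -> ATSumScore:
    """Signed sum of percent weights; in [−100, 100]."""
    if len(signs.signs) != len(d.weights):
        raise ValidationError(
            f"sign assignment covers {len(signs.signs)} archetypes, "
            f"decomposition has {len(d.weights)}"
        )
    return ATSumScore(value=float(signs.signs @ d.weights), field_ref=d.field_ref)


def match_classification(
    dominant: int,
    archetype_labels: Mapping[int, set[str] | Sequence[str]],
    expert_label: set[str] | Sequence[str],
) -> str:
    """Compare a dominant archetype's feature tags with the expert's.

    Returns ``"exact"`` (equal tag sets), ``"partial"`` (nonempty
    intersection), or ``"different"``.
    """
    if dominant not in archetype_labels:
        raise ValidationError(f"archetype {dominant} has no feature-tag label")
    at_tags = set(archetype_labels[dominant])
    expert_tags = set(expert_label)
    if not at_tags or not expert_tags:
        raise ValidationError("feature-tag sets must be nonempty")
    if at_tags == expert_tags:
        return "exact"
    if at_tags & expert_tags:
        return "partial"
    return "different"


# ---------------------------------------------------------------------------
# Cohort-level reports


def cohort_report(
    decompositions: Sequence[Decomposition],
    threshold: float,
    signs: SignAssignment | None = None,
    metadata: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    group_col: str | None = None,
    holm: bool = False,
    exact_small_n: bool = False,
) -> dict[str, pd.DataFrame]:
    """Frequency, correlation, and group-comparison tables for a cohort.

    ``metadata`` is one row per decomposition (aligned by position) with
    numeric covariate columns (e.g. md, psd, acuity, frisen_grade) and an
    optional two-level group column (e.g. treatment arm).  Produces:

    * ``frequencies`` — per archetype, count/fraction of fields at or above
      the meaningful-weight threshold;
    * ``meaningful_counts`` — distribution of meaningful-archetype counts;
    * ``correlations`` — Spearman rank correlation of each archetype weight
      (and the AT Sum, when signs are given) against each covariate;
    * ``group_tests`` — Wilcoxon rank-sum per archetype weight between the
      two groups, plus a chi-squared test on the 2×k table of
      above-threshold frequencies.
    """
    if not decompositions:
        raise ValidationError("no decompositions supplied")
    k = len(decompositions[0].weights)
    if any(len(d.weights) != k for d in decompositions):
        raise ValidationError("decompositions disagree on the number of archetypes")
    W = np.array([d.weights for d in decompositions])
    n = W.shape[0]

    meaningful = W >= threshold
    freq = pd.DataFrame(
        {
            "archetype": np.arange(1, k + 1),
            "n_meaningful": meaningful.sum(axis=0),
            "fraction": meaningful.sum(axis=0) / n,
        }
    )
    counts = meaningful.sum(axis=1)
    count_dist = (
        pd.Series(counts).value_counts().sort_index().rename_axis("n_archetypes").reset_index(name="n_fields")
    )

    report: dict[str, pd.DataFrame] = {
        "frequencies": freq,
        "meaningful_counts": count_dist,
    }

    scores = None
    if signs is not None:
        scores = np.array([at_sum(d, signs).value for d in decompositions])

    if metadata is not None and covariates:
        if len(metadata) != n:
            raise ValidationError("metadata rows must align with decompositions")
        rows = []
        variables = [(f"AT{j+1}", W[:, j]) for j in range(k)]
        if scores is not None:
            variables.append(("AT_sum", scores))
        for cov in covariates:
            x = pd.to_numeric(metadata[cov], errors="coerce").to_numpy(dtype=float)
            ok = np.isfinite(x)
            if np.unique(x[ok]).size < 3:
                logger.info("covariate %s: fewer than 3 distinct values, skipped", cov)
                continue
            for name, values in variables:
                v = values[ok]
                if np.unique(v).size < 2:
                    rows.append({"covariate": cov, "variable": name, "r": np.nan, "p": np.nan, "n": int(ok.sum()), "note": "constant weight"})
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = scipy.stats.spearmanr(v, x[ok])
                    if exact_small_n and ok.sum() <= 10:
                        p = _spearman_exact_p(v, x[ok])
                rows.append({"covariate": cov, "variable": name, "r": float(r), "p": float(p), "n": int(ok.sum()), "note": ""})
        corr = pd.DataFrame(rows, columns=["covariate", "variable", "r", "p", "n", "note"])
        if holm and len(corr):
            corr = _holm_adjust(corr)
        report["correlations"] = corr

    if metadata is not None and group_col is not None:
        groups = metadata[group_col].to_numpy()
        levels = pd.unique(groups[pd.notna(groups)])
        if len(levels) != 2:
            raise ValidationError(
                f"group column {group_col!r} must have exactly 2 levels, got {list(levels)}"
            )
        a, b = (groups == levels[0]), (groups == levels[1])
        rows = []
        for j in range(k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = scipy.stats.ranksums(W[a, j], W[b, j])
            rows.append({"archetype": j + 1, "test": "wilcoxon_rank_sum", "statistic": float(stat), "p": float(p)})
        table = np.vstack([meaningful[a].sum(axis=0), meaningful[b].sum(axis=0)])
        chi2_p, chi2_stat = np.nan, np.nan
        kept = table[:, table.sum(axis=0) > 0]  # drop empty columns
        if kept.shape[1] >= 2:
            chi2_stat, chi2_p = scipy.stats.chi2_contingency(kept, correction=False)[:2]
        rows.append({"archetype": 0, "test": "chi2_frequency_table", "statistic": float(chi2_stat), "p": float(chi2_p)})
        report["group_tests"] = pd.DataFrame(rows)

    return report


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the Spearman statistic (n <= 10)."""
    import itertools

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    observed = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, np.array(perm))[0, 1])
        count += r >= observed - 1e-12
        total += 1
    return count / total


def _holm_adjust(corr: pd.DataFrame) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    corr = corr.copy()
    ok = corr["p"].notna()
    adj = np.full(len(corr), np.nan)
    if ok.sum():
        adj[ok.to_numpy()] = multipletests(corr.loc[ok, "p"], method="holm")[1]
    corr["p_holm"] = adj
    return corr
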