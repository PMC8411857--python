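"""Model-order selection: RSS curves and elbow rules.

The number of archetypes is chosen from the residual-sum-of-squares curve
over a range of k (default 2..20), computed two ways: training RSS from a
full-data fit and held-out RSS from 10-fold cross-validation (each fold's rows
decomposed against archetypes fit on the other nine, accumulated over the
folds so every row is held out exactly once and the total is directly
comparable to the training RSS).  The
default elbow rule picks the k whose point on the min-max-normalized CV
curve is furthest from the chord joining the curve's endpoints; a
relative-drop rule (first k where the fractional RSS improvement falls
below a tolerance) is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .aa import fit_archetypes, model_rss
from .errors import ValidationError


@dataclass
class RSSCurve:
    k_values: np.ndarray
    train_rss: np.ndarray
    cv_rss: np.ndarray
    folds: int
    seed: int | None

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.train_rss = np.asarray(self.train_rss, dtype=float)
        self.cv_rss = np.asarray(self.cv_rss, dtype=float)
        if not np.all(np.diff(self.k_values) > 0):
            raise ValidationError("k_values must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": self.k_values, "train_rss": self.train_rss, "cv_rss": self.cv_rss}
        )


def rss_curve(
    X: np.ndarray,
    k_values: Sequence[int] = tuple(range(2, 21)),
    folds: int = 10,
    seed: int | None = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    cv_n_restarts: int | None = None,
    cv_max_iter: int | None = None,
) -> RSSCurve:
    """Training and cross-validated RSS for each candidate k.

    ``cv_rss`` accumulates the held-out RSS over the folds, so it is on the
    same scale as ``train_rss``.  Folds are formed by seeded shuffling
    (rows treated as exchangeable).
    ``cv_n_restarts``/``cv_max_iter`` allow cheaper settings for the fold
    fits than for the full-data fit; they default to the full settings.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_values = sorted(set(int(k) for k in k_values))
    if n < max(k_values) + n // folds:
        raise ValidationError(
            f"n={n} too small for k_max={max(k_values)} with {folds}-fold CV"
        )
    if n // folds < 1:
        raise ValidationError(f"{folds} folds leave empty held-out sets for n={n}")
    cv_n_restarts = n_restarts if cv_n_restarts is None else cv_n_restarts
    cv_max_iter = max_iter if cv_max_iter is None else cv_max_iter

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    train_rss, cv_rss = [], []
    for i, k in enumerate(k_values):
        full = fit_archetypes(
            X, k, seed=_derive(seed, k, 0), n_restarts=n_restarts, max_iter=max_iter, tol=tol
        )
        train_rss.append(full.rss)
        fold_rss = []
        for f, (tr, te) in enumerate(splits):
            m = fit_archetypes(
                X[tr],
                k,
                seed=_derive(seed, k, f + 1),
                n_restarts=cv_n_restarts,
                max_iter=cv_max_iter,
                tol=tol,
            )
            fold_rss.append(model_rss(X[te], m))
        cv_rss.append(float(np.sum(fold_rss)))
    return RSSCurve(
        k_values=np.array(k_values),
        train_rss=np.array(train_rss),
        cv_rss=np.array(cv_rss),
        folds=folds,
        seed=seed,
    )


def _derive(seed: int | None, k: int, fold: int) -> int | None:
    if seed is None:
        return None
    return int(np.random.default_rng([seed, k, fold]).integers(2**31 - 1))


def select_k_elbow(
    curve: RSSCurve,
    criterion: str = "chord",
    rel_tol: float = 0.05,
    use: str = "cv",
) -> int:
    """Pick the elbow k of an RSS curve.

    ``chord`` (default): after min-max normalization of both axes, the k
    maximizing perpendicular distance to the line joining the first and
    last points.  ``relative_drop``: smallest k whose RSS improvement over
    the previous k falls below ``rel_tol`` (fraction).
    """
    ks = curve.k_values
    if len(ks) < 3:
        raise ValidationError("elbow selection needs at least 3 curve points")
    rss = curve.cv_rss if use == "cv" else curve.train_rss

    if criterion == "chord":
        x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
        span = rss[0] - rss[-1]
        if abs(span) < 1e-300:
            warnings.warn("flat RSS curve; returning smallest k", stacklevel=2)
            return int(ks[0])
        y = (rss - rss[-1]) / span
        # distance from (x, y) to the chord through (0, 1) and (1, 0)
        dist = (1.0 - x - y) / np.sqrt(2.0)
        dist = np.abs(dist)
        if float(np.max(dist)) < 1e-12:
            warnings.warn("RSS curve is a straight line; returning smallest k", stacklevel=2)
            return int(ks[0])
        return int(ks[int(np.argmax(dist))])
    if criterion == "relative_drop":
        prev = rss[:-1]
        drop = np.where(np.abs(prev) > 0, (prev - rss[1:]) / np.abs(prev), 0.0)
        hits = np.flatnonzero(drop < rel_tol)
        if hits.size == 0:
            return int(ks[-1])
        return int(ks[hits[0] + 1])
    raise ValidationError(f"unknown elbow criterion {criterion!r}")
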