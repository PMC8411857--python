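"""Archetypal analysis of total-deviation maps.

Fits the Cutler–Breiman model: given a data matrix X (n fields × p
locations), find archetypes Z = βX and per-field loadings α, both with
rows on the probability simplex, minimizing ||X − αZ||².  Each archetype
is thereby constrained to the convex hull of the observed fields, so the
fitted patterns are extreme but data-realizable TD maps.

The alternating scheme here performs exact coordinate minimization:

* α-step — every field's loading row is an exact simplex-constrained
  least-squares solve against the current archetypes;
* Z-step — archetypes are updated one at a time; for slot j the
  unconstrained optimum v_j = α_jᵀR_j / ||α_j||² (R_j the residual
  excluding slot j) is projected onto the convex hull of the data, which
  is exactly the optimal β_j because
  ||R_j − α_j z||² = ||R_j||² + ||α_j||²(||z − v_j||² − ||v_j||²).

Both half-steps therefore never increase the objective, giving a
monotonically nonincreasing RSS up to the simplex-penalty tolerance.
Initialization uses furthest-sum seeding of candidate archetype rows for
the first restart and random row subsets for subsequent restarts (the
furthest-sum pick is nearly deterministic, so pure furthest-sum restarts
would barely explore); the best restart by final RSS is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._simplex import convex_coding, simplex_lstsq
from .errors import ValidationError
from .vf_data import VisualField

MODEL_SCHEMA_VERSION = 1

_WEIGHT_SUM_TOL = 1e-6


@dataclass
class ArchetypeModel:
    """A fitted k-archetype decomposition basis.

    ``archetypes`` holds the k TD patterns (dB) ordered by relative weight
    descending; ``relative_weight`` is each archetype's mean loading over
    the fitted fields (fractions summing to 1); ``average_td`` the mean TD
    of each archetype's entries.
    """

    k: int
    archetypes: np.ndarray  # (k, p) dB
    relative_weight: np.ndarray  # (k,) fractions, descending
    average_td: np.ndarray  # (k,) dB
    rss: float
    n_fit: int
    seed: int | None = None
    n_restarts: int = 1
    n_iterations: int = 0
    converged: bool = True
    grid: str = "24-2/54"
    rss_trace: list[float] = dc_field(default_factory=list)  # per-iteration RSS (best restart)

    def __post_init__(self) -> None:
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        self.relative_weight = np.asarray(self.relative_weight, dtype=float)
        self.average_td = np.asarray(self.average_td, dtype=float)
        if self.archetypes.shape[0] != self.k:
            raise ValidationError(
                f"model k={self.k} but {self.archetypes.shape[0]} archetypes present"
            )

    @property
    def n_locations(self) -> int:
        return self.archetypes.shape[1]


@dataclass
class Decomposition:
    """Archetype weights (percent, summing to 100) for one field."""

    weights: np.ndarray  # (k,) percent
    residual_norm: float  # dB (euclidean norm of the TD residual)
    field_ref: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        total = float(self.weights.sum())
        if abs(total - 100.0) > _WEIGHT_SUM_TOL or np.any(self.weights < -1e-9):
            raise ValidationError(
                f"decomposition weights must be nonnegative and sum to 100, got sum {total!r}"
            )


def furthest_sum_indices(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum seeding: k well-spread row indices of X.

    Starts from a random row, greedily adds the row maximizing the summed
    distance to all chosen rows, then discards the arbitrary initial row
    and re-picks it by the same rule.
    """
    n = X.shape[0]

    def _dist_to(j: int) -> np.ndarray:
        return np.linalg.norm(X - X[j], axis=1)

    first = int(rng.integers(n))
    chosen = [first]
    dist_sum = _dist_to(first)
    for _ in range(k - 1):
        masked = dist_sum.copy()
        masked[chosen] = -np.inf
        nxt = int(np.argmax(masked))
        chosen.append(nxt)
        dist_sum = dist_sum + _dist_to(nxt)
    if k > 1:  # discard the arbitrary initial point and re-pick it greedily
        rest = chosen[1:]
        d = np.sum([_dist_to(j) for j in rest], axis=0)
        d[rest] = -np.inf
        chosen = rest + [int(np.argmax(d))]
    return np.array(chosen, dtype=int)


def _single_fit(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    penalty: float,
    first_restart: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n, p = X.shape
    if first_restart or n <= k:
        init = furthest_sum_indices(X, k, rng)
    else:
        # later restarts explore beyond the (nearly deterministic)
        # furthest-sum seeding with random distinct rows
        init = rng.choice(n, size=k, replace=False)
    Z = X[init].copy()

    rss_prev = np.inf
    rss = np.inf
    converged = False
    alpha = np.full((n, k), 1.0 / k)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        alpha = simplex_lstsq(Z, X, penalty=penalty)
        resid = X - alpha @ Z
        rss = float(np.sum(resid * resid))
        trace.append(rss)
        if rss_prev - rss <= tol * max(rss_prev, 1e-300) and np.isfinite(rss_prev):
            converged = True
            break
        rss_prev = rss

        for j in range(k):
            a_j = alpha[:, j]
            a2 = float(a_j @ a_j)
            Rj = resid + np.outer(a_j, Z[j])
            if a2 < 1e-12:
                # unused archetype: reseed at the worst-fit field
                worst = int(np.argmax(np.sum(Rj * Rj, axis=1)))
                Z[j] = X[worst]
            else:
                v = (a_j @ Rj) / a2
                beta_j = convex_coding(X, v, penalty=penalty)
                Z[j] = beta_j @ X
            resid = Rj - np.outer(a_j, Z[j])

    alpha = simplex_lstsq(Z, X, penalty=penalty)
    resid = X - alpha @ Z
    rss = float(np.sum(resid * resid))
    trace.append(rss)
    return Z, alpha, rss, it, converged, trace


def fit_archetypes(
    X: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    penalty: float = 200.0,
    grid: str = "24-2/54",
) -> ArchetypeModel:
    """Fit a k-archetype model to an (n, p) TD data matrix.

    Runs ``n_restarts`` seeded alternating fits and keeps the best by final
    RSS.  Archetypes are reordered by relative weight (mean loading)
    descending, ties broken by average TD descending then by index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-d matrix of fields × locations")
    n, p = X.shape
    if not (1 <= k <= n):
        raise ValidationError(f"need 1 <= k <= n fields; got k={k}, n={n}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")

    if k == n:
        import warnings

        warnings.warn(
            f"k equals the number of fields (n={n}); archetypes degenerate to the data rows",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        result = _single_fit(
            X, k, rng, max_iter=max_iter, tol=tol, penalty=penalty,
            first_restart=(restart == 0),
        )
        if best is None or result[2] < best[2]:
            best = result
    assert best is not None
    Z, alpha, rss, iters, converged, trace = best
    if not converged:
        import warnings

        warnings.warn(
            f"archetype fit (k={k}) did not converge in {max_iter} iterations; "
            "returning best iterate",
            stacklevel=2,
        )

    rel_weight = alpha.mean(axis=0)
    avg_td = Z.mean(axis=1)
    # order: relative weight desc, then average TD desc, then original index
    order = sorted(range(k), key=lambda j: (-rel_weight[j], -avg_td[j], j))
    return ArchetypeModel(
        k=k,
        archetypes=Z[order],
        relative_weight=rel_weight[order],
        average_td=avg_td[order],
        rss=rss,
        n_fit=n,
        seed=seed,
        n_restarts=n_restarts,
        n_iterations=iters,
        converged=converged,
        grid=grid,
        rss_trace=trace,
    )


def decompose_matrix(X: np.ndarray, model: ArchetypeModel, penalty: float = 200.0) -> np.ndarray:
    """Weights (n, k) in percent for every row of X against fixed archetypes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_locations:
        raise ValidationError(
            f"field has {X.shape[1]} locations but model expects {model.n_locations}"
        )
    W = simplex_lstsq(model.archetypes, X, penalty=penalty)
    return W * 100.0


def decompose(
    field: VisualField | np.ndarray,
    model: ArchetypeModel,
    penalty: float = 200.0,
) -> Decomposition:
    """Decompose one field into archetype weights (percent, summing to 100).

    Deterministic simplex-constrained least squares against the fitted
    archetypes; no randomness is involved.
    """
    if isinstance(field, VisualField):
        x = field.td
        ref = f"{field.eye_id}/{field.visit}"
    else:
        x = np.asarray(field, dtype=float)
        ref = ""
    if x.shape != (model.n_locations,):
        raise ValidationError(
            f"field has {x.shape[0] if x.ndim == 1 else x.shape} locations "
            f"but model expects {model.n_locations}"
        )
    weights = decompose_matrix(x[None, :], model, penalty=penalty)[0]
    resid = x - (weights / 100.0) @ model.archetypes
    return Decomposition(weights=weights, residual_norm=float(np.linalg.norm(resid)), field_ref=ref)


def model_rss(X: np.ndarray, model: ArchetypeModel, penalty: float = 200.0) -> float:
    """Residual sum of squares of X decomposed against fixed archetypes.

    Each row is decomposed independently; this is also the held-out
    criterion used in cross-validation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = decompose_matrix(X, model, penalty=penalty) / 100.0
    resid = X - W @ model.archetypes
    return float(np.sum(resid * resid))


# ---------------------------------------------------------------------------
# Serialization


def serialize_model(model: ArchetypeModel, path: str | Path) -> None:
    """Write a model to JSON (full-precision decimal floats)."""
    payload = {
        "version": MODEL_SCHEMA_VERSION,
        "k": model.k,
        "grid": model.grid,
        "archetypes": [[float(v) for v in row] for row in model.archetypes],
        "relative_weight": [float(v) for v in model.relative_weight],
        "average_td": [float(v) for v in model.average_td],
        "rss": float(model.rss),
        "n_fit": model.n_fit,
        "seed": model.seed,
        "n_restarts": model.n_restarts,
        "n_iterations": model.n_iterations,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ArchetypeModel:
    """Load a model JSON written by :func:`serialize_model`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(
            f"model file {path}: schema version {version!r} not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    archetypes = np.array(payload["archetypes"], dtype=float)
    if archetypes.shape[0] != payload["k"]:
        raise ValidationError(
            f"model file {path}: k={payload['k']} but {archetypes.shape[0]} archetypes"
        )
    return ArchetypeModel(
        k=int(payload["k"]),
        archetypes=archetypes,
        relative_weight=np.array(payload["relative_weight"], dtype=float),
        average_td=np.array(payload["average_td"], dtype=float),
        rss=float(payload["rss"]),
        n_fit=int(payload["n_fit"]),
        seed=payload.get("seed"),
        n_restarts=int(payload.get("n_restarts", 1)),
        n_iterations=int(payload.get("n_iterations", 0)),
        converged=bool(payload.get("converged", True)),
        grid=payload.get("grid", "24-2/54"),
    )


def export_archetype_grid(model: ArchetypeModel, path: str | Path) -> None:
    """Per-archetype CSV in the cohort td_01..td_NN layout (for plotting)."""
    import pandas as pd

    cols = [f"td_{i:02d}" for i in range(1, model.n_locations + 1)]
    df = pd.DataFrame(model.archetypes, columns=cols)
    df.insert(0, "archetype", np.arange(1, model.k + 1))
    df.insert(1, "relative_weight", model.relative_weight)
    df.insert(2, "average_td", model.average_td)
    df.to_csv(path, index=False)


def archetype_labels(k: int) -> list[str]:
    """Display labels AT1..ATk (order of relative weight)."""
    return [f"AT{i}" for i in range(1, k + 1)]
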