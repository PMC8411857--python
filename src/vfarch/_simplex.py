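"""Simplex-constrained least squares via penalized NNLS.

The archetypal-analysis subproblems all have the form

    min ||x - w^T B||^2   s.t.  w >= 0,  sum(w) = 1,

solved with the classical penalty device: append a constraint row with a
large multiplier M to the design, turning the problem into plain NNLS.
NNLS itself is solved for many right-hand sides at once with block
principal pivoting (Kim & Park) on the Gram system, falling back to
scipy's Lawson–Hanson solver for any column that fails to converge.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

_FEAS_TOL = 1e-12


def nnls_multi(
    AtA: np.ndarray,
    AtB: np.ndarray,
    max_iter: int = 120,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve min ||A w_j - b_j||^2, w_j >= 0 for all columns j.

    Operates on normal equations: ``AtA`` is (q, q), ``AtB`` is (q, n).
    Returns ``(W, converged)`` with W of shape (q, n) and a boolean mask of
    columns that reached optimality.
    """
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.asarray(AtB, dtype=float)
    q, n = AtB.shape
    F = np.zeros((q, n), dtype=bool)  # passive (unconstrained) set
    W = np.zeros((q, n))
    Y = -AtB.copy()  # dual variables; optimal iff W,Y >= 0 split by F
    # Kim–Park backup-rule bookkeeping
    p = np.full(n, 3, dtype=int)
    ninf = np.full(n, q + 1, dtype=int)

    for _ in range(max_iter):
        infeas = (F & (W < -_FEAS_TOL)) | (~F & (Y < -_FEAS_TOL))
        n_inf = infeas.sum(axis=0)
        active_cols = np.flatnonzero(n_inf > 0)
        if active_cols.size == 0:
            return W, np.ones(n, dtype=bool)

        improved = n_inf < ninf
        ninf = np.where(improved, n_inf, ninf)
        p = np.where(improved, 3, p)

        flip = np.zeros_like(F)
        for j in active_cols:
            if improved[j] or p[j] > 0:
                if not improved[j]:
                    p[j] -= 1
                flip[:, j] = infeas[:, j]
            else:  # Murty's single-variable backup rule: guaranteed finite
                flip[infeas[:, j].nonzero()[0][-1], j] = True
        F[:, active_cols] ^= flip[:, active_cols]

        _solve_passive(AtA, AtB, F, W, active_cols)
        Y[:, active_cols] = AtA @ W[:, active_cols] - AtB[:, active_cols]
        Y[F] = 0.0

    infeas = (F & (W < -_FEAS_TOL)) | (~F & (Y < -_FEAS_TOL))
    return W, infeas.sum(axis=0) == 0


def _solve_passive(
    AtA: np.ndarray,
    AtB: np.ndarray,
    F: np.ndarray,
    W: np.ndarray,
    cols: np.ndarray,
) -> None:
    """Refresh W on the passive sets of ``cols``, grouping equal patterns."""
    _, inverse = np.unique(F[:, cols], axis=1, return_inverse=True)
    for g in range(int(inverse.max()) + 1):
        members = cols[np.asarray(inverse).ravel() == g]
        mask = F[:, members[0]]
        idx = np.flatnonzero(mask)
        W[:, members] = 0.0
        if idx.size == 0:
            continue
        sub = AtA[np.ix_(idx, idx)]
        rhs = AtB[np.ix_(idx, members)]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        W[np.ix_(idx, members)] = sol


def _penalty_multiplier(penalty: float, *arrays: np.ndarray) -> float:
    scale = max([1.0] + [float(np.max(np.abs(a))) for a in arrays if a.size])
    return penalty * scale


def simplex_lstsq(
    basis: np.ndarray,
    targets: np.ndarray,
    penalty: float = 200.0,
) -> np.ndarray:
    """Rows of W on the probability simplex minimizing ||targets - W @ basis||.

    ``basis`` is (k, p); ``targets`` is (n, p); returns W of shape (n, k).
    The penalized-NNLS solution is renormalized so each row sums to one
    exactly (the penalty leaves a deviation of order 1/M^2).
    """
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if basis.shape[1] != targets.shape[1]:
        raise ValueError(
            f"dimension mismatch: basis has {basis.shape[1]} coordinates, "
            f"targets have {targets.shape[1]}"
        )
    M = _penalty_multiplier(penalty, basis, targets)
    AtA = basis @ basis.T + M * M
    AtB = basis @ targets.T + M * M
    W, ok = nnls_multi(AtA, AtB)
    if not np.all(ok):
        aug_A = np.vstack([basis.T, np.full((1, basis.shape[0]), M)])
        for j in np.flatnonzero(~ok):
            aug_b = np.concatenate([targets[j], [M]])
            W[:, j] = scipy.optimize.nnls(aug_A, aug_b)[0]
    sums = W.sum(axis=0)
    bad = sums <= 0
    if np.any(bad):  # all-zero solution cannot be optimal under the penalty
        W[0, bad] = 1.0
        sums = W.sum(axis=0)
    return (W / sums).T


def convex_coding(
    data: np.ndarray,
    target: np.ndarray,
    penalty: float = 200.0,
) -> np.ndarray:
    """Coefficients beta on the simplex minimizing ||target - beta @ data||.

    Used for the archetype-update step: ``data`` is the (n, p) training
    matrix and ``target`` a p-vector.  Returns beta of shape (n,).
    """
    data = np.asarray(data, dtype=float)
    target = np.asarray(target, dtype=float)
    M = _penalty_multiplier(penalty, data, target)
    # more unknowns than equations: use Lawson–Hanson, which handles the
    # rank deficiency gracefully (support size never exceeds p + 1)
    aug_A = np.vstack([data.T, np.full((1, data.shape[0]), M)])
    aug_b = np.concatenate([target, [M]])
    beta = scipy.optimize.nnls(aug_A, aug_b)[0]
    s = beta.sum()
    if s <= 0:
        beta = np.zeros_like(beta)
        beta[int(np.argmin(((data - target) ** 2).sum(axis=1)))] = 1.0
        s = 1.0
    return beta / s
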