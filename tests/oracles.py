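"""Independent brute-force oracles for the archetypal-analysis tests.

These deliberately avoid the package's NNLS machinery: the decomposition
oracle enumerates a fine grid on the simplex, and the 2-D fit oracle does
exhaustive search over convex-hull boundary candidates followed by a
derivative-free polish of the boundary parameterization.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.optimize
import scipy.spatial


def simplex_grid(step: float = 1e-3) -> np.ndarray:
    """All points of the 2-simplex lattice with the given step (k = 3)."""
    ticks = int(round(1.0 / step))
    rows = []
    for a in range(ticks + 1):
        b = np.arange(0, ticks - a + 1)
        rows.append(np.column_stack([np.full_like(b, a), b, ticks - a - b]))
    return np.concatenate(rows).astype(float) / ticks


def grid_search_objective(Z: np.ndarray, x: np.ndarray, W: np.ndarray) -> float:
    """min over grid weights w of ||x - w @ Z||^2 (k = 3 archetypes)."""
    G = Z @ Z.T
    quad = np.einsum("ij,jk,ik->i", W, G, W)
    cross = W @ (Z @ x)
    return float(np.min(x @ x - 2.0 * cross + quad))


# ---------------------------------------------------------------------------
# 2-D exhaustive fit oracle


def _segment_sqdist(P: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared distances from points P (n, 2) to segment ab."""
    d = b - a
    denom = float(d @ d)
    if denom < 1e-300:
        return np.sum((P - a) ** 2, axis=1)
    t = np.clip((P - a) @ d / denom, 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.sum((P - proj) ** 2, axis=1)


def _triangle_sqdist(P: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Squared distances from points P to the (filled) triangle V (3, 2)."""
    a, b, c = V
    # barycentric inside test via sign of cross products
    def cross(o, p, q):
        return (p[0] - o[0]) * (q[:, 1] - o[1]) - (p[1] - o[1]) * (q[:, 0] - o[0])

    s1 = cross(a, b, P)
    s2 = cross(b, c, P)
    s3 = cross(c, a, P)
    inside = ((s1 >= 0) & (s2 >= 0) & (s3 >= 0)) | ((s1 <= 0) & (s2 <= 0) & (s3 <= 0))
    d = np.minimum(
        _segment_sqdist(P, a, b),
        np.minimum(_segment_sqdist(P, b, c), _segment_sqdist(P, c, a)),
    )
    return np.where(inside, 0.0, d)


def _hull_rss(X: np.ndarray, Z: np.ndarray) -> float:
    """Sum over data points of squared distance to conv(Z), k = 2 or 3."""
    if Z.shape[0] == 2:
        return float(np.sum(_segment_sqdist(X, Z[0], Z[1])))
    return float(np.sum(_triangle_sqdist(X, Z)))


def _boundary_param(hull_pts: np.ndarray):
    """Map arc-length parameter t in [0, L) to a hull-boundary point."""
    closed = np.vstack([hull_pts, hull_pts[0]])
    seg_len = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    L = cum[-1]

    def point_at(t: float) -> np.ndarray:
        t = t % L
        i = int(np.searchsorted(cum, t, side="right")) - 1
        i = min(i, len(seg_len) - 1)
        frac = (t - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        return closed[i] + frac * (closed[i + 1] - closed[i])

    return point_at, L


def fit_oracle_2d(X: np.ndarray, k: int, n_boundary: int = 60) -> float:
    """Exhaustive-search RSS for archetypal analysis of 2-D data, k in {2, 3}.

    Optimal archetypes for k >= 2 lie on the convex-hull boundary, so the
    search enumerates all k-subsets of a dense boundary discretization
    (including the hull vertices themselves) and polishes the best subset
    with Nelder–Mead on the boundary arc-length parameters.
    """
    assert k in (2, 3)
    hull = scipy.spatial.ConvexHull(X)
    hull_pts = X[hull.vertices]
    point_at, L = _boundary_param(hull_pts)
    ts = np.linspace(0.0, L, n_boundary, endpoint=False)
    cands = np.array([point_at(t) for t in ts])

    best_rss, best_ts = np.inf, None
    for idx in itertools.combinations(range(len(ts)), k):
        rss = _hull_rss(X, cands[list(idx)])
        if rss < best_rss:
            best_rss, best_ts = rss, ts[list(idx)]

    def objective(t_vec: np.ndarray) -> float:
        Z = np.array([point_at(t) for t in t_vec])
        return _hull_rss(X, Z)

    res = scipy.optimize.minimize(
        objective, best_ts, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    return float(min(best_rss, res.fun))
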