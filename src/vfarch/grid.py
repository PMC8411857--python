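"""Canonical 24-2 test-point lattice.

The Humphrey 24-2 pattern probes 54 locations on a 6-degree grid:
rows at vertical eccentricities y in {±3, ±9, ±15, ±21} degrees, with
horizontal extents of 4/6/8/9 points per row (the 9-point rows at y = ±3
include the extra nasal points at 27 degrees).  Everything in this package
works in *right-eye orientation*: temporal eccentricity is positive x,
superior is positive y.  Two locations, (15, 3) and (15, −3), overlie the
physiologic blind spot.

Canonical ordering is row-major starting at the superior-temporal corner:
rows from y = +21 down to y = −21, and within each row from the temporal
edge (largest x) to the nasal edge (smallest x).

Left-eye (OS) fields arrive on the mirror-image lattice (their nasal
extension points at the opposite side) scanned with the same
superior-temporal-first scheme.  Reflecting about the vertical midline
(x → −x) maps that lattice exactly onto the canonical one and, expressed
as a permutation of the stored 54-vector, amounts to reversing each row
segment.  The permutation is an involution, so it also converts canonical
fields back to left-eye orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# x offsets per row, temporal (positive) first
_ROW_X: dict[int, tuple[int, ...]] = {
    21: (9, 3, -3, -9),
    15: (15, 9, 3, -3, -9, -15),
    9: (21, 15, 9, 3, -3, -9, -15, -21),
    3: (21, 15, 9, 3, -3, -9, -15, -21, -27),
    -3: (21, 15, 9, 3, -3, -9, -15, -21, -27),
    -9: (21, 15, 9, 3, -3, -9, -15, -21),
    -15: (15, 9, 3, -3, -9, -15),
    -21: (9, 3, -3, -9),
}

_ROW_Y: tuple[int, ...] = (21, 15, 9, 3, -3, -9, -15, -21)

BLIND_SPOT_COORDS: frozenset[tuple[int, int]] = frozenset({(15, 3), (15, -3)})

N_LOCATIONS = 54


@dataclass(frozen=True)
class VFLocation:
    """One 24-2 test location in right-eye orientation."""

    x_deg: int
    y_deg: int
    is_blind_spot: bool


def locations() -> list[VFLocation]:
    """The 54 locations in canonical order."""
    locs = []
    for y in _ROW_Y:
        for x in _ROW_X[y]:
            locs.append(VFLocation(x, y, (x, y) in BLIND_SPOT_COORDS))
    return locs


_LOCATIONS = locations()
_INDEX = {(loc.x_deg, loc.y_deg): i for i, loc in enumerate(_LOCATIONS)}


def index_of(x_deg: int, y_deg: int) -> int:
    """Canonical index of the location at (x, y); KeyError if off-lattice."""
    return _INDEX[(x_deg, y_deg)]


def coordinates() -> np.ndarray:
    """(54, 2) array of (x, y) in canonical order."""
    return np.array([(loc.x_deg, loc.y_deg) for loc in _LOCATIONS], dtype=float)


def blind_spot_indices() -> np.ndarray:
    return np.array([i for i, loc in enumerate(_LOCATIONS) if loc.is_blind_spot])


def non_blind_spot_indices() -> np.ndarray:
    return np.array([i for i, loc in enumerate(_LOCATIONS) if not loc.is_blind_spot])


def mirror_permutation() -> np.ndarray:
    """Permutation mapping a left-eye field onto the canonical lattice.

    ``td_canonical = td_os[mirror_permutation()]``.  Reverses each row
    segment; involutive, so applying it twice is the identity.
    """
    perm = np.empty(N_LOCATIONS, dtype=int)
    start = 0
    for y in _ROW_Y:
        n = len(_ROW_X[y])
        perm[start : start + n] = np.arange(start + n - 1, start - 1, -1)
        start += n
    return perm


def grid_indices(include_blind_spot: bool = True) -> np.ndarray:
    """Column indices used for model fitting (54- or 52-location mode)."""
    if include_blind_spot:
        return np.arange(N_LOCATIONS)
    return non_blind_spot_indices()
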