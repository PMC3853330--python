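"""Toroidal lattice geometry.

The tissue patch is a square lattice with periodic (torus) wrapping on both
axes, matching the default NetLogo world topology and avoiding edge
artifacts.  Coordinates are 0-based (row, col).  All radius tests use
Euclidean distance with an inclusive (<= r) convention.
"""

from __future__ import annotations

import math
from functools import lru_cache

Position = tuple[int, int]


def axis_delta(a: int, b: int, n: int) -> int:
    """Minimal wrap-around separation of two coordinates on an axis of length n."""
    d = abs(a - b) % n
    return min(d, n - d)


def distance(a: Position, b: Position, grid_size: int) -> float:
    """Euclidean distance between two lattice positions with torus wrapping."""
    return math.hypot(
        axis_delta(a[0], b[0], grid_size), axis_delta(a[1], b[1], grid_size)
    )


def von_neumann_neighbors(p: Position, grid_size: int) -> list[Position]:
    """The 4 orthogonally adjacent positions of p, wrapped toroidally."""
    i, j = p
    n = grid_size
    return [
        ((i - 1) % n, j),
        ((i + 1) % n, j),
        (i, (j - 1) % n),
        (i, (j + 1) % n),
    ]


@lru_cache(maxsize=None)
def ring_offsets(
    grid_size: int, radius: float
) -> tuple[tuple[float, tuple[tuple[int, int], ...]], ...]:
    """Lattice offsets within `radius`, grouped by distance, nearest first.

    Returns ((distance, offsets), ...) sorted by ascending distance; the
    (0, 0) offset is included at distance 0.  Offsets are canonical torus
    displacements, so every reachable patch appears exactly once even when
    2*radius + 1 exceeds the grid size.  Used for neighborhood scans
    (nearest-target searches and radius counts) in O(patches in radius).
    """
    rings: dict[float, list[tuple[int, int]]] = {}
    for di in range(grid_size):
        for dj in range(grid_size):
            d = math.hypot(min(di, grid_size - di), min(dj, grid_size - dj))
            if d <= radius:
                rings.setdefault(d, []).append((di, dj))
    return tuple((d, tuple(rings[d])) for d in sorted(rings))
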