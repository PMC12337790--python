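"""Axial-coordinate helpers for the regular hexagonal tiling.

Cells are addressed by axial coordinates (q, r); the six neighbors of a
cell are the standard axial offsets.  Used for the theoretical
maximal-connectivity polyhexes and for hexagonal-tiling ring-size
approximations.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable

AXIAL_DIRS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))

Cellq = tuple[int, int]


def neighbors(cell: Cellq) -> list[Cellq]:
    q, r = cell
    return [(q + dq, r + dr) for dq, dr in AXIAL_DIRS]


def hex_ring(radius: int) -> list[Cellq]:
    """Cells at exact hex distance ``radius`` from the origin, in walk order."""
    if radius == 0:
        return [(0, 0)]
    out: list[Cellq] = []
    q, r = (AXIAL_DIRS[4][0] * radius, AXIAL_DIRS[4][1] * radius)
    for side in range(6):
        dq, dr = AXIAL_DIRS[side]
        for _ in range(radius):
            out.append((q, r))
            q, r = q + dq, r + dr
    return out


def spiral(n: int) -> list[Cellq]:
    """A maximally compact polyhex of n cells (spiral-equivalent).

    Greedy accretion from the origin, always adding the candidate with
    the most neighbors already in the set (ties broken toward the
    origin, then lexicographically); attains the maximal internal-edge
    count 3n − ⌈√(12n−3)⌉.
    """
    cells: list[Cellq] = [(0, 0)]
    s = {(0, 0)}
    while len(cells) < n:
        cand = {nb for c in s for nb in neighbors(c)} - s
        best = max(
            cand,
            key=lambda c: (
                sum(1 for nb in neighbors(c) if nb in s),
                -_hex_dist(c),
                (-c[0], -c[1]),
            ),
        )
        cells.append(best)
        s.add(best)
    return cells


def _hex_dist(c: Cellq) -> int:
    q, r = c
    return (abs(q) + abs(r) + abs(q + r)) // 2


def internal_edges(cells: Iterable[Cellq]) -> int:
    s = set(cells)
    return sum(1 for c in s for nb in neighbors(c) if nb in s) // 2


def bfs_rings(cells: Iterable[Cellq], max_ring: int = 3) -> dict[int, int]:
    """Ring populations {1: m₁, ...} around a cell set on the infinite tiling."""
    clone = set(cells)
    dist: dict[Cellq, int] = {c: 0 for c in clone}
    frontier = deque(clone)
    counts = {r: 0 for r in range(1, max_ring + 1)}
    while frontier:
        c = frontier.popleft()
        d = dist[c]
        if d >= max_ring:
            continue
        for nb in neighbors(c):
            if nb not in dist:
                dist[nb] = d + 1
                counts[d + 1] += 1
                frontier.append(nb)
    return counts


def max_internal_edges(n: int) -> int:
    """Maximum adjacent-pair count among n cells on the hexagonal tiling.

    Closed form 3n − ⌈√(12n − 3)⌉ (the hexagonal analogue of the maximal
    polyomino-edge formula); the exhaustive search below confirms it for
    n ≤ 10 and the spiral polyhex attains it.
    """
    import math

    if n < 1:
        raise ValueError("n must be ≥ 1")
    x = 12 * n - 3
    r = math.isqrt(x)
    ceil_sqrt = r if r * r == x else r + 1
    return 3 * n - ceil_sqrt


def max_internal_edges_exhaustive(n_max: int) -> dict[int, int]:
    """Exhaustive maximal internal-edge counts for polyhexes of size ≤ n_max.

    Enumerates every fixed polyhex (connected cell set up to translation)
    by incremental growth with canonical-translation deduplication and
    tracks the internal-edge count incrementally.  Exponential in n_max;
    intended as an oracle for small n (n_max ≤ 10).
    """
    level: dict[tuple[Cellq, ...], int] = {((0, 0),): 0}
    best = {1: 0}
    for n in range(2, n_max + 1):
        nxt: dict[tuple[Cellq, ...], int] = {}
        for cells, e in level.items():
            s = set(cells)
            for c in cells:
                for nb in neighbors(c):
                    if nb in s:
                        continue
                    grown = s | {nb}
                    key = _canonical(grown)
                    if key not in nxt:
                        nxt[key] = e + sum(1 for x in neighbors(nb) if x in s)
        level = nxt
        best[n] = max(level.values())
    return best


def _canonical(cells: set[Cellq]) -> tuple[Cellq, ...]:
    qmin = min(q for q, _ in cells)
    rmin = min(r for _, r in cells)
    return tuple(sorted((q - qmin, r - rmin) for q, r in cells))
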