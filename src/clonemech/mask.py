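"""Build a :class:`~clonemech.tissue.Tissue` from an integer label mask.

Labels ≥ 1 are cells; 0 is background / membrane skeleton.  Junction
polylines are traced on the pixel-corner grid: every unit edge between
two 4-adjacent pixels carrying different labels belongs to the boundary
of that label pair, and chaining the edges of one pair yields its shared
polylines.  Two labels count as adjacent only when a shared chain has at
least two unit edges, which suppresses the spurious one-pixel contacts
that pixelation creates where four cells meet.

Coordinates follow the pixel-center convention: pixel (row, col) has its
center at (x, y) = (col, row) · scale, so pixel corners sit at
half-integer offsets.  All output geometry is in µm.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from shapely.geometry import Polygon
from skimage import measure

from .tissue import Cell, Junction, Tissue


def mask_to_tissue(
    label_mask: np.ndarray,
    scale: float = 1.0,
    excluded_labels: set[int] | None = None,
) -> Tissue:
    """Convert a 2D integer label image into a tissue graph.

    Parameters
    ----------
    label_mask
        2D array; labels ≥ 1 are cells, 0 is background.
    scale
        µm per pixel, > 0.
    excluded_labels
        Cell labels (e.g. sensory-organ cells) flagged ``excluded`` and
        omitted from downstream statistics; they stay in the graph.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must have an integer dtype")
    if scale <= 0:
        raise ValueError("scale must be positive")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size < 3:
        raise ValueError(f"mask has {labels.size} cells; at least 3 required")
    excluded_labels = set(excluded_labels or ())

    chains = _boundary_chains(mask)

    # Collect chain endpoints as tissue vertices (corner-grid coordinates).
    vert_index: dict[tuple[int, int], int] = {}
    vertices: list[tuple[float, float]] = []

    def _vid(corner: tuple[int, int]) -> int:
        if corner not in vert_index:
            vert_index[corner] = len(vertices)
            r, c = corner
            vertices.append(((c - 0.5) * scale, (r - 0.5) * scale))
        return vert_index[corner]

    junctions: list[Junction] = []
    border_cells: set[int] = set()
    jid = 0
    for (a, b), pair_chains in sorted(chains.items()):
        for pts in pair_chains:
            n_edges = len(pts) - 1
            if b == 0:
                border_cells.add(a)
            elif n_edges < 2:
                continue  # single-corner contact: not a real junction
            poly = np.array(
                [((c - 0.5) * scale, (r - 0.5) * scale) for r, c in pts], dtype=float
            )
            seglen = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
            junctions.append(
                Junction(
                    id=jid,
                    v1=_vid(pts[0]),
                    v2=_vid(pts[-1]),
                    cells=(int(a), None) if b == 0 else (int(a), int(b)),
                    polyline=poly,
                    length=seglen,
                )
            )
            jid += 1

    cells = _extract_cells(mask, labels, scale, border_cells, excluded_labels)
    fov = mask.size * scale**2 / 1e6  # mm²
    return Tissue(
        vertices=np.asarray(vertices, dtype=float),
        junctions=junctions,
        cells=cells,
        scale=scale,
        field_of_view_area=fov,
    )


# ----------------------------------------------------------------------

def _boundary_chains(mask: np.ndarray) -> dict[tuple[int, int], list[list[tuple[int, int]]]]:
    """Chain the pixel-corner boundary edges of every label pair.

    Returns {(a, b) with a < b or b == 0 → list of corner-point chains};
    each chain is a maximal path (or cycle) of unit edges on the corner
    grid shared by exactly that pair.  The outside of the image counts as
    label 0.
    """
    padded = np.pad(mask, 1, constant_values=0)
    edges: dict[tuple[int, int], list[tuple[tuple[int, int], tuple[int, int]]]] = defaultdict(list)

    # Vertical unit edges from horizontal label changes.
    diff = padded[:, :-1] != padded[:, 1:]
    for r, c in zip(*np.nonzero(diff)):
        a, b = int(padded[r, c]), int(padded[r, c + 1])
        pair = (min(a, b), max(a, b)) if 0 not in (a, b) else (max(a, b), 0)
        # corner column in original-mask corner coords = c (padded offset −1, corner +... )
        edges[pair].append(((r - 1, c), (r, c)))
    # Horizontal unit edges from vertical label changes.
    diff = padded[:-1, :] != padded[1:, :]
    for r, c in zip(*np.nonzero(diff)):
        a, b = int(padded[r, c]), int(padded[r + 1, c])
        pair = (min(a, b), max(a, b)) if 0 not in (a, b) else (max(a, b), 0)
        edges[pair].append(((r, c - 1), (r, c)))

    chains: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}
    for pair, es in edges.items():
        chains[pair] = _chain_edges(es)
    return chains


def _chain_edges(
    es: list[tuple[tuple[int, int], tuple[int, int]]]
) -> list[list[tuple[int, int]]]:
    """Greedily walk unit edges into maximal paths/cycles."""
    incid: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, (p, q) in enumerate(es):
        incid[p].append(i)
        incid[q].append(i)
    used = [False] * len(es)
    chains: list[list[tuple[int, int]]] = []

    def _walk(start_edge: int, start_pt: tuple[int, int]) -> list[tuple[int, int]]:
        chain = [start_pt]
        e, pt = start_edge, start_pt
        while True:
            used[e] = True
            p, q = es[e]
            pt = q if pt == p else p
            chain.append(pt)
            nxt = [i for i in incid[pt] if not used[i]]
            if not nxt:
                return chain
            e = nxt[0]

    # paths first (start at odd-degree corners), then remaining cycles
    for pt, inc in incid.items():
        if len(inc) % 2 == 1:
            for e in inc:
                if not used[e]:
                    chains.append(_walk(e, pt))
    for i, (p, _q) in enumerate(es):
        if not used[i]:
            chains.append(_walk(i, p))
    return chains


def _extract_cells(
    mask: np.ndarray,
    labels: np.ndarray,
    scale: float,
    border_cells: set[int],
    excluded_labels: set[int],
) -> dict[int, Cell]:
    cells: dict[int, Cell] = {}
    h, w = mask.shape
    props = {p.label: p for p in measure.regionprops(mask)}
    for lab in labels:
        lab = int(lab)
        p = props.get(lab)
        if p is None or p.area == 0:
            raise ValueError(f"label {lab} has zero area")
        r0, c0, r1, c1 = p.bbox
        sub = np.pad((mask[r0:r1, c0:c1] == lab).astype(np.uint8), 1)
        contours = measure.find_contours(sub, 0.5)
        outer = max(contours, key=len)
        # contour is (row, col) in padded-bbox coords; to pixel-center µm
        pts = np.column_stack(
            [(outer[:, 1] - 1 + c0) * scale, (outer[:, 0] - 1 + r0) * scale]
        )
        poly = Polygon(pts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        touches_edge = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cells[lab] = Cell(
            id=lab,
            polygon=pts,
            area=float(poly.area),
            perimeter=float(poly.length),
            centroid=np.array(poly.centroid.coords[0]),
            excluded=lab in excluded_labels or lab in border_cells or touches_edge,
        )
    return cells
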