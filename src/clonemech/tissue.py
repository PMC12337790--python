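"""Canonical planar-tissue representation.

A :class:`Tissue` is a polygonal tessellation of an epithelial monolayer:
2D vertices, junction polylines (each flanked by one or two cells), and
cell polygons carrying per-cell flags (clonal / apoptotic / excluded).
All geometry is stored in micrometres; the pixel→µm scale used at
ingestion is retained for provenance.

Junction classes relative to a set of clonal cells follow the standard
mosaic-analysis nomenclature: *internal* junctions separate two clonal
cells, *peripheral* junctions separate a clonal from a non-clonal cell,
*external* junctions separate two non-clonal cells.  Junctions on the
tissue border (a single flanking cell) are left unclassified and are
excluded from every statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import Polygon

INTERNAL = "internal"
PERIPHERAL = "peripheral"
EXTERNAL = "external"
JUNCTION_CLASSES = (INTERNAL, PERIPHERAL, EXTERNAL)


@dataclass
class Cell:
    """A single cell: outer boundary polygon plus flags.

    ``vertex_ids`` is the ordered ring of tissue vertex indices around the
    cell; it is populated for synthetic tessellations (where the
    combinatorics are known exactly) and ``None`` for mask-derived cells.
    """

    id: int
    polygon: np.ndarray  # (k, 2) outer boundary, µm
    area: float
    perimeter: float
    centroid: np.ndarray
    clonal: bool = False
    apoptotic: bool = False
    excluded: bool = False
    vertex_ids: list[int] | None = None


@dataclass
class Junction:
    """A cell-cell (or cell-border) interface.

    ``cells`` holds the one or two flanking cell ids; border junctions
    carry ``None`` in the second slot.  ``polyline`` runs from vertex
    ``v1`` to vertex ``v2`` in µm.
    """

    id: int
    v1: int
    v2: int
    cells: tuple[int, int | None]
    polyline: np.ndarray
    length: float

    @property
    def is_border(self) -> bool:
        return self.cells[1] is None


@dataclass
class Clone:
    """A connected set of clonal cells with derived union geometry."""

    id: int
    cell_ids: list[int]
    area: float
    perimeter: float
    e_int: int  # distinct adjacent clonal cell pairs inside the clone
    polygon: Polygon | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class Tissue:
    vertices: np.ndarray  # (V, 2) µm
    junctions: list[Junction]
    cells: dict[int, Cell]
    scale: float = 1.0  # µm per pixel at ingestion
    field_of_view_area: float = 0.0  # mm²
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = set(self.cells)
        for j in self.junctions:
            a, b = j.cells
            if a not in ids:
                raise ValueError(f"junction {j.id} flanks unknown cell {a}")
            if b is not None and (b not in ids or b == a):
                raise ValueError(f"junction {j.id} has invalid flank pair {j.cells}")
            if j.length <= 0:
                raise ValueError(f"junction {j.id} has non-positive length")
        for c in self.cells.values():
            if c.area <= 0 or c.perimeter <= 0:
                raise ValueError(f"cell {c.id} has non-positive area/perimeter")

    # ------------------------------------------------------------------
    def adjacency(self) -> nx.Graph:
        """Cell-adjacency graph; edges carry the shared junction ids."""
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.cells)
            for j in self.junctions:
                a, b = j.cells
                if b is None:
                    continue
                if g.has_edge(a, b):
                    g.edges[a, b]["junctions"].append(j.id)
                else:
                    g.add_edge(a, b, junctions=[j.id])
            self._graph = g
        return self._graph

    def invalidate_cache(self) -> None:
        self._graph = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def interior_junctions(self) -> list[Junction]:
        return [j for j in self.junctions if not j.is_border]

    def clonal_ids(self) -> set[int]:
        return {c.id for c in self.cells.values() if c.clonal}

    def vertex_junctions(self) -> dict[int, list[int]]:
        """Map vertex id → incident junction ids."""
        out: dict[int, list[int]] = {}
        for j in self.junctions:
            out.setdefault(j.v1, []).append(j.id)
            if j.v2 != j.v1:
                out.setdefault(j.v2, []).append(j.id)
        return out

    def free_vertices(self) -> list[int]:
        """Vertices whose every incident junction has two flanking cells.

        These are the interior vertices at which mechanical force balance
        is assembled, and the only vertices moved during foam relaxation —
        the two uses must share one definition.
        """
        incid = self.vertex_junctions()
        jmap = {j.id: j for j in self.junctions}
        return [
            v
            for v, jids in incid.items()
            if jids and all(not jmap[i].is_border for i in jids)
        ]


# ----------------------------------------------------------------------
# Junction classification and neighbor rings
# ----------------------------------------------------------------------

def classify_junctions(
    tissue: Tissue, clonal_ids: Iterable[int], min_length: float = 0.0
) -> dict[int, str]:
    """Classify every two-sided junction as internal/peripheral/external.

    Border junctions are omitted.  ``min_length`` (µm) drops junctions
    shorter than the optical resolution from the classification; the
    default keeps everything.
    """
    clonal = set(clonal_ids)
    unknown = clonal - set(tissue.cells)
    if unknown:
        raise ValueError(f"clonal ids not in tissue: {sorted(unknown)[:5]}")
    out: dict[int, str] = {}
    for j in tissue.junctions:
        if j.is_border or j.length < min_length:
            continue
        a, b = j.cells
        k = (a in clonal) + (b in clonal)
        out[j.id] = (EXTERNAL, PERIPHERAL, INTERNAL)[k]
    return out


def junction_class_counts(classes: Mapping[int, str]) -> dict[str, int]:
    counts = {c: 0 for c in JUNCTION_CLASSES}
    for c in classes.values():
        counts[c] += 1
    return counts


def neighbor_rings(
    tissue: Tissue, clonal_ids: Iterable[int], max_ring: int = 3
) -> dict[int, int]:
    """Graph distance of every cell to the nearest clonal cell.

    Clonal cells get ring 0; a cell sharing a junction with a clonal cell
    is ring +1, and so on by breadth-first search on the cell-adjacency
    graph.  Distances beyond ``max_ring`` are collapsed to
    ``max_ring + 1`` (read: ">max_ring"); unreachable cells get the same
    collapsed value.
    """
    clonal = set(clonal_ids)
    if not clonal:
        raise ValueError("clonal_ids must be non-empty")
    g = tissue.adjacency()
    dist = nx.multi_source_dijkstra_path_length(g, clonal & set(g), weight=None)
    cap = max_ring + 1
    return {cid: min(int(dist.get(cid, cap)), cap) for cid in tissue.cells}


def ring_label(ring: int, max_ring: int = 3) -> str:
    if ring == 0:
        return "0"
    if ring <= max_ring:
        return f"+{ring}"
    return f">+{max_ring}"


# ----------------------------------------------------------------------
# Clone extraction
# ----------------------------------------------------------------------

def find_clones(tissue: Tissue, clonal_ids: Iterable[int] | None = None) -> list[Clone]:
    """Connected components of the clonal-cell adjacency subgraph.

    Cells sharing only a vertex (no junction) fall in different clones.
    The union polygon keeps enclosed holes for the area but uses the
    outer boundary only for the perimeter, matching a contour-traced
    measurement.
    """
    clonal = set(clonal_ids) if clonal_ids is not None else tissue.clonal_ids()
    g = tissue.adjacency().subgraph(clonal)
    clones: list[Clone] = []
    for k, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        members = sorted(comp)
        union = _union_polygon(tissue, members)
        e_int = g.subgraph(comp).number_of_edges()
        clones.append(
            Clone(
                id=k,
                cell_ids=members,
                area=union.area,
                perimeter=union.exterior.length,
                e_int=e_int,
                polygon=union,
            )
        )
    return clones


def _union_polygon(tissue: Tissue, cell_ids: Sequence[int]) -> Polygon:
    import shapely
    from shapely.ops import unary_union

    polys = [
        shapely.set_precision(Polygon(tissue.cells[c].polygon).buffer(0), 1e-9)
        for c in cell_ids
    ]  # snap to a fine grid so exactly-shared edges merge robustly
    union = unary_union(polys)
    if union.geom_type == "MultiPolygon":
        # a residual sliver gap between touching polygons must not split
        # the clone: keep the dominant piece
        union = max(union.geoms, key=lambda p: p.area)
    return union


# ----------------------------------------------------------------------
# JSON interchange
# ----------------------------------------------------------------------

def tissue_to_json(tissue: Tissue) -> dict:
    return {
        "schema": "clonemech-tissue/1",
        "scale_um_per_px": tissue.scale,
        "field_of_view_area_mm2": tissue.field_of_view_area,
        "vertices": tissue.vertices.tolist(),
        "junctions": [
            {
                "id": j.id,
                "v1": j.v1,
                "v2": j.v2,
                "cells": [j.cells[0], j.cells[1]],
                "polyline": j.polyline.tolist(),
                "length_um": j.length,
            }
            for j in tissue.junctions
        ],
        "cells": [
            {
                "id": c.id,
                "polygon": c.polygon.tolist(),
                "area_um2": c.area,
                "perimeter_um": c.perimeter,
                "centroid": c.centroid.tolist(),
                "clonal": c.clonal,
                "apoptotic": c.apoptotic,
                "excluded": c.excluded,
                "vertex_ids": c.vertex_ids,
            }
            for c in tissue.cells.values()
        ],
    }


def tissue_from_json(doc: dict) -> Tissue:
    cells = {
        int(c["id"]): Cell(
            id=int(c["id"]),
            polygon=np.asarray(c["polygon"], dtype=float),
            area=float(c["area_um2"]),
            perimeter=float(c["perimeter_um"]),
            centroid=np.asarray(c["centroid"], dtype=float),
            clonal=bool(c["clonal"]),
            apoptotic=bool(c["apoptotic"]),
            excluded=bool(c["excluded"]),
            vertex_ids=list(c["vertex_ids"]) if c.get("vertex_ids") is not None else None,
        )
        for c in doc["cells"]
    }
    junctions = [
        Junction(
            id=int(j["id"]),
            v1=int(j["v1"]),
            v2=int(j["v2"]),
            cells=(int(j["cells"][0]), None if j["cells"][1] is None else int(j["cells"][1])),
            polyline=np.asarray(j["polyline"], dtype=float),
            length=float(j["length_um"]),
        )
        for j in doc["junctions"]
    ]
    return Tissue(
        vertices=np.asarray(doc["vertices"], dtype=float),
        junctions=junctions,
        cells=cells,
        scale=float(doc["scale_um_per_px"]),
        field_of_view_area=float(doc["field_of_view_area_mm2"]),
    )


def save_tissue(tissue: Tissue, path) -> None:
    with open(path, "w") as fh:
        json.dump(tissue_to_json(tissue), fh)


def load_tissue(path) -> Tissue:
    with open(path) as fh:
        return tissue_from_json(json.load(fh))
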