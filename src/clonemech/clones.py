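"""Clone shape and sorting statistics.

Two complementary readouts of cell sorting are computed per clone:

* **circularity** C = 4πA/P² of the clone union outline (1 for a perfect
  circle, → 0 for elongated shapes);
* **connectivity index** K = 2·E_int/n, the mean number of homotypic
  (clonal–clonal) contacts per clonal cell, compared against the
  theoretical ceiling K_max(n) attained by maximally compact polyhexes
  on the regular hexagonal tiling — the cellular idealization of minimal
  soap-bubble clusters.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import _hex
from .tissue import Clone, Tissue


def circularity(clone: Clone | Polygon, smooth: bool = False) -> float:
    """Circularity index 4πA/P² of the clone union outline.

    ``smooth`` applies one pass of corner-cutting (Chaikin) smoothing to
    the outer boundary before measuring, which compensates the staircase
    perimeter bias of pixelated outlines; leave it off for exact
    polygonal tessellations.  The area is taken from the same (smoothed)
    outline so the index stays ≤ 1 within discretization tolerance.
    """
    poly = clone.polygon if isinstance(clone, Clone) else clone
    if poly is None or poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate clone outline (zero area)")
    ring = np.asarray(poly.exterior.coords)[:-1]
    if smooth:
        ring = chaikin(ring)
    outline = Polygon(ring)
    a, p = outline.area, outline.exterior.length
    if p <= 0:
        raise ValueError("degenerate clone outline (zero perimeter)")
    return 4.0 * math.pi * a / p**2


def circularity_from_area_perimeter(area: float, perimeter: float) -> float:
    """4πA/P² for an outline known only through its area and perimeter."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def chaikin(ring: np.ndarray, n_pass: int = 1) -> np.ndarray:
    """Corner-cutting smoothing of a closed ring (Chaikin's 1/4–3/4 rule)."""
    pts = np.asarray(ring, dtype=float)
    for _ in range(n_pass):
        q = np.roll(pts, -1, axis=0)
        a = 0.75 * pts + 0.25 * q
        b = 0.25 * pts + 0.75 * q
        pts = np.empty((2 * len(a), 2))
        pts[0::2] = a
        pts[1::2] = b
    return pts


def connectivity_index(clone: Clone) -> float:
    """Mean homotypic contacts per clonal cell, K = 2·E_int/n."""
    return 2.0 * clone.e_int / clone.n_cells


def max_connectivity(n: int) -> float:
    """Theoretical ceiling K_max(n) = 2·E_max(n)/n.

    E_max(n) is the maximum adjacent-pair count among n cells of the
    regular hexagonal tiling, 3n − ⌈√(12n−3)⌉ — attained by compact
    spiral polyhexes and confirmed by exhaustive polyhex search for
    n ≤ 10 (see :func:`clonemech._hex.max_internal_edges_exhaustive`).
    """
    if n < 1:
        raise ValueError("clone size must be ≥ 1")
    return 2.0 * _hex.max_internal_edges(n) / n


def clone_density(tissue: Tissue, clones: Sequence[Clone]) -> float:
    """Clones per mm² of analyzable field (excluded-cell area subtracted)."""
    excluded = sum(c.area for c in tissue.cells.values() if c.excluded) / 1e6
    area = tissue.field_of_view_area - excluded
    if area <= 0:
        raise ValueError("no analyzable field area")
    return len(clones) / area


def clone_size_table(
    clones: Sequence[Clone], genotype: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Clone-size histogram plus mean ± sd of cells per clone, per genotype."""
    tags = [genotype.get(c.id, "all") if genotype else "all" for c in clones]
    df = pd.DataFrame({"genotype": tags, "n_cells": [c.n_cells for c in clones]})
    hist = (
        df.groupby(["genotype", "n_cells"]).size().rename("count").reset_index()
    )
    summary = (
        df.groupby("genotype")["n_cells"]
        .agg(n_clones="size", mean_cells="mean", sd_cells="std")
        .reset_index()
    )
    return hist.merge(summary, on="genotype")


def clone_metrics_table(
    tissue: Tissue,
    clones: Sequence[Clone],
    smooth: bool = False,
) -> pd.DataFrame:
    """Per-clone metrics: size, union geometry, circularity, connectivity."""
    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.id,
                "n_cells": c.n_cells,
                "A_um2": c.area,
                "P_um": c.perimeter,
                "circularity": circularity(c, smooth=smooth),
                "connectivity": connectivity_index(c),
                "K_max": max_connectivity(c.n_cells),
            }
        )
    return pd.DataFrame(rows)
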