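"""Spatial apoptosis statistics around clones.

The null model is random sampling without replacement: with N cells in
the image, m of them in a category of interest (the clone, or the ring
of cells at a given graph distance from it) and n apoptotic cells in
total, the count of apoptotic cells falling in the category is
hypergeometric,

    P(X = k) = C(m, k) · C(N − m, n − k) / C(N, n),

and the *expected* count is taken as the mode k* of this distribution
(ties broken toward the smaller k).  Each ring is tested marginally
against its own hypergeometric; excluded cells (sensory organs, border
cells, debris) are removed from N, m and n consistently.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import _hex
from .tissue import Clone, Tissue, neighbor_rings, ring_label


def hypergeom_pmf(N: int, m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf over the feasible support k ∈ [max(0, n−(N−m)), min(m, n)]."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("need 0 ≤ m ≤ N and 0 ≤ n ≤ N")
    k = np.arange(max(0, n - (N - m)), min(m, n) + 1)
    pmf = hypergeom.pmf(k, N, m, n)
    return k, pmf / pmf.sum()


def expected_count(N: int, m: int, n: int) -> int:
    """Mode k* of the hypergeometric pmf (smaller k wins ties)."""
    k, pmf = hypergeom_pmf(N, m, n)
    return int(k[int(np.argmax(pmf))])


def ring_cell_counts(
    clone_size: int | None = None,
    mode: str = "hex-approx",
    tissue: Tissue | None = None,
    clonal_ids: Iterable[int] | None = None,
    max_ring: int = 3,
) -> dict[int, int]:
    """Cells per ring {1: m₁, 2: m₂, ...} around a clone.

    ``hex-approx`` builds a maximally compact (spiral) polyhex of
    ``clone_size`` cells on the regular hexagonal tiling and counts its
    breadth-first rings — the idealization used when only the average
    clone size is known.  ``measured`` tallies rings on the actual
    tissue graph (excluded cells omitted).
    """
    if mode == "hex-approx":
        if clone_size is None or clone_size < 1:
            raise ValueError("hex-approx mode needs clone_size ≥ 1")
        return _hex.bfs_rings(_hex.spiral(clone_size), max_ring=max_ring)
    if mode == "measured":
        if tissue is None or clonal_ids is None:
            raise ValueError("measured mode needs tissue and clonal_ids")
        rings = neighbor_rings(tissue, clonal_ids, max_ring=max_ring)
        counts: dict[int, int] = {}
        for cid, r in rings.items():
            if tissue.cells[cid].excluded:
                continue
            counts[r] = counts.get(r, 0) + 1
        return counts
    raise ValueError(f"unknown mode {mode!r}")


def clone_apoptosis_fraction(
    clones: Sequence[Clone], apoptotic_ids: Iterable[int]
) -> float:
    """Percentage of clones containing at least one apoptotic cell."""
    if not clones:
        raise ValueError("no clones")
    apo = set(apoptotic_ids)
    hit = sum(1 for c in clones if apo & set(c.cell_ids))
    return 100.0 * hit / len(clones)


def ring_table(
    tissue: Tissue,
    clonal_ids: Iterable[int],
    apoptotic_ids: Iterable[int],
    max_ring: int = 3,
) -> pd.DataFrame:
    """Observed vs hypergeometric-expected apoptosis per ring.

    One row per ring r ∈ {0, +1, ..., >max_ring}: cells m_r, observed
    apoptotic count o_r, expected k*_r = mode of Hypergeom(N, m_r, n),
    and the percentage of apoptotic cells falling in the ring.  N and n
    count non-excluded cells only.
    """
    apo = {a for a in apoptotic_ids if not tissue.cells[a].excluded}
    rings = neighbor_rings(tissue, clonal_ids, max_ring=max_ring)
    m: dict[int, int] = {}
    o: dict[int, int] = {}
    for cid, r in rings.items():
        if tissue.cells[cid].excluded:
            continue
        m[r] = m.get(r, 0) + 1
        if cid in apo:
            o[r] = o.get(r, 0) + 1
    N = sum(m.values())
    n = len(apo)
    rows = []
    for r in sorted(m):
        rows.append(
            {
                "ring": ring_label(r, max_ring),
                "ring_index": r,
                "m_cells": m[r],
                "observed": o.get(r, 0),
                "expected_kstar": expected_count(N, m[r], n),
                "pct_dcp1": 100.0 * o.get(r, 0) / n if n else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["N"] = N
    df.attrs["n_dcp1"] = n
    return df


def normalize_across_groups(
    per_image: pd.DataFrame,
    group_col: str = "group",
    total_col: str = "total_dcp1",
    pct_col: str = "pct_dcp1",
) -> pd.DataFrame:
    """Rescale per-image ring percentages for cross-genotype comparison.

    Each group's percentages are multiplied by (grand mean of the total
    apoptotic count across groups) / (that group's mean total), so
    genotypes with globally more cell death are put on a common footing.
    """
    df = per_image.copy()
    group_means = df.groupby(group_col)[total_col].mean()
    grand = float(group_means.mean())
    factor = df[group_col].map(grand / group_means)
    df["normalized_pct"] = df[pct_col] * factor
    df["group_mean_total"] = df[group_col].map(group_means)
    return df
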