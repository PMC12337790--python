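"""Relative junction-tension inference from tissue geometry.

At mechanical equilibrium every interior tri-cellular vertex satisfies a
force balance: the tensions of its incident junctions, pulling along the
junction chords, sum to zero (plus pressure terms if enabled).  Stacking
the two (x, y) balance equations of every interior vertex gives a linear
system B·T ≈ 0 in the unknown junction tensions, determined only up to
scale.  Tensions are estimated by ridge-regularized least squares with a
unit-mean prior,

    T̂ = argmin ‖B·T‖² + μ‖T − 1‖²   subject to   mean(T) = 1,

the regularization weight μ playing the role of the prior strength
(values below 1 are typical for well-segmented tissues).  The output is
a dimensionless relative tension map, mean 1 by gauge fixing; negative
inferred tensions are flagged, never clipped — they diagnose
ill-conditioned regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lstsq, null_space

from .tissue import Tissue, classify_junctions


@dataclass
class InferenceProblem:
    """Assembled vertex force-balance system.

    ``B`` has two rows (x, y) per interior vertex and one column per
    two-sided junction; entries are unit chord-direction components.
    ``Bp`` (optional) holds the pressure columns, one per cell.
    """

    B: np.ndarray
    junction_ids: list[int]
    vertex_ids: list[int]
    mu: float
    Bp: np.ndarray | None = None
    cell_ids: list[int] | None = None


@dataclass
class ForceMap:
    """Relative junction tensions (mean 1) and optional cell pressures."""

    tensions: dict[int, float]
    negative: set[int] = field(default_factory=set)
    pressures: dict[int, float] | None = None

    def as_array(self, junction_ids: Sequence[int]) -> np.ndarray:
        return np.array([self.tensions[j] for j in junction_ids])


def balance_residual(
    tissue: Tissue,
    tensions: Mapping[int, float],
    pressures: Mapping[int, float] | None = None,
) -> dict[int, np.ndarray]:
    """Net force at every interior vertex for given tensions (+ pressures).

    Tensions pull along junction chords; pressure differences push along
    edge normals with half the edge length attributed to each endpoint.
    This is the single force-balance definition shared by the synthetic
    foam relaxation (which drives it to zero) and by inference (which
    assembles it into B).
    """
    out: dict[int, np.ndarray] = {}
    for v in tissue.free_vertices():
        out[v] = np.zeros(2)
    for j in tissue.junctions:
        if j.v1 not in out and j.v2 not in out:
            continue
        t = tensions.get(j.id, 0.0)
        chord = tissue.vertices[j.v2] - tissue.vertices[j.v1]
        n = np.linalg.norm(chord)
        if n == 0:
            continue
        u = chord / n
        if j.v1 in out:
            out[j.v1] += t * u
        if j.v2 in out:
            out[j.v2] -= t * u
        if pressures is not None and not j.is_border:
            a, b = j.cells
            normal = np.array([-chord[1], chord[0]]) / n
            mid = 0.5 * (tissue.vertices[j.v1] + tissue.vertices[j.v2])
            if np.dot(normal, tissue.cells[a].centroid - mid) > 0:
                normal = -normal  # orient from cell a toward cell b
            f = 0.5 * n * (pressures.get(a, 0.0) - pressures.get(b, 0.0)) * normal
            if j.v1 in out:
                out[j.v1] += f
            if j.v2 in out:
                out[j.v2] += f
    return out


def assemble_balance(
    tissue: Tissue, with_pressure: bool = False, mu: float = 0.1
) -> InferenceProblem:
    """Build the force-balance matrix over interior vertices.

    Chord (straight-segment) directions are used for the junction pull;
    pressure terms, if enabled, act along edge normals with the edge
    length split between its endpoints.
    """
    free = tissue.free_vertices()
    if not free:
        raise ValueError("tissue has no interior vertex")
    junctions = [j for j in tissue.junctions if not j.is_border]
    jcol = {j.id: k for k, j in enumerate(junctions)}
    vrow = {v: 2 * k for k, v in enumerate(free)}
    B = np.zeros((2 * len(free), len(junctions)))
    for j in junctions:
        p1, p2 = tissue.vertices[j.v1], tissue.vertices[j.v2]
        chord = p2 - p1
        n = np.linalg.norm(chord)
        if n == 0:
            continue
        u = chord / n
        if j.v1 in vrow:
            B[vrow[j.v1] : vrow[j.v1] + 2, jcol[j.id]] += u
        if j.v2 in vrow:
            B[vrow[j.v2] : vrow[j.v2] + 2, jcol[j.id]] -= u

    Bp = None
    cell_ids = None
    if with_pressure:
        cell_ids = sorted(tissue.cells)
        ccol = {c: k for k, c in enumerate(cell_ids)}
        Bp = np.zeros((2 * len(free), len(cell_ids)))
        for j in junctions:
            a, b = j.cells
            p1, p2 = tissue.vertices[j.v1], tissue.vertices[j.v2]
            chord = p2 - p1
            n = np.linalg.norm(chord)
            if n == 0:
                continue
            normal = np.array([-chord[1], chord[0]]) / n  # 90° CCW of chord
            mid = 0.5 * (p1 + p2)
            if np.dot(normal, tissue.cells[a].centroid - mid) > 0:
                normal = -normal  # point from cell a toward cell b
            for v in (j.v1, j.v2):
                if v in vrow:
                    Bp[vrow[v] : vrow[v] + 2, ccol[a]] += 0.5 * n * normal
                    Bp[vrow[v] : vrow[v] + 2, ccol[b]] -= 0.5 * n * normal
    return InferenceProblem(
        B=B, junction_ids=[j.id for j in junctions], vertex_ids=free, mu=mu,
        Bp=Bp, cell_ids=cell_ids,
    )


def infer_tensions(problem: InferenceProblem) -> ForceMap:
    """Solve the ridge-regularized balance system under mean(T) = 1.

    The unit-mean gauge is enforced exactly by parametrizing
    T = 1 + P·z with P an orthonormal basis of the mean-zero subspace.
    With μ = 0 the system must be identifiable on that subspace, else an
    error instructs choosing μ > 0.
    """
    B = problem.B
    nj = B.shape[1]
    if problem.mu < 0:
        raise ValueError("mu must be ≥ 0")
    P = null_space(np.ones((1, nj)))  # nj × (nj−1), orthonormal, mean-zero columns
    ones = np.ones(nj)
    BP = B @ P
    rhs0 = -B @ ones
    if problem.Bp is not None:
        npc = problem.Bp.shape[1]
        A = np.block(
            [
                [BP, problem.Bp],
                [np.sqrt(max(problem.mu, 1e-12)) * np.eye(nj - 1), np.zeros((nj - 1, npc))],
                [np.zeros((npc, nj - 1)), np.sqrt(max(problem.mu, 1e-12)) * np.eye(npc)],
            ]
        )
        b = np.concatenate([rhs0, np.zeros(nj - 1 + npc)])
        sol, _, rank, _ = lstsq(A, b)
        z, p = sol[: nj - 1], sol[nj - 1 :]
        p = p - p.mean()
        pressures = dict(zip(problem.cell_ids, p))
    else:
        if problem.mu == 0:
            sol, _, rank, _ = lstsq(BP, rhs0)
            if rank < nj - 1:
                raise ValueError(
                    "balance system is rank-deficient under the mean-1 gauge; "
                    "use mu > 0 to regularize"
                )
            z = sol
        else:
            A = np.vstack([BP, np.sqrt(problem.mu) * np.eye(nj - 1)])
            b = np.concatenate([rhs0, np.zeros(nj - 1)])
            z, _, _, _ = lstsq(A, b)
        pressures = None
    T = ones + P @ z
    tensions = dict(zip(problem.junction_ids, T.astype(float)))
    negative = {j for j, t in tensions.items() if t < 0}
    return ForceMap(tensions=tensions, negative=negative, pressures=pressures)


def zone_tensions(
    forcemap: ForceMap, tissue: Tissue, clonal_ids: Iterable[int]
) -> pd.DataFrame:
    """Inferred tensions grouped by junction class around the clone.

    Returns one row per classified junction (internal / peripheral /
    external) with its inferred tension; summarize with
    :func:`zone_summary` (medians and quartiles, matching how relative
    tensions are conventionally reported).
    """
    classes = classify_junctions(tissue, clonal_ids)
    rows = [
        {"junction_id": j, "cls": c, "tension": forcemap.tensions[j],
         "warn_negative": j in forcemap.negative}
        for j, c in classes.items()
        if j in forcemap.tensions
    ]
    return pd.DataFrame(rows)


def zone_summary(zones: pd.DataFrame) -> pd.DataFrame:
    return (
        zones.groupby("cls")["tension"]
        .agg(
            n="size",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )


def randomization_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for the difference of medians.

    p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (1 + n_perm), the add-one estimate
    that never returns zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    obs = abs(np.median(a) - np.median(b))
    pool = np.concatenate([a, b])
    na = a.size
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        d = abs(np.median(pool[:na]) - np.median(pool[na:]))
        if d >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
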