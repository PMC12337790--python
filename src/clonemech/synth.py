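"""Synthetic epithelium generator.

Everything the downstream analyses consume can be generated here with
known ground truth: near-hexagonal polygonal monolayers (exact hexagonal
lattice or Lloyd-relaxed Voronoi), planted clones of tunable compactness,
painted junction-intensity images with per-class enrichment, exponential
recoil traces at the experimental frame cadence, mechanically
equilibrated foams with planted junction tensions, and apoptotic cells
placed uniformly without replacement (the hypergeometric null) or with
ring-biased odds.  Every generator is fully deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from . import _hex
from .forces import ForceMap, balance_residual
from .recoil import RecoilTrace, relaxation_model
from .tissue import Cell, Junction, Tissue, neighbor_rings

DEFAULT_CELL_AREA_UM2 = 16.0  # apical area of a pupal notum epidermal cell (~4.5 µm across)
MARGIN_UM = 2.0


# ----------------------------------------------------------------------
# Configuration (used by the CLI; library functions take plain arguments)
# ----------------------------------------------------------------------

@dataclass
class CloneSpec:
    count: int = 5
    sizes: list[int] | None = None  # explicit sizes; else sampled from size_p over 1..10
    size_p: float = 0.3  # truncated-geometric parameter for 1..10-cell clones
    compactness: float = 0.0


@dataclass
class IntensitySpec:
    baseline_mean: float = 100.0
    noise_sigma: float = 10.0
    internal_factor: float = 1.5
    peripheral_factor: float = 2.0
    px: float = 0.2  # µm per image pixel


@dataclass
class RecoilSpec:
    d_inf_norm: float = 0.3
    tau: float = 10.0  # s
    t0: float = 7.5  # s (after 5 pre-ablation frames)
    lc: float = 3.0  # µm
    dt: float = 1.5  # s frame cadence
    pre_window: float = 7.5  # s
    post_window: float = 60.0  # s (acquisitions ran 55.5–79.5 s post-cut)
    noise_sigma: float = 0.0  # µm


@dataclass
class TensionSpec:
    sigma: float = 0.2  # lognormal spread of planted tensions (mean 1)


@dataclass
class ApoptosisSpec:
    n_dcp1: int = 20
    placement: str = "uniform"  # or "ring-biased"
    ring_odds: dict = field(default_factory=lambda: {0: 3.0, 1: 3.0})


@dataclass
class SynthConfig:
    n_cells: int = 400
    seed: int = 0
    lattice: str = "relaxed-voronoi"  # or "hexagonal"
    clones: CloneSpec = field(default_factory=CloneSpec)
    intensity: IntensitySpec = field(default_factory=IntensitySpec)
    recoil: RecoilSpec = field(default_factory=RecoilSpec)
    tension: TensionSpec = field(default_factory=TensionSpec)
    apoptosis: ApoptosisSpec = field(default_factory=ApoptosisSpec)

    @classmethod
    def from_dict(cls, doc: dict) -> "SynthConfig":
        kw = dict(doc)
        for name, sub in (
            ("clones", CloneSpec),
            ("intensity", IntensitySpec),
            ("recoil", RecoilSpec),
            ("tension", TensionSpec),
            ("apoptosis", ApoptosisSpec),
        ):
            if name in kw:
                kw[name] = sub(**kw[name])
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ----------------------------------------------------------------------
# Tessellation generators
# ----------------------------------------------------------------------

def generate_epithelium(cfg: SynthConfig) -> Tissue:
    if cfg.n_cells < 9:
        raise ValueError("need at least 9 cells")
    if cfg.lattice == "hexagonal":
        return hexagonal_tissue(cfg.n_cells)
    if cfg.lattice == "relaxed-voronoi":
        return voronoi_tissue(cfg.n_cells, seed=cfg.seed)
    raise ValueError(f"unknown lattice type {cfg.lattice!r}")


def hexagonal_tissue(
    n_cells: int, cell_area: float = DEFAULT_CELL_AREA_UM2
) -> Tissue:
    """Exact regular hexagonal lattice of ≈ n_cells pointy-top hexagons."""
    side = float(np.sqrt(2.0 * cell_area / (3.0 * np.sqrt(3.0))))
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    axial: dict[tuple[int, int], int] = {}
    k = 0
    for i in range(rows):
        for jj in range(cols):
            if k >= n_cells:
                break
            axial[(jj - i // 2, i)] = k
            k += 1

    def center(q: int, r: int) -> np.ndarray:
        return np.array([np.sqrt(3.0) * side * (q + r / 2.0), 1.5 * side * r])

    def corners(q: int, r: int) -> np.ndarray:
        ang = np.deg2rad(60.0 * np.arange(6) + 30.0)
        return center(q, r) + side * np.column_stack([np.cos(ang), np.sin(ang)])

    all_corners = {qr: corners(*qr) for qr in axial}
    shift = MARGIN_UM - np.min([c.min(axis=0) for c in all_corners.values()], axis=0)
    vert_index: dict[tuple[int, int], int] = {}
    vertices: list[np.ndarray] = []

    def vid(p: np.ndarray) -> int:
        key = (round(float(p[0]) * 1e6), round(float(p[1]) * 1e6))
        if key not in vert_index:
            vert_index[key] = len(vertices)
            vertices.append(p)
        return vert_index[key]

    cells: dict[int, Cell] = {}
    junctions: list[Junction] = []
    jid = 0
    for (q, r), cid in axial.items():
        pts = all_corners[(q, r)] + shift
        ids = [vid(p) for p in pts]
        poly = Polygon(pts)
        nb = [_hex_nb for _hex_nb in _hex.neighbors((q, r))]
        border = any(x not in axial for x in nb)
        cells[cid] = Cell(
            id=cid,
            polygon=pts,
            area=float(poly.area),
            perimeter=float(poly.length),
            centroid=np.array(poly.centroid.coords[0]),
            excluded=border,
            vertex_ids=ids,
        )
    # junction per hex edge (corner k → corner k+1); shared with one neighbor
    for (q, r), cid in axial.items():
        pts = all_corners[(q, r)] + shift
        ids = cells[cid].vertex_ids
        assert ids is not None
        for k6 in range(6):
            a, b = ids[k6], ids[(k6 + 1) % 6]
            nb_id = _edge_partner(axial, all_corners, shift, (q, r), k6)
            if nb_id is not None and nb_id < cid:
                continue  # already created from the partner side
            seg = np.vstack([vertices[a], vertices[b]])
            junctions.append(
                Junction(
                    id=jid,
                    v1=a,
                    v2=b,
                    cells=(cid, nb_id) if nb_id is not None else (cid, None),
                    polyline=seg,
                    length=float(np.linalg.norm(seg[1] - seg[0])),
                )
            )
            jid += 1
    fov = sum(c.area for c in cells.values()) / 1e6
    return Tissue(
        vertices=np.asarray(vertices),
        junctions=junctions,
        cells=cells,
        scale=1.0,
        field_of_view_area=fov,
    )


def _edge_partner(axial, all_corners, shift, qr, k6) -> int | None:
    """Neighbor cell sharing hex edge (corner k6, k6+1), if present."""
    pts = all_corners[qr] + shift
    a, b = pts[k6], pts[(k6 + 1) % 6]
    mid = 0.5 * (a + b)
    for nb in _hex.neighbors(qr):
        if nb not in axial:
            continue
        npts = all_corners[nb] + shift
        d = np.linalg.norm(npts - mid, axis=1)
        # neighbor shares this edge iff two of its corners coincide with a, b
        if np.sort(d)[1] < 1e-6 + np.linalg.norm(b - a):
            if (
                np.min(np.linalg.norm(npts - a, axis=1)) < 1e-6
                and np.min(np.linalg.norm(npts - b, axis=1)) < 1e-6
            ):
                return axial[nb]
    return None


def voronoi_tissue(
    n_cells: int,
    cell_area: float = DEFAULT_CELL_AREA_UM2,
    seed: int | None = None,
    lloyd_iters: int = 5,
) -> Tissue:
    """Lloyd-relaxed Voronoi monolayer in a square box.

    Seed points are mirrored across the box edges so every region is
    finite; cells whose region touches the box boundary are flagged
    excluded (their polygons are truncated by the mirror construction).
    """
    rng = np.random.default_rng(seed)
    L = float(np.sqrt(n_cells * cell_area))
    pts = rng.uniform(0.0, L, size=(n_cells, 2))
    for _ in range(lloyd_iters):
        vor = Voronoi(_mirror(pts, L))
        new = np.empty_like(pts)
        for i in range(n_cells):
            region = vor.regions[vor.point_region[i]]
            poly = _ordered_region(vor, region, pts[i])
            new[i] = Polygon(poly).centroid.coords[0]
        pts = new

    vor = Voronoi(_mirror(pts, L))
    used: dict[int, int] = {}
    vertices: list[np.ndarray] = []

    def vid(i: int) -> int:
        if i not in used:
            used[i] = len(vertices)
            vertices.append(vor.vertices[i] + MARGIN_UM)
        return used[i]

    cells: dict[int, Cell] = {}
    border: set[int] = set()
    junctions: list[Junction] = []
    jid = 0
    for (pa, pb), rv in zip(vor.ridge_points, vor.ridge_vertices):
        a, b = int(pa), int(pb)
        if a >= n_cells and b >= n_cells:
            continue
        if a > b:
            a, b = b, a
        v1, v2 = int(rv[0]), int(rv[1])
        if v1 < 0 or v2 < 0:  # cannot happen with mirroring, but be safe
            continue
        flank = (a, b) if b < n_cells else (a, None)
        if flank[1] is None:
            border.add(a)
        seg = np.vstack([vor.vertices[v1] + MARGIN_UM, vor.vertices[v2] + MARGIN_UM])
        length = float(np.linalg.norm(seg[1] - seg[0]))
        if length <= 0:
            continue
        junctions.append(
            Junction(
                id=jid, v1=vid(v1), v2=vid(v2), cells=flank,
                polyline=seg, length=length,
            )
        )
        jid += 1
    for i in range(n_cells):
        region = vor.regions[vor.point_region[i]]
        ordered = _ordered_region_ids(vor, region, pts[i])
        poly_pts = vor.vertices[ordered] + MARGIN_UM
        poly = Polygon(poly_pts)
        cells[i] = Cell(
            id=i,
            polygon=poly_pts,
            area=float(poly.area),
            perimeter=float(poly.length),
            centroid=np.array(poly.centroid.coords[0]),
            excluded=i in border,
            vertex_ids=[vid(v) for v in ordered],
        )
    return Tissue(
        vertices=np.asarray(vertices),
        junctions=junctions,
        cells=cells,
        scale=1.0,
        field_of_view_area=L * L / 1e6,
    )


def _mirror(pts: np.ndarray, L: float) -> np.ndarray:
    refl = [pts]
    for axis, bound in ((0, 0.0), (0, L), (1, 0.0), (1, L)):
        m = pts.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        refl.append(m)
    return np.vstack(refl)


def _ordered_region_ids(vor: Voronoi, region: list[int], center: np.ndarray) -> list[int]:
    vs = np.array([vor.vertices[v] for v in region])
    ang = np.arctan2(vs[:, 1] - center[1], vs[:, 0] - center[0])
    return [region[k] for k in np.argsort(ang)]


def _ordered_region(vor: Voronoi, region: list[int], center: np.ndarray) -> np.ndarray:
    return vor.vertices[_ordered_region_ids(vor, region, center)]


# ----------------------------------------------------------------------
# Clone planting
# ----------------------------------------------------------------------

def plant_clones(
    tissue: Tissue,
    sizes: list[int],
    compactness: float = 0.0,
    seed: int | None = None,
    max_tries: int = 200,
) -> list[list[int]]:
    """Plant pairwise non-adjacent connected clones and set clonal flags.

    ``compactness`` interpolates the connected-set ensemble: 0 draws
    unbiased naive-growth sets, 1 deterministically builds the
    maximally connected (most compact) set, and intermediate values use
    rejection sampling with acceptance weight exp(β·E_int), β increasing
    with compactness.
    """
    if not 0.0 <= compactness <= 1.0:
        raise ValueError("compactness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = tissue.adjacency()
    centroids = {c.id: c.centroid for c in tissue.cells.values()}
    pre = tissue.clonal_ids()
    halo = pre | {n for m in pre if m in g for n in g[m]}
    eligible = {
        c.id for c in tissue.cells.values() if not c.excluded and c.id not in halo
    }
    out: list[list[int]] = []
    for size in sizes:
        if size < 1 or size > len(eligible):
            raise ValueError(f"cannot place a clone of {size} cells")
        if compactness >= 1.0:
            members = _max_connected_clone(g, eligible, size, centroids, rng)
        else:
            members = _sampled_clone(g, eligible, size, compactness, rng, max_tries)
        if members is None:
            raise RuntimeError(f"could not place a clone of {size} cells")
        out.append(sorted(members))
        for m in members:
            tissue.cells[m].clonal = True
        halo = members | {n for m in members for n in g[m]}
        eligible -= halo
    return out


def _max_connected_clone(g, eligible, size, centroids, rng):
    """Beam search for the connected set maximizing internal edges.

    On the hexagonal lattice this recovers the maximal polyhex
    (spiral-equivalent) for all small sizes; ties are broken toward the
    tightest cluster around the seed cell.
    """
    starts = list(eligible)
    rng.shuffle(starts)
    for start in starts[:30]:
        c0 = centroids[start]
        beam: list[tuple[int, float, frozenset]] = [(0, 0.0, frozenset([start]))]
        for _ in range(size - 1):
            seen: set[frozenset] = set()
            nxt: list[tuple[int, float, frozenset]] = []
            for e, _, S in beam:
                cand = {n for m in S for n in g[m] if n in eligible} - S
                for c in cand:
                    S2 = S | {c}
                    if S2 in seen:
                        continue
                    seen.add(S2)
                    e2 = e + sum(1 for n in g[c] if n in S)
                    spread = max(
                        float(np.linalg.norm(centroids[m] - c0)) for m in S2
                    )
                    nxt.append((e2, spread, frozenset(S2)))
            if not nxt:
                break
            nxt.sort(key=lambda t: (-t[0], t[1]))
            beam = nxt[:16]
        if beam and len(beam[0][2]) == size:
            return set(beam[0][2])
    return None


def _sampled_clone(g, eligible, size, compactness, rng, max_tries):
    beta = min(4.0 * compactness / max(1.0 - compactness, 1e-9), 3.0)
    e_ub = _hex.max_internal_edges(size)
    best, best_e = None, -1
    for _ in range(max_tries):
        S = _naive_growth(g, eligible, size, rng)
        if S is None:
            continue
        e = sum(1 for a in S for b in g[a] if b in S) // 2
        if beta == 0.0 or rng.random() < np.exp(beta * min(e - e_ub, 0.0)):
            return S
        if e > best_e:
            best, best_e = S, e
    return best  # rejection budget exhausted: most compact draw seen


def _naive_growth(g, eligible, size, rng):
    start = rng.choice(sorted(eligible))
    S = {int(start)}
    while len(S) < size:
        frontier = sorted({n for m in S for n in g[m] if n in eligible} - S)
        if not frontier:
            return None
        S.add(int(frontier[rng.integers(len(frontier))]))
    return S


# ----------------------------------------------------------------------
# Intensity painting
# ----------------------------------------------------------------------

def paint_junction_image(
    tissue: Tissue,
    classes: dict[int, str],
    spec: IntensitySpec | None = None,
    seed: int | None = None,
    paint_halfwidth_px: float = 2.0,
    psf_sigma_px: float = 0.0,
) -> tuple[np.ndarray, dict[int, float]]:
    """Render junctions onto a noisy image; return it with ground truth.

    Each junction band (half-width ``paint_halfwidth_px``) is set to its
    class amplitude — baseline for external/border, baseline × the class
    enrichment factor otherwise — composing overlaps at shared vertices
    with the maximum.  Optional gaussian PSF smoothing and additive
    gaussian pixel noise follow.  Returns (image, {junction_id: planted
    band amplitude}).
    """
    from scipy.ndimage import gaussian_filter

    from .tissue import INTERNAL, PERIPHERAL
    from .intensity import polyline_band

    spec = spec or IntensitySpec()
    rng = np.random.default_rng(seed)
    px = spec.px
    hi = tissue.vertices.max(axis=0) + MARGIN_UM
    shape = (int(np.ceil(hi[1] / px)) + 1, int(np.ceil(hi[0] / px)) + 1)
    factors = {INTERNAL: spec.internal_factor, PERIPHERAL: spec.peripheral_factor}
    image = np.full(shape, 0.2 * spec.baseline_mean, dtype=float)
    gt: dict[int, float] = {}
    for j in tissue.junctions:
        amp = spec.baseline_mean * factors.get(classes.get(j.id, ""), 1.0)
        rr, cc = polyline_band(shape, j.polyline / px, 2.0 * paint_halfwidth_px)
        np.maximum.at(image, (rr, cc), amp)
        if j.id in classes:
            gt[j.id] = amp
    if psf_sigma_px > 0:
        image = gaussian_filter(image, psf_sigma_px)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    return image, gt


# ----------------------------------------------------------------------
# Recoil traces
# ----------------------------------------------------------------------

def simulate_recoil(spec: RecoilSpec | None = None, seed: int | None = None) -> RecoilTrace:
    """Sample a recoil trace from the exponential-plateau relaxation.

    Frames run every ``dt`` through the pre-ablation window and the
    post-ablation period; pre-ablation frames sit at d0 (= l_c) plus
    noise.
    """
    spec = spec or RecoilSpec()
    rng = np.random.default_rng(seed)
    n_pre = int(round(spec.pre_window / spec.dt))
    t_pre = spec.t0 - spec.dt * np.arange(n_pre, 0, -1)
    n_post = int(np.floor(spec.post_window / spec.dt))
    t_post = spec.t0 + spec.dt * np.arange(0, n_post + 1)
    times = np.concatenate([t_pre, t_post])
    d0 = spec.lc
    d = relaxation_model(times, d0, spec.lc, spec.d_inf_norm, spec.tau, spec.t0)
    if spec.noise_sigma > 0:
        d = d + rng.normal(0.0, spec.noise_sigma, size=d.shape)
    return RecoilTrace(times=times, distances=d, t0=spec.t0, lc=spec.lc)


# ----------------------------------------------------------------------
# Equilibrium foams with planted tensions
# ----------------------------------------------------------------------

def planted_tensions(
    tissue: Tissue, sigma: float = 0.2, seed: int | None = None,
    internal_factor: float | None = None, clonal_ids=None,
) -> dict[int, float]:
    """Lognormal per-junction tensions, normalized to mean 1.

    ``internal_factor`` optionally rescales internal (clonal–clonal)
    junctions after the draw — e.g. 0.6 to plant the reduced-tension
    signature of a sorting clone.
    """
    rng = np.random.default_rng(seed)
    interior = [j for j in tissue.junctions if not j.is_border]
    t = rng.lognormal(mean=0.0, sigma=sigma, size=len(interior))
    tensions = {j.id: float(x) for j, x in zip(interior, t)}
    if internal_factor is not None:
        from .tissue import INTERNAL, classify_junctions

        classes = classify_junctions(tissue, clonal_ids or tissue.clonal_ids())
        for jid, c in classes.items():
            if c == INTERNAL:
                tensions[jid] *= internal_factor
    mean = np.mean(list(tensions.values()))
    tensions = {j: t / mean for j, t in tensions.items()}
    for j in tissue.junctions:
        tensions.setdefault(j.id, 1.0)
    return tensions


def equilibrium_foam(
    tissue: Tissue,
    tensions: dict[int, float],
    area_stiffness: float = 0.02,
    tol_factor: float = 1e-8,
    collapse_frac: float = 0.1,
) -> tuple[Tissue, ForceMap]:
    """Relax interior vertices to force balance under planted tensions.

    Vertex-model statics: the energy is the line-tension term
    Σ_j T_j·L_j plus an area elasticity (K_A/2)·Σ_c (A_c − A_c⁰)² with
    the input areas as rest areas; boundary vertices are held fixed.
    The area term regularizes the relaxation — a pure tension network
    is only marginally stable — and is annealed from a stiff value down
    to ``area_stiffness`` so that the residual cell pressures
    p_c = K_A·(A_c⁰ − A_c) are small and the planted tensions alone
    carry the balance to good approximation.

    An edge whose drawn tension exceeds what its neighborhood can
    support undergoes a T1-type collapse (length → 0) and the fixed
    topology then has no equilibrium; such edges (length below
    ``collapse_frac`` of rest length) have their tension reduced by 30%
    and the relaxation resumes, so the *returned* tension map — the
    actual ground truth — always admits an equilibrium.  With moderate
    heterogeneity only a few percent of edges are touched.

    Damped-Newton minimization (analytic gradient and Hessian) drives
    the residual vertex force below ``tol_factor`` × mean tension in
    max-norm; raises on non-convergence with the residual attained.
    Returns the relaxed tissue and the ground-truth force map (final
    planted tensions renormalized to mean 1, plus the mean-centered
    equilibrium pressures on the same scale).
    """
    solver = _FoamSolver(tissue, tensions, collapse_frac)
    ka_stages = [0.2]
    while ka_stages[-1] > area_stiffness * 1.001:
        ka_stages.append(max(ka_stages[-1] / 2.5, area_stiffness))
    x = solver.x0.copy()
    mean_t = solver.mean_tension(tissue)
    tol = tol_factor * mean_t
    resid = np.inf
    for ka in ka_stages:
        # chunked calls restart the damping and T1-cooldown state, which
        # unsticks configurations a single long run can stall on
        for _chunk in range(15):
            x = solver.newton(x, ka, tol, max_iter=60)
            resid = solver.max_force(x, ka)
            Y = solver.unpack(x)
            L = np.linalg.norm(Y[solver.e1] - Y[solver.e2], axis=1)
            if resid < tol and not (L < collapse_frac * solver.L0).any():
                break
        else:
            raise RuntimeError(
                f"foam relaxation did not converge at K_A={ka:g}: "
                f"residual {resid:.3e} ≥ tol {tol:.3e}"
            )

    Y = solver.unpack(x)
    relaxed = _rebuild_geometry(tissue, Y)
    A = solver.areas(Y)
    work = solver.work
    interior = [j for j in relaxed.junctions if not j.is_border]
    mean = float(np.mean([work[j.id] for j in interior]))
    gt = {j: t / mean for j, t in work.items()}
    ka = ka_stages[-1]
    praw = {
        cid: float(ka * (A0c - Ac))
        for cid, Ac, A0c in zip(solver.ring_cells, A, solver.a0)
    }
    pmean = float(np.mean(list(praw.values())))
    gp = {c: (p - pmean) / mean for c, p in praw.items()}
    fmap = ForceMap(
        tensions=gt, negative={j for j, t in gt.items() if t < 0}, pressures=gp
    )
    # sanity: ground truth satisfies the shared balance definition
    res2 = balance_residual(relaxed, gt, pressures=gp)
    worst = max((float(np.linalg.norm(v)) for v in res2.values()), default=0.0)
    if worst >= 100 * tol_factor:
        raise RuntimeError(f"ground-truth balance violated after rescale: {worst:.3e}")
    return relaxed, fmap


class _FoamSolver:
    """Vectorized energy/gradient/Hessian of the foam functional."""

    def __init__(self, tissue: Tissue, tensions: dict[int, float], collapse_frac: float):
        free = tissue.free_vertices()
        if not free:
            raise ValueError("tissue has no interior vertex to relax")
        freeset = set(free)
        self.work = dict(tensions)
        self.jlist = [
            j for j in tissue.junctions if j.v1 in freeset or j.v2 in freeset
        ]
        self.e1 = np.array([j.v1 for j in self.jlist])
        self.e2 = np.array([j.v2 for j in self.jlist])
        self.X0 = tissue.vertices.copy()
        self.L0 = np.linalg.norm(self.X0[self.e1] - self.X0[self.e2], axis=1)
        self.collapse_frac = collapse_frac
        self.fidx = np.array(free)
        self.nfree = len(free)
        pos = {v: k for k, v in enumerate(free)}
        self.x0 = self.X0[self.fidx].ravel()

        rings, ring_cells = [], []
        for c in tissue.cells.values():
            if c.vertex_ids is None:
                raise ValueError("foam relaxation needs cells with ordered vertex ids")
            ids = np.array(c.vertex_ids)
            if _shoelace(self.X0[ids]) < 0:
                ids = ids[::-1]
            if any(v in freeset for v in ids):
                rings.append(ids)
                ring_cells.append(c.id)
        self.rings, self.ring_cells = rings, ring_cells
        self.a0 = np.array([_shoelace(self.X0[r]) for r in rings])
        self.rv = np.concatenate(rings)
        self.rid = np.concatenate([np.full(len(r), k) for k, r in enumerate(rings)])
        self.rnext = np.concatenate([np.roll(r, -1) for r in rings])
        self.rprev = np.concatenate([np.roll(r, 1) for r in rings])

        # flat scatter indices: tension-edge blocks over free endpoints
        n2 = 2 * self.nfree
        te_i, te_j, te_sign, te_edge = [], [], [], []
        for k, j in enumerate(self.jlist):
            ia, ib = pos.get(j.v1), pos.get(j.v2)
            if ia is not None:
                te_i.append(ia); te_j.append(ia); te_sign.append(1.0); te_edge.append(k)
            if ib is not None:
                te_i.append(ib); te_j.append(ib); te_sign.append(1.0); te_edge.append(k)
            if ia is not None and ib is not None:
                te_i.append(ia); te_j.append(ib); te_sign.append(-1.0); te_edge.append(k)
                te_i.append(ib); te_j.append(ia); te_sign.append(-1.0); te_edge.append(k)
        self.te = (np.array(te_i), np.array(te_j), np.array(te_sign), np.array(te_edge))

        # area-Hessian pair indices: within-ring (i, j) with both free
        pa_fi, pa_fj, pa_pi, pa_pj, pa_ring, pa_adj = [], [], [], [], [], []
        off = 0
        for kr, r in enumerate(rings):
            m = len(r)
            rfree = [pos.get(int(v)) for v in r]
            for i in range(m):
                if rfree[i] is None:
                    continue
                for jx in range(m):
                    if rfree[jx] is None:
                        continue
                    pa_fi.append(off + i); pa_fj.append(off + jx)
                    pa_pi.append(rfree[i]); pa_pj.append(rfree[jx])
                    pa_ring.append(kr)
                    adj = 1 if jx == (i + 1) % m else (-1 if jx == (i - 1) % m else 0)
                    pa_adj.append(adj)
            off += m
        self.pa = (
            np.array(pa_fi), np.array(pa_fj), np.array(pa_pi), np.array(pa_pj),
            np.array(pa_ring), np.array(pa_adj),
        )
        self._rot = 0.5 * np.array([[0.0, 1.0], [-1.0, 0.0]])
        self._n2 = n2

    # ------------------------------------------------------------------
    def mean_tension(self, tissue: Tissue) -> float:
        return float(
            np.mean([self.work[j.id] for j in tissue.junctions if not j.is_border])
        )

    def unpack(self, x: np.ndarray) -> np.ndarray:
        Y = self.X0.copy()
        Y[self.fidx] = x.reshape(-1, 2)
        return Y

    def areas(self, Y: np.ndarray) -> np.ndarray:
        contrib = 0.5 * (
            Y[self.rv, 0] * Y[self.rnext, 1] - Y[self.rnext, 0] * Y[self.rv, 1]
        )
        A = np.zeros(len(self.rings))
        np.add.at(A, self.rid, contrib)
        return A

    def _tw(self) -> np.ndarray:
        return np.array([self.work[j.id] for j in self.jlist])

    def energy_grad(self, x: np.ndarray, ka: float) -> tuple[float, np.ndarray]:
        Y = self.unpack(x)
        tw = self._tw()
        d = Y[self.e1] - Y[self.e2]
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        E = float(np.sum(tw * L))
        u = (tw / L)[:, None] * d
        G = np.zeros_like(Y)
        np.add.at(G, self.e1, u)
        np.add.at(G, self.e2, -u)
        A = self.areas(Y)
        E += 0.5 * ka * float(np.sum((A - self.a0) ** 2))
        dA = 0.5 * np.column_stack(
            [Y[self.rnext, 1] - Y[self.rprev, 1], Y[self.rprev, 0] - Y[self.rnext, 0]]
        )
        np.add.at(G, self.rv, (ka * (A - self.a0))[self.rid][:, None] * dA)
        return E, G[self.fidx].ravel()

    def max_force(self, x: np.ndarray, ka: float) -> float:
        _, g = self.energy_grad(x, ka)
        return float(np.max(np.linalg.norm(g.reshape(-1, 2), axis=1)))

    def hessian(self, x: np.ndarray, ka: float) -> np.ndarray:
        Y = self.unpack(x)
        tw = self._tw()
        n2 = self._n2
        H = np.zeros((n2, n2))
        d = Y[self.e1] - Y[self.e2]
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        u = d / L[:, None]
        blocks = (tw / L)[:, None, None] * (
            np.eye(2) - u[:, :, None] * u[:, None, :]
        )
        ti, tj, tsign, tedge = self.te
        blk = tsign[:, None, None] * blocks[tedge]
        _scatter_blocks(H, ti, tj, blk)
        A = self.areas(Y)
        dA = 0.5 * np.column_stack(
            [Y[self.rnext, 1] - Y[self.rprev, 1], Y[self.rprev, 0] - Y[self.rnext, 0]]
        )
        fi, fj, pi, pj, pring, padj = self.pa
        blk = ka * np.einsum("ki,kj->kij", dA[fi], dA[fj])
        coef = (ka * (A - self.a0))[pring]
        fwd = padj == 1
        bwd = padj == -1
        blk[fwd] += coef[fwd][:, None, None] * self._rot
        blk[bwd] += coef[bwd][:, None, None] * self._rot.T
        _scatter_blocks(H, pi, pj, blk)
        return H

    def newton(
        self, x: np.ndarray, ka: float, tol: float, max_iter: int
    ) -> np.ndarray:
        """Damped Newton with in-loop T1 stabilization.

        An edge whose length falls below the collapse threshold has its
        tension reduced by 30% (at most once per 10 iterations per edge,
        giving the geometry time to reopen) and iteration continues with
        the updated tension field, so the final ``self.work`` always
        admits the equilibrium reached.
        """
        lam = 0.0
        cooldown: dict[int, int] = {}
        n_reductions: dict[int, int] = {}
        for it in range(max_iter):
            Y = self.unpack(x)
            L = np.linalg.norm(Y[self.e1] - Y[self.e2], axis=1)
            bad = np.nonzero(L < self.collapse_frac * self.L0)[0]
            reduced = False
            for k in bad:
                if it >= cooldown.get(k, 0):
                    n_reductions[k] = n_reductions.get(k, 0) + 1
                    self.work[self.jlist[k].id] *= 0.7
                    cooldown[k] = it + 10
                    reduced = True
            E0, g = self.energy_grad(x, ka)
            if not reduced and bad.size == 0 and float(
                np.max(np.linalg.norm(g.reshape(-1, 2), axis=1))
            ) < tol:
                break
            H = self.hessian(x, ka)
            H[np.diag_indices_from(H)] += lam + 1e-12
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, -g, rcond=None)[0]
            smax = float(np.max(np.abs(step)))
            cap = 0.5 * float(np.median(self.L0))
            if smax > cap:
                step *= cap / smax
            g0 = float(np.linalg.norm(g))
            alpha, ok = 1.0, False
            for _ls in range(30):
                E1, g1 = self.energy_grad(x + alpha * step, ka)
                if E1 < E0 or float(np.linalg.norm(g1)) < g0:
                    ok = True
                    break
                alpha *= 0.5
            if ok:
                x = x + alpha * step
                lam = lam * 0.25
            else:
                lam = max(lam * 10.0, 1e-8)
        return x


    def newton_root(self, x: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
        """Damped Newton on the tension-only force residual g(x) = 0.

        The tension-only equilibrium is generically a saddle of the
        energy, so this accepts steps on ‖g‖ decrease rather than energy
        decrease; quadratic convergence once the (existing) root is near.
        """
        lam = 1e-12
        for _ in range(max_iter):
            _, g = self.energy_grad(x, 0.0)
            if float(np.max(np.linalg.norm(g.reshape(-1, 2), axis=1))) < tol:
                break
            H = self.hessian(x, 0.0)
            Hd = H.copy()
            Hd[np.diag_indices_from(Hd)] += lam
            try:
                step = np.linalg.solve(Hd, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hd, -g, rcond=None)[0]
            cap = 0.3 * float(np.median(self.L0))
            smax = float(np.max(np.abs(step)))
            if smax > cap:
                step *= cap / smax
            gn = float(np.linalg.norm(g))
            alpha, ok = 1.0, False
            for _ls in range(25):
                g1 = self.energy_grad(x + alpha * step, 0.0)[1]
                if float(np.linalg.norm(g1)) < gn:
                    ok = True
                    break
                alpha *= 0.5
            if ok:
                x = x + alpha * step
                lam = max(lam * 0.3, 1e-12)
                continue
            # Gauss-Newton/LM step on ½‖g‖² (H is the symmetric Jacobian of g)
            lam = max(lam * 10.0, 1e-8)
            step = np.linalg.solve(H @ H + lam * np.eye(len(g)), -(H @ g))
            for _ls in range(25):
                g1 = self.energy_grad(x + step, 0.0)[1]
                if float(np.linalg.norm(g1)) < gn:
                    x = x + step
                    break
                step *= 0.5
        return x


def _scatter_blocks(H: np.ndarray, bi: np.ndarray, bj: np.ndarray, blk: np.ndarray) -> None:
    """H[2bi+a, 2bj+b] += blk[:, a, b] with repeated-index accumulation."""
    n2 = H.shape[0]
    for a in range(2):
        for b in range(2):
            np.add.at(H.ravel(), (2 * bi + a) * n2 + (2 * bj + b), blk[:, a, b])


def tension_only_foam(
    tissue: Tissue,
    sigma: float = 0.2,
    seed: int | None = None,
    internal_factor: float | None = None,
    clonal_ids=None,
    tol_factor: float = 1e-8,
    max_alternations: int = 60,
    proj_ridge: float = 0.05,
    max_attempts: int = 6,
) -> tuple[Tissue, ForceMap]:
    """Equilibrium foam whose planted tensions balance with zero pressure.

    A small fraction of tension draws admits no stable relaxation path
    at fixed topology; those draws are rejected and redrawn from a
    sub-seed derived deterministically from ``seed``, so every seed
    yields a foam and the ensemble is conditioned on relaxability.
    """
    last: Exception | None = None
    for attempt in range(max_attempts):
        sub = int(np.random.SeedSequence(seed, spawn_key=(attempt,)).generate_state(1)[0] % (2**31))
        try:
            return _tension_only_foam_once(
                tissue, sigma, sub if attempt else seed, internal_factor,
                clonal_ids, tol_factor, max_alternations, proj_ridge,
            )
        except RuntimeError as err:
            last = err
    raise RuntimeError(f"tension-only foam generation failed after {max_attempts} draws: {last}")


def _tension_only_foam_once(
    tissue: Tissue,
    sigma: float,
    seed: int | None,
    internal_factor: float | None,
    clonal_ids,
    tol_factor: float,
    max_alternations: int,
    proj_ridge: float,
) -> tuple[Tissue, ForceMap]:
    """Equilibrium foam whose planted tensions balance with *zero* pressure.

    Heterogeneous tensions on a trivalent network determine the angles at
    every vertex, and those angles must close around every face — so an
    arbitrary (e.g. iid lognormal) tension field admits no tension-only
    equilibrium.  This generator draws a lognormal field and then
    alternates (i) vertex-model relaxation of the geometry and (ii) a
    minimal ridge projection of the tensions toward the null space of
    the current balance matrix (mean fixed at 1, spread rescaled to the
    drawn sd), converging geometrically to a tension field *on* the
    feasible manifold; a final Newton root polish on the vertex
    positions drives the tension-only residual below ``tol_factor`` ×
    mean tension.  The returned ground truth is the final tension map —
    lognormal-seeded with the drawn sd, minimally adjusted — with no
    pressures, so it satisfies the tension-only force balance that
    inference assembles, exactly.

    ``internal_factor`` rescales the clone-internal junction tensions of
    the *initial* draw (e.g. 0.6 to plant a low-tension clone); the
    projection preserves the contrast.
    """
    from scipy.linalg import lstsq, null_space

    from .forces import assemble_balance

    T = planted_tensions(
        tissue, sigma=sigma, seed=seed,
        internal_factor=internal_factor, clonal_ids=clonal_ids,
    )
    interior_ids = [j.id for j in tissue.junctions if not j.is_border]
    target_sd = float(np.std([T[j] for j in interior_ids]))
    tis = tissue
    ok = False
    for _it in range(max_alternations):
        tr, gt = equilibrium_foam(tis, T, area_stiffness=0.02)
        T = dict(gt.tensions)  # includes any T1 stabilization, mean 1
        prob = assemble_balance(tr, mu=0.0)
        tv = np.array([T[j] for j in prob.junction_ids])
        resid = float(np.abs(prob.B @ tv).max())
        mean_t = float(tv.mean())
        if resid < 1e-5 * mean_t:
            ok = True
        nj = len(prob.junction_ids)
        P = null_space(np.ones((1, nj)))
        A = np.vstack([prob.B @ P, np.sqrt(proj_ridge) * np.eye(nj - 1)])
        b = np.concatenate(
            [-(prob.B @ np.full(nj, mean_t)), np.sqrt(proj_ridge) * (P.T @ (tv - mean_t))]
        )
        z, _, _, _ = lstsq(A, b)
        tnew = mean_t + P @ z
        sd = float(tnew.std())
        if sd > 1e-12:
            tnew = 1.0 + (tnew - tnew.mean()) * (target_sd / sd)
        T = {j: float(x) for j, x in zip(prob.junction_ids, tnew)}
        for j in tr.junctions:
            T.setdefault(j.id, 1.0)
        tis = tr
        if ok:
            break
    if not ok:
        raise RuntimeError("tension projection did not reach the feasible manifold")

    # final relaxation, then joint Newton on (positions, tensions): the
    # residual is linear in T, so a min-norm joint step lands exactly on
    # the nearest tension-only root, moving the tensions minimally.
    tr, _ = equilibrium_foam(tis, T, area_stiffness=0.02)
    solver = _FoamSolver(tr, T, collapse_frac=0.05)
    mean_t = solver.mean_tension(tr)
    tol = tol_factor * mean_t
    x = solver.newton_root(solver.x0.copy(), tol, max_iter=60)
    resid = solver.max_force(x, 0.0)
    w_t = 0.3  # tension-step weight: prefer moving geometry
    for _ in range(40):
        if resid < tol:
            break
        _, g = solver.energy_grad(x, 0.0)
        H = solver.hessian(x, 0.0)
        Y = solver.unpack(x)
        d = Y[solver.e1] - Y[solver.e2]
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        u = d / L[:, None]
        nf = len(solver.fidx)
        pos = {v: k for k, v in enumerate(solver.fidx)}
        M = np.zeros((2 * nf, len(solver.jlist)))
        for k, j in enumerate(solver.jlist):
            ia, ib = pos.get(j.v1), pos.get(j.v2)
            if ia is not None:
                M[2 * ia : 2 * ia + 2, k] += u[k]
            if ib is not None:
                M[2 * ib : 2 * ib + 2, k] -= u[k]
        A = np.hstack([H, w_t * M])
        s, _, _, _ = np.linalg.lstsq(A, -g, rcond=None)
        dx, dT = s[: 2 * nf], w_t * s[2 * nf :]
        gn = float(np.linalg.norm(g))
        alpha = 1.0
        for _ls in range(25):
            for k, j in enumerate(solver.jlist):
                solver.work[j.id] = max(solver.work[j.id] + alpha * dT[k], 1e-3)
            g1 = solver.energy_grad(x + alpha * dx, 0.0)[1]
            if float(np.linalg.norm(g1)) < gn:
                x = x + alpha * dx
                break
            for k, j in enumerate(solver.jlist):
                solver.work[j.id] -= alpha * dT[k]
            alpha *= 0.5
        resid = solver.max_force(x, 0.0)
    T = dict(solver.work)
    mean_t = solver.mean_tension(tr)
    tol = tol_factor * mean_t
    if resid >= tol:
        raise RuntimeError(
            f"tension-only root polish did not converge: residual {resid:.3e} ≥ {tol:.3e}"
        )
    relaxed = _rebuild_geometry(tr, solver.unpack(x))
    gt = {j: t / mean_t for j, t in T.items()}
    fmap = ForceMap(tensions=gt, negative={j for j, t in gt.items() if t < 0})
    res2 = balance_residual(relaxed, gt)
    worst = max((float(np.linalg.norm(v)) for v in res2.values()), default=0.0)
    if worst >= 10 * tol_factor:
        raise RuntimeError(f"ground-truth balance violated: {worst:.3e}")
    return relaxed, fmap


def _shoelace(P: np.ndarray) -> float:
    x, y = P[:, 0], P[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _rebuild_geometry(tissue: Tissue, X: np.ndarray) -> Tissue:
    cells: dict[int, Cell] = {}
    for c in tissue.cells.values():
        if c.vertex_ids is None:
            raise ValueError("foam relaxation needs cells with ordered vertex ids")
        pts = X[np.array(c.vertex_ids)]
        poly = Polygon(pts)
        cells[c.id] = Cell(
            id=c.id, polygon=pts, area=float(poly.area),
            perimeter=float(poly.length),
            centroid=np.array(poly.centroid.coords[0]),
            clonal=c.clonal, apoptotic=c.apoptotic, excluded=c.excluded,
            vertex_ids=list(c.vertex_ids),
        )
    junctions = []
    for j in tissue.junctions:
        seg = np.vstack([X[j.v1], X[j.v2]])
        junctions.append(
            Junction(
                id=j.id, v1=j.v1, v2=j.v2, cells=j.cells, polyline=seg,
                length=float(np.linalg.norm(seg[1] - seg[0])),
            )
        )
    return Tissue(
        vertices=X.copy(), junctions=junctions, cells=cells,
        scale=tissue.scale, field_of_view_area=tissue.field_of_view_area,
    )


# ----------------------------------------------------------------------
# Apoptosis planting
# ----------------------------------------------------------------------

def plant_apoptosis(
    tissue: Tissue,
    clonal_ids,
    n_dcp1: int,
    seed: int | None = None,
    ring_odds: dict[int, float] | None = None,
    max_ring: int = 3,
) -> set[int]:
    """Place apoptotic cells; uniform without replacement unless biased.

    With ``ring_odds`` (e.g. {0: 3, 1: 3}) the selection odds of cells in
    those rings are multiplied, using weighted sampling without
    replacement (Efraimidis–Spirakis exponential keys); without it the
    draw is plain uniform sampling without replacement — the
    hypergeometric null.  Sets the apoptotic flags and returns the ids.
    """
    rng = np.random.default_rng(seed)
    eligible = sorted(c.id for c in tissue.cells.values() if not c.excluded)
    if n_dcp1 > len(eligible):
        raise ValueError("more apoptotic cells requested than available")
    if ring_odds:
        rings = neighbor_rings(tissue, clonal_ids, max_ring=max_ring)
        w = np.array([ring_odds.get(rings[c], 1.0) for c in eligible], dtype=float)
        keys = rng.random(len(eligible)) ** (1.0 / w)
        chosen = {eligible[i] for i in np.argsort(keys)[-n_dcp1:]}
    else:
        chosen = set(rng.choice(eligible, size=n_dcp1, replace=False).tolist())
    for c in chosen:
        tissue.cells[c].apoptotic = True
    return chosen


def sample_clone_sizes(spec: CloneSpec, rng: np.random.Generator) -> list[int]:
    """Clone sizes: explicit list, or truncated geometric on 1..10."""
    if spec.sizes is not None:
        return list(spec.sizes)
    k = np.arange(1, 11)
    p = (1 - spec.size_p) ** (k - 1) * spec.size_p
    p = p / p.sum()
    return rng.choice(k, size=spec.count, p=p).tolist()


def rasterize_mask(tissue: Tissue, px: float = 0.2) -> np.ndarray:
    """Label image of the tessellation (pixel-center sampling), uint16.

    Labels are cell id + 1; 0 is background.  Inverse of
    :func:`clonemech.mask.mask_to_tissue` up to pixelation.
    """
    from skimage.draw import polygon as draw_polygon

    hi = tissue.vertices.max(axis=0) + MARGIN_UM
    shape = (int(np.ceil(hi[1] / px)) + 1, int(np.ceil(hi[0] / px)) + 1)
    out = np.zeros(shape, dtype=np.uint16)
    for c in tissue.cells.values():
        rr, cc = draw_polygon(c.polygon[:, 1] / px, c.polygon[:, 0] / px, shape)
        out[rr, cc] = c.id + 1
    return out
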