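"""Force-balance assembly, tension inference and the randomization test."""

import itertools

import numpy as np
import pytest
from shapely.geometry import Polygon

from clonemech import synth
from clonemech.forces import (
    assemble_balance,
    infer_tensions,
    randomization_test,
    zone_summary,
    zone_tensions,
)
from clonemech.mask import mask_to_tissue
from clonemech.tissue import Cell, Junction, Tissue


def three_spoke_tissue(angles_deg):
    """One interior vertex with three unit spokes at the given directions."""
    O = np.zeros(2)
    spokes = [
        np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))]) for a in angles_deg
    ]
    outer = [2.0 * (spokes[i] + spokes[(i + 1) % 3]) for i in range(3)]
    verts = [O] + spokes + outer  # 0, 1..3, 4..6
    cells = {}
    for i in range(3):
        ring = [0, 1 + i, 4 + i, 1 + (i + 1) % 3]
        pts = np.array([verts[v] for v in ring])
        poly = Polygon(pts)
        cells[i] = Cell(
            id=i, polygon=pts, area=abs(poly.area), perimeter=poly.length,
            centroid=np.array(poly.centroid.coords[0]), vertex_ids=ring,
        )
    junctions = []
    jid = 0
    for i in range(3):  # spokes: flanked by the two adjacent cells
        seg = np.vstack([O, spokes[i]])
        junctions.append(
            Junction(id=jid, v1=0, v2=1 + i, cells=(i, (i - 1) % 3),
                     polyline=seg, length=1.0)
        )
        jid += 1
    for i in range(3):  # outer rim: border junctions
        for a, b in ((1 + i, 4 + i), (4 + i, 1 + (i + 1) % 3)):
            seg = np.vstack([verts[a], verts[b]])
            junctions.append(
                Junction(id=jid, v1=a, v2=b, cells=(i, None), polyline=seg,
                         length=float(np.linalg.norm(seg[1] - seg[0])))
            )
            jid += 1
    return Tissue(
        vertices=np.array(verts), junctions=junctions, cells=cells,
        scale=1.0, field_of_view_area=1e-4,
    )


class TestAssembleBalance:
    def test_symmetric_120_vertex_balanced_by_uniform_tension(self):
        t = three_spoke_tissue([90, 210, 330])
        prob = assemble_balance(t)
        resid = prob.B @ np.ones(len(prob.junction_ids))
        assert np.abs(resid).max() < 1e-12

    def test_90_135_135_vertex_has_sqrt2_ratios(self):
        # edge between the two 135° gaps carries √2 × the other tensions:
        # the 2×3 balance system has a one-dimensional null space
        t = three_spoke_tissue([0, 135, 225])
        prob = assemble_balance(t)
        from scipy.linalg import null_space

        ns = null_space(prob.B)
        assert ns.shape[1] == 1
        v = ns[:, 0] / ns[:, 0][1]
        assert v[0] == pytest.approx(np.sqrt(2), rel=1e-9)
        assert v[2] == pytest.approx(1.0, rel=1e-9)

    def test_foam_ground_truth_satisfies_assembled_rows(self):
        t = synth.hexagonal_tissue(100)
        relaxed, fmap = synth.tension_only_foam(t, sigma=0.2, seed=3)
        prob = assemble_balance(relaxed)
        tv = np.array([fmap.tensions[j] for j in prob.junction_ids])
        assert np.abs(prob.B @ tv).max() < 1e-6

    def test_no_interior_vertex_rejected(self):
        m = np.zeros((4, 12), dtype=np.int32)
        m[:, :4], m[:, 4:8], m[:, 8:] = 1, 2, 3
        t = mask_to_tissue(m)
        with pytest.raises(ValueError, match="interior"):
            assemble_balance(t)


class TestInferTensions:
    def test_uniform_hex_lattice_returns_all_ones(self):
        t = synth.hexagonal_tissue(100)
        fmap = infer_tensions(assemble_balance(t, mu=0.1))
        vals = np.array(list(fmap.tensions.values()))
        assert np.abs(vals - 1.0).max() < 1e-6
        assert not fmap.negative

    def test_gauge_mean_is_one(self):
        t = synth.voronoi_tissue(80, seed=6)
        fmap = infer_tensions(assemble_balance(t, mu=0.1))
        assert np.mean(list(fmap.tensions.values())) == pytest.approx(1.0, abs=1e-9)

    def test_large_mu_shrinks_to_prior(self):
        t = synth.voronoi_tissue(80, seed=6)
        fmap = infer_tensions(assemble_balance(t, mu=1e8))
        assert np.abs(np.array(list(fmap.tensions.values())) - 1.0).max() < 1e-4

    def test_mu_zero_rank_deficiency_raises(self):
        # two disconnected star vertices carry independent tension scales;
        # the single mean-1 gauge cannot identify both, so mu = 0 must fail
        a = three_spoke_tissue([90, 210, 330])
        b = three_spoke_tissue([90, 210, 330])
        off_v = len(a.vertices)
        cells = dict(a.cells)
        for c in b.cells.values():
            pts = c.polygon + 10.0
            cells[c.id + 3] = Cell(
                id=c.id + 3, polygon=pts, area=c.area, perimeter=c.perimeter,
                centroid=c.centroid + 10.0,
                vertex_ids=[v + off_v for v in c.vertex_ids],
            )
        junctions = list(a.junctions)
        for j in b.junctions:
            junctions.append(
                Junction(
                    id=j.id + len(a.junctions), v1=j.v1 + off_v, v2=j.v2 + off_v,
                    cells=(j.cells[0] + 3, None if j.cells[1] is None else j.cells[1] + 3),
                    polyline=j.polyline + 10.0, length=j.length,
                )
            )
        t = Tissue(
            vertices=np.vstack([a.vertices, b.vertices + 10.0]),
            junctions=junctions, cells=cells, scale=1.0, field_of_view_area=1e-4,
        )
        with pytest.raises(ValueError, match="mu > 0"):
            infer_tensions(assemble_balance(t, mu=0.0))

    def test_mu_zero_identifiable_single_vertex(self):
        t = three_spoke_tissue([0, 135, 225])
        fmap = infer_tensions(assemble_balance(t, mu=0.0))
        vals = fmap.as_array(sorted(fmap.tensions))
        assert vals[0] / vals[1] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_variance_shrinks_monotonically_with_mu(self):
        t = synth.hexagonal_tissue(100)
        relaxed, _ = synth.tension_only_foam(t, sigma=0.2, seed=5)
        sds = []
        for mu in (0.01, 0.1, 1.0):
            fmap = infer_tensions(assemble_balance(relaxed, mu=mu))
            sds.append(np.std(list(fmap.tensions.values())))
        assert sds[0] > sds[1] > sds[2]

    def test_recovery_on_planted_foam(self):
        t = synth.hexagonal_tissue(150)
        relaxed, gt = synth.tension_only_foam(t, sigma=0.2, seed=8)
        fmap = infer_tensions(assemble_balance(relaxed, mu=0.1))
        free = set(relaxed.free_vertices())
        jint = [
            j.id for j in relaxed.junctions
            if not j.is_border and j.v1 in free and j.v2 in free
        ]
        p = np.array([gt.tensions[j] for j in jint])
        q = np.array([fmap.tensions[j] for j in jint])
        from scipy.stats import spearmanr

        assert spearmanr(p, q).statistic >= 0.85

    def test_pressure_mode_on_symmetric_lattice(self):
        t = synth.hexagonal_tissue(64)
        fmap = infer_tensions(assemble_balance(t, mu=0.1, with_pressure=True))
        assert np.abs(np.array(list(fmap.tensions.values())) - 1.0).max() < 1e-6
        assert np.abs(np.array(list(fmap.pressures.values()))).max() < 1e-6


class TestZoneTensions:
    def test_low_tension_clone_detected(self):
        t = synth.hexagonal_tissue(100)
        synth.plant_clones(t, [7], compactness=1.0, seed=2)
        relaxed, _ = synth.tension_only_foam(
            t, sigma=0.2, seed=12, internal_factor=0.6, clonal_ids=t.clonal_ids()
        )
        fmap = infer_tensions(assemble_balance(relaxed, mu=0.1))
        zones = zone_tensions(fmap, relaxed, relaxed.clonal_ids())
        med = zones.groupby("cls")["tension"].median()
        assert med["internal"] < med["external"]
        summary = zone_summary(zones)
        assert set(summary.columns) == {"cls", "n", "median", "q1", "q3"}


class TestRandomizationTest:
    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert randomization_test(a, list(a), n_perm=500, seed=0) == 1.0

    def test_separated_groups_small_p(self):
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        assert randomization_test(a, b, n_perm=10_000, seed=0) <= 0.001

    def test_matches_exhaustive_enumeration(self):
        a = [0.1, 0.9, 1.3, 2.0]
        b = [1.1, 1.7, 2.4, 3.0]
        pool = np.array(a + b)
        obs = abs(np.median(a) - np.median(b))
        count = sum(
            abs(np.median(pool[list(idx)]) - np.median(np.delete(pool, list(idx))))
            >= obs - 1e-12
            for idx in itertools.combinations(range(8), 4)
        )
        p_exact = count / 70
        n_perm = 20_000
        p_hat = randomization_test(a, b, n_perm=n_perm, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_hat - p_exact) < 3 * se + 2 / n_perm

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            randomization_test([], [1.0], n_perm=10)
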