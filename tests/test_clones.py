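"""Clone morphometrics: circularity, connectivity, theoretical ceiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon

from clonemech import _hex, synth
from clonemech.clones import (
    circularity,
    circularity_from_area_perimeter,
    clone_density,
    clone_metrics_table,
    clone_size_table,
    connectivity_index,
    max_connectivity,
)
from clonemech.tissue import find_clones


class TestCircularity:
    def test_disc_is_one(self):
        # closed form: A = πr², P = 2πr ⇒ 4πA/P² = 1 for any r
        for r in (0.5, 1.0, 7.3):
            assert circularity_from_area_perimeter(
                np.pi * r**2, 2 * np.pi * r
            ) == pytest.approx(1.0, abs=1e-15)

    def test_fine_polygon_circle_converges(self):
        poly = Point(0, 0).buffer(1.0, quad_segs=2500)  # 10,000-vertex circle
        assert circularity(poly) == pytest.approx(1.0, abs=1e-4)

    def test_regular_hexagon_closed_form(self):
        s = 2.0
        pts = [
            (s * np.cos(a), s * np.sin(a)) for a in np.linspace(0, 2 * np.pi, 7)[:-1]
        ]
        expected = np.pi * np.sqrt(3) / 6  # 4π(3√3/2)s² / (6s)² ≈ 0.9069
        assert circularity(Polygon(pts)) == pytest.approx(expected, rel=1e-12)

    def test_elongated_rectangles_decrease_to_zero(self):
        vals = [
            circularity(Polygon([(0, 0), (k, 0), (k, 1), (0, 1)])) for k in (2, 5, 20, 100)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.15

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, s):
        pts = np.array([(0, 0), (3, 0), (4, 2), (1, 3)], dtype=float)
        c1 = circularity(Polygon(pts))
        c2 = circularity(Polygon(pts * s))
        assert abs(c1 - c2) < 1e-12

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            circularity_from_area_perimeter(0.0, 1.0)

    def test_smoothing_raises_pixelated_circularity(self):
        # a pixel staircase underestimates C; corner cutting recovers some of it
        from clonemech.mask import mask_to_tissue

        t0 = synth.hexagonal_tissue(32)
        m = synth.rasterize_mask(t0, px=0.05)
        t = mask_to_tissue(m, scale=0.05)
        interior = next(c for c in t.cells.values() if not c.excluded)
        raw = circularity(Polygon(interior.polygon))
        smoothed = circularity(Polygon(interior.polygon), smooth=True)
        assert smoothed > raw


class TestConnectivity:
    @pytest.mark.parametrize(
        "shape, expected",
        [("single", 0.0), ("chain3", 4 / 3), ("triangle3", 2.0)],
    )
    def test_small_clone_values(self, shape, expected):
        t = synth.hexagonal_tissue(100)
        g = t.adjacency()
        interior = [c.id for c in t.cells.values() if not c.excluded]
        a = interior[len(interior) // 2]
        if shape == "single":
            members = {a}
        elif shape == "chain3":
            nbrs = sorted(g[a])
            # two neighbors of a that are not mutually adjacent
            b, c = next(
                (x, y) for x in nbrs for y in nbrs if x < y and y not in g[x]
            )
            members = {a, b, c}
        else:
            nbrs = sorted(g[a])
            b, c = next((x, y) for x in nbrs for y in nbrs if x < y and y in g[x])
            members = {a, b, c}
        clone = find_clones(t, members)[0]
        assert connectivity_index(clone) == pytest.approx(expected)

    def test_matches_brute_force_on_random_clones(self):
        mismatches = 0
        for seed in range(60):
            t = synth.hexagonal_tissue(100)
            synth.plant_clones(
                t, [int(1 + seed % 8)], compactness=0.0, seed=seed
            )
            clone = find_clones(t)[0]
            g = t.adjacency()
            e = sum(
                1 for a in clone.cell_ids for b in g[a] if b in clone.cell_ids
            ) // 2
            if connectivity_index(clone) != pytest.approx(2 * e / clone.n_cells):
                mismatches += 1
        assert mismatches == 0


class TestMaxConnectivity:
    @pytest.mark.parametrize("n, expected", [(1, 0.0), (3, 2.0), (7, 24 / 7)])
    def test_known_values(self, n, expected):
        assert max_connectivity(n) == pytest.approx(expected)

    def test_closed_form_matches_exhaustive_small(self):
        best = _hex.max_internal_edges_exhaustive(7)
        for n, e in best.items():
            assert e == _hex.max_internal_edges(n)

    def test_spiral_polyhex_attains_maximum(self):
        for n in range(1, 13):
            assert _hex.internal_edges(_hex.spiral(n)) == _hex.max_internal_edges(n)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            max_connectivity(0)

    def test_compact_planted_clones_reach_ceiling(self):
        for n in range(1, 9):
            t = synth.hexagonal_tissue(121)
            synth.plant_clones(t, [n], compactness=1.0, seed=n)
            clone = find_clones(t)[0]
            assert connectivity_index(clone) == pytest.approx(max_connectivity(n))


def test_connectivity_correlates_with_circularity():
    # the sorting readouts agree: over random clones of fixed size, more
    # connected clones are rounder (rank correlation > 0)
    from scipy.stats import spearmanr

    ks, cs = [], []
    for seed in range(220):
        t = synth.hexagonal_tissue(100)
        synth.plant_clones(t, [6], compactness=0.0, seed=seed)
        clone = find_clones(t)[0]
        ks.append(connectivity_index(clone))
        cs.append(circularity(clone))
    rho, _ = spearmanr(ks, cs)
    assert rho > 0


class TestDensityAndSizes:
    def test_density_arithmetic(self, hex_tissue):
        clones = find_clones(hex_tissue, set(list(hex_tissue.cells)[:1]))
        d = clone_density(hex_tissue, clones)
        excl = sum(c.area for c in hex_tissue.cells.values() if c.excluded) / 1e6
        assert d == pytest.approx(1 / (hex_tissue.field_of_view_area - excl))

    def test_zero_clones(self, hex_tissue):
        assert clone_density(hex_tissue, []) == 0.0

    def test_size_table_and_metrics_table(self):
        t = synth.voronoi_tissue(150, seed=8)
        synth.plant_clones(t, [2, 4, 4], compactness=0.8, seed=1)
        clones = find_clones(t)
        table = clone_size_table(clones)
        assert table["count"].sum() == 3
        df = clone_metrics_table(t, clones)
        assert set(df["n_cells"]) == {2, 4}
        assert ((0 < df["circularity"]) & (df["circularity"] <= 1)).all()
        assert (df["connectivity"] <= df["K_max"] + 1e-12).all()
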