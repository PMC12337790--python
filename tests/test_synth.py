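"""Synthetic-tissue generators: lattices, clones, recoil, foams, apoptosis."""

import numpy as np
import pytest

from clonemech import synth
from clonemech.apoptosis import ring_cell_counts
from clonemech.forces import balance_residual
from clonemech.recoil import relaxation_model
from clonemech.tissue import neighbor_rings


class TestLattices:
    def test_hex_interior_cells_have_six_neighbors(self, hex_tissue):
        g = hex_tissue.adjacency()
        degs = [g.degree(c.id) for c in hex_tissue.cells.values() if not c.excluded]
        assert degs and all(d == 6 for d in degs)

    def test_voronoi_deterministic_under_seed(self):
        a = synth.voronoi_tissue(80, seed=5)
        b = synth.voronoi_tissue(80, seed=5)
        assert np.array_equal(a.vertices, b.vertices)
        assert [j.cells for j in a.junctions] == [j.cells for j in b.junctions]

    def test_voronoi_mean_interior_neighbor_number(self):
        # Euler relation for planar tilings puts the interior mean near 6
        t = synth.voronoi_tissue(300, seed=7)
        g = t.adjacency()
        degs = [g.degree(c.id) for c in t.cells.values() if not c.excluded]
        assert 5.6 <= np.mean(degs) <= 6.4

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            synth.generate_epithelium(synth.SynthConfig(n_cells=5))


class TestPlantClones:
    def test_compact_four_cell_clone_has_five_internal_edges(self):
        t = synth.hexagonal_tissue(100)
        synth.plant_clones(t, [4], compactness=1.0, seed=0)
        g = t.adjacency()
        clonal = t.clonal_ids()
        e = sum(1 for a in clonal for b in g[a] if b in clonal) // 2
        assert e == 5

    def test_single_cell_clone(self):
        t = synth.hexagonal_tissue(64)
        clones = synth.plant_clones(t, [1], compactness=1.0, seed=0)
        assert len(clones[0]) == 1

    def test_random_clones_less_connected_than_compact(self):
        es = []
        for seed in range(40):
            t = synth.hexagonal_tissue(100)
            synth.plant_clones(t, [4], compactness=0.0, seed=seed)
            g = t.adjacency()
            clonal = t.clonal_ids()
            es.append(sum(1 for a in clonal for b in g[a] if b in clonal) // 2)
        assert np.mean(es) < 5  # compact value is 5

    def test_clones_pairwise_non_adjacent(self):
        t = synth.voronoi_tissue(150, seed=3)
        clones = synth.plant_clones(t, [3, 3, 3], compactness=0.5, seed=9)
        g = t.adjacency()
        for i, a in enumerate(clones):
            for b in clones[i + 1 :]:
                assert not any(y in g[x] for x in a for y in b)

    def test_infeasible_clone_rejected(self):
        t = synth.hexagonal_tissue(16)
        with pytest.raises((ValueError, RuntimeError)):
            synth.plant_clones(t, [500], seed=0)


class TestSimulateRecoil:
    def test_noiseless_trace_matches_formula(self):
        spec = synth.RecoilSpec(noise_sigma=0.0)
        tr = synth.simulate_recoil(spec, seed=0)
        expect = relaxation_model(
            tr.times, spec.lc, spec.lc, spec.d_inf_norm, spec.tau, spec.t0
        )
        assert np.allclose(tr.distances, expect)

    def test_infinite_tau_limit_is_flat(self):
        spec = synth.RecoilSpec(tau=1e9, noise_sigma=0.0)
        tr = synth.simulate_recoil(spec, seed=0)
        assert np.max(np.abs(tr.distances - spec.lc)) < 1e-6

    def test_reproducible_under_seed(self):
        spec = synth.RecoilSpec(noise_sigma=0.1)
        a = synth.simulate_recoil(spec, seed=42)
        b = synth.simulate_recoil(spec, seed=42)
        assert np.array_equal(a.distances, b.distances)

    def test_cadence_matches_protocol(self):
        tr = synth.simulate_recoil(seed=0)
        assert np.allclose(np.diff(tr.times), 1.5)
        assert np.count_nonzero(tr.times < tr.t0) == 5


class TestEquilibriumFoam:
    def test_uniform_hex_is_already_equilibrium(self):
        t = synth.hexagonal_tissue(64)
        T = {j.id: 1.0 for j in t.junctions}
        relaxed, fmap = synth.equilibrium_foam(t, T)
        assert np.abs(relaxed.vertices - t.vertices).max() < 1e-9
        res = balance_residual(relaxed, fmap.tensions, pressures=fmap.pressures)
        assert max(np.linalg.norm(v) for v in res.values()) < 1e-8

    def test_high_tension_junction_shortens(self):
        t = synth.hexagonal_tissue(64)
        target = next(
            j for j in t.junctions
            if not j.is_border
            and all(not x.is_border for x in t.junctions if x.v1 in (j.v1, j.v2) or x.v2 in (j.v1, j.v2))
        )
        T = {j.id: (2.0 if j.id == target.id else 1.0) for j in t.junctions}
        relaxed, _ = synth.equilibrium_foam(t, T)
        new_len = next(j.length for j in relaxed.junctions if j.id == target.id)
        assert new_len < target.length

    def test_lognormal_foam_converges_and_shares_balance_definition(self):
        t = synth.hexagonal_tissue(100)
        T = synth.planted_tensions(t, sigma=0.2, seed=4)
        relaxed, fmap = synth.equilibrium_foam(t, T)
        res = balance_residual(relaxed, fmap.tensions, pressures=fmap.pressures)
        assert max(np.linalg.norm(v) for v in res.values()) < 1e-6

    def test_tension_only_foam_balances_without_pressure(self):
        t = synth.hexagonal_tissue(100)
        relaxed, fmap = synth.tension_only_foam(t, sigma=0.2, seed=4)
        assert fmap.pressures is None
        res = balance_residual(relaxed, fmap.tensions)
        assert max(np.linalg.norm(v) for v in res.values()) < 1e-7
        vals = [fmap.tensions[j.id] for j in relaxed.junctions if not j.is_border]
        assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)
        assert 0.1 < np.std(vals) < 0.3


class TestPlantApoptosis:
    def test_uniform_counts_match_hypergeometric_means(self):
        t = synth.voronoi_tissue(120, seed=2)
        synth.plant_clones(t, [5], compactness=1.0, seed=1)
        clonal = t.clonal_ids()
        rings = neighbor_rings(t, clonal)
        eligible = [c.id for c in t.cells.values() if not c.excluded]
        m = {}
        for cid in eligible:
            m[rings[cid]] = m.get(rings[cid], 0) + 1
        N, n = len(eligible), 12
        reps = 2000
        tot = {r: 0 for r in m}
        for s in range(reps):
            apo = synth.plant_apoptosis(t, clonal, n, seed=s)
            for a in apo:
                tot[rings[a]] = tot.get(rings[a], 0) + 1
                t.cells[a].apoptotic = False
        for r, m_r in m.items():
            expect = n * m_r / N
            p = m_r / N
            se = np.sqrt(reps * n * p * (1 - p)) / reps
            assert abs(tot[r] / reps - expect) < 3 * max(se, 1e-6), f"ring {r}"

    def test_ring_bias_raises_ring0_and_1_counts(self):
        t = synth.voronoi_tissue(120, seed=2)
        synth.plant_clones(t, [5], compactness=1.0, seed=1)
        clonal = t.clonal_ids()
        rings = neighbor_rings(t, clonal)
        hits = 0
        reps = 300
        for s in range(reps):
            apo = synth.plant_apoptosis(
                t, clonal, 10, seed=s, ring_odds={0: 3.0, 1: 3.0}
            )
            hits += sum(1 for a in apo if rings[a] <= 1)
            for a in apo:
                t.cells[a].apoptotic = False
        frac_biased = hits / (10 * reps)
        m01 = sum(1 for c in t.cells.values() if not c.excluded and rings[c.id] <= 1)
        n_elig = sum(1 for c in t.cells.values() if not c.excluded)
        assert frac_biased > 1.5 * m01 / n_elig

    def test_deterministic_and_without_replacement(self):
        t = synth.voronoi_tissue(60, seed=2)
        clonal = set(list(t.cells)[:3])
        a = synth.plant_apoptosis(t, clonal, 15, seed=7)
        assert len(a) == 15
        for c in a:
            t.cells[c].apoptotic = False
        b = synth.plant_apoptosis(t, clonal, 15, seed=7)
        assert a == b


def test_hex_approx_rings_share_generator_with_planted_compact_clones():
    # the spiral polyhex used for ring approximation matches measured
    # rings of a maximally compact planted clone of the same size
    t = synth.hexagonal_tissue(400)
    synth.plant_clones(t, [7], compactness=1.0, seed=0)
    rings = neighbor_rings(t, t.clonal_ids())
    measured = {}
    for cid, r in rings.items():
        if 1 <= r <= 3:
            measured[r] = measured.get(r, 0) + 1
    assert measured == ring_cell_counts(7, mode="hex-approx")
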