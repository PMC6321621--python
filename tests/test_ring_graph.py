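import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import ideal_water, linear_dimer, random_water
from oracles import com_oracle, hbond_edges_oracle, rings_oracle
from twn.ring_graph import (
    WaterRing,
    build_hbond_graph,
    canonical_cycle,
    detect_rings,
    enumerate_rings,
    ring_center_of_mass,
)
from twn.synthetic_data import PlantedRingSpec, generate_planted_frame
from twn.water_model import TIP3PParameters


def graph_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestBuildHBondGraph:
    @pytest.mark.parametrize("n", [0, 1])
    def test_trivial_inputs_give_edgeless_graph(self, n, params):
        waters = [ideal_water(i, (10.0 * i, 0, 0), (1, 0, 0)) for i in range(n)]
        g = build_hbond_graph(waters, params)
        assert g.number_of_nodes() == n
        assert g.number_of_edges() == 0

    def test_planted_dimer_plus_far_water_gives_one_edge(self, params):
        donor, acceptor = linear_dimer()
        far = ideal_water(2, (50, 50, 50), (0, 0, 1))
        g = build_hbond_graph([donor, acceptor, far], params)
        assert set(map(frozenset, g.edges)) == {frozenset((0, 1))}
        assert g.edges[0, 1]["energy"] <= params.e_hbond

    def test_edge_set_matches_double_loop_oracle(self, params):
        rng = np.random.default_rng(11)
        waters = [random_water(rng, i, box=14.0) for i in range(50)]
        # discard geometries too close to be physical
        o = np.stack([w.o_pos for w in waters])
        d = np.linalg.norm(o[:, None] - o[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        waters = [w for k, w in enumerate(waters) if d[k].min() > 1.8]
        g = build_hbond_graph(waters, params)
        assert set(map(frozenset, g.edges)) == hbond_edges_oracle(waters, params)

    def test_prescreen_is_result_identical_to_all_pairs(self, params):
        rng = np.random.default_rng(23)
        waters = [random_water(rng, i, box=16.0) for i in range(60)]
        g_fast = build_hbond_graph(waters, params, prescreen=6.0)
        g_full = build_hbond_graph(waters, params, prescreen=None)
        assert set(map(frozenset, g_fast.edges)) == set(map(frozenset, g_full.edges))

    def test_duplicate_ids_rejected(self, params):
        waters = [
            ideal_water(0, (0, 0, 0), (1, 0, 0)),
            ideal_water(0, (10, 0, 0), (1, 0, 0)),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_hbond_graph(waters, params)

    def test_lower_criterion_never_adds_edges(self, params):
        """Making e_hbond more negative can only remove hydrogen bonds."""
        frame = generate_planted_frame(
            [PlantedRingSpec(5)], seed=3, validate=True
        )
        edges_default = set(
            map(frozenset, build_hbond_graph(frame.waters, params).edges)
        )
        stricter = TIP3PParameters(e_hbond=-4.0)
        edges_strict = set(
            map(frozenset, build_hbond_graph(frame.waters, stricter).edges)
        )
        assert edges_strict <= edges_default


class TestEnumerateRings:
    def test_empty_graph_has_no_rings(self):
        assert enumerate_rings(nx.Graph()) == set()

    def test_triangle_gives_exactly_one_three_ring(self):
        g = graph_from_edges([(0, 1), (1, 2), (2, 0)])
        rings = enumerate_rings(g)
        assert {r.members for r in rings} == {(0, 1, 2)}

    def test_k4_has_four_triangles_and_three_squares(self):
        g = nx.complete_graph(4)
        rings = enumerate_rings(g)
        assert len(rings) == 7
        assert sum(1 for r in rings if r.size == 3) == 4
        assert sum(1 for r in rings if r.size == 4) == 3
        # cross-check against the exhaustive subset oracle
        assert {r.members for r in rings} == rings_oracle(g.nodes, g.edges)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_subset_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        rings = enumerate_rings(g)
        assert {r.members for r in rings} == rings_oracle(g.nodes, g.edges)

    def test_matches_networkx_bounded_simple_cycles(self):
        """Independent library cross-check on a denser graph."""
        g = nx.gnp_random_graph(11, 0.4, seed=99)
        ours = {r.members for r in enumerate_rings(g)}
        reference = {
            canonical_cycle(c)
            for c in nx.simple_cycles(g, length_bound=6)
            if len(c) >= 3
        }
        assert ours == reference

    def test_ring_count_invariant_under_node_relabeling(self):
        g = nx.gnp_random_graph(10, 0.35, seed=5)
        rng = np.random.default_rng(8)
        for _ in range(10):
            perm = rng.permutation(10)
            h = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(10)})
            assert len(enumerate_rings(h)) == len(enumerate_rings(g))

    def test_size_bounds_respected(self):
        g = nx.cycle_graph(8)
        assert enumerate_rings(g, 3, 6) == set()
        rings = enumerate_rings(g, 3, 8)
        assert {r.size for r in rings} == {8}

    def test_invalid_size_bounds_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rings(nx.Graph(), min_size=2)
        with pytest.raises(ValueError):
            enumerate_rings(nx.Graph(), min_size=5, max_size=4)

    def test_chordless_mode_drops_chorded_cycles(self):
        # a square with one diagonal: two triangles, one chorded 4-cycle
        g = graph_from_edges([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        all_rings = enumerate_rings(g)
        chordless = enumerate_rings(g, chordless=True)
        assert {r.members for r in all_rings} == {(0, 1, 2), (0, 2, 3), (0, 1, 2, 3)}
        assert {r.members for r in chordless} == {(0, 1, 2), (0, 2, 3)}

    def test_canonical_form_starts_small_and_goes_toward_smaller_neighbor(self):
        assert canonical_cycle([4, 2, 9, 7]) == (2, 4, 7, 9)
        assert canonical_cycle([3, 1, 2]) == (1, 2, 3)
        # reflection and rotation collapse to one representative
        for rot in range(4):
            cyc = [5, 8, 6, 7][rot:] + [5, 8, 6, 7][:rot]
            assert canonical_cycle(cyc) == canonical_cycle(cyc[::-1])


class TestRingCenterOfMass:
    def test_symmetric_square_ring_com_at_origin(self):
        frame = generate_planted_frame([PlantedRingSpec(4)], seed=0)
        (ring,) = detect_rings(frame.waters)
        # planted geometry is symmetric about the ring centre in x and y
        assert ring.com[0] == pytest.approx(0.0, abs=1e-9)
        assert ring.com[1] == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self):
        frame = generate_planted_frame([PlantedRingSpec(3)], seed=0)
        lookup = frame.water_lookup()
        ring = WaterRing((0, 1, 2))
        com0 = ring_center_of_mass(ring, lookup)
        t = np.array([1.5, -2.0, 4.25])
        shifted = {k: w.translated(t) for k, w in lookup.items()}
        com1 = ring_center_of_mass(ring, shifted)
        np.testing.assert_allclose(com1, com0 + t, atol=1e-12)

    def test_matches_flat_weighted_sum_oracle(self):
        rng = np.random.default_rng(17)
        waters = {i: random_water(rng, i) for i in range(3)}
        ring = WaterRing((0, 1, 2))
        com = ring_center_of_mass(ring, waters)
        np.testing.assert_allclose(com, com_oracle(waters.values()), atol=1e-12)

    def test_missing_member_is_usage_error(self):
        with pytest.raises(ValueError, match="member"):
            ring_center_of_mass(WaterRing((0, 1, 2)), {})


class TestDetectRings:
    def test_planted_frame_pipeline(self, params):
        frame = generate_planted_frame(
            [PlantedRingSpec(6), PlantedRingSpec(3, center=(12, 0, 0))], seed=1
        )
        rings = detect_rings(frame.waters, params, frame_index=frame.frame_index)
        assert sorted((r.size, r.members) for r in rings) == [
            (3, (6, 7, 8)),
            (6, (0, 1, 2, 3, 4, 5)),
        ]
        for r in rings:
            assert r.com is not None
            assert r.frame_index == frame.frame_index
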