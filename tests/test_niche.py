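"""Niche rings, ring differential expression, line scans, shell fractions."""

from collections import deque

import numpy as np
import pytest

from ifniche.colony import colony_stats, segment_colonies
from ifniche.containers import GeneSet
from ifniche.errors import ValidationError
from ifniche.io import normalize_log10k
from ifniche.lattice import build_adjacency, full_hex_lattice
from ifniche.niche import (
    assign_rings,
    line_scan,
    neighbor_fraction_profile,
    ring_de,
)
from ifniche.scoring import ScoreVector
from ifniche.simulate import SimulationConfig, make_lattice_sample


def bfs_all_distances(graph, sources):
    dist = {int(s): 0 for s in sources}
    q = deque(dist)
    while q:
        u = q.popleft()
        for v in graph.neighbors(u):
            v = int(v)
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _colony_at(graph, lattice, members, scores=None):
    states = np.zeros(graph.n, bool)
    states[members] = True
    return colony_stats(segment_colonies(states, graph), lattice, scores=scores)


class TestAssignRings:
    def test_interior_ring_sizes_6_12_18(self):
        lat = full_hex_lattice(11, 11)
        g = build_adjacency(lat)
        center = int(np.argmin(np.linalg.norm(g.coords_um - g.coords_um.mean(axis=0), axis=1)))
        nb = [int(v) for v in g.neighbors(center)]
        colonies = _colony_at(g, lat, [center, nb[0]],
                              scores=np.eye(1, g.n, center).ravel())
        rings = assign_rings(colonies, g, max_ring=3)
        assert (rings.ring == 1).sum() == 6
        assert (rings.ring == 2).sum() == 12
        assert (rings.ring == 3).sum() == 18

    def test_edge_centroid_rings_smaller(self, small_graph, small_lattice):
        colonies = _colony_at(small_graph, small_lattice, [0, 1],
                              scores=np.eye(1, small_graph.n, 0).ravel())
        rings = assign_rings(colonies, small_graph, max_ring=3)
        assert (rings.ring == 1).sum() < 6

    def test_ring_equals_bfs_distance_oracle(self, small_graph, small_lattice, rng):
        center = int(np.argmax(small_graph.degree() == 6))
        nb = int(small_graph.neighbors(center)[0])
        scores = np.zeros(small_graph.n)
        scores[center] = 1.0
        colonies = _colony_at(small_graph, small_lattice, [center, nb], scores=scores)
        rings = assign_rings(colonies, small_graph, max_ring=3)
        dist = bfs_all_distances(small_graph, [center])
        for spot in range(small_graph.n):
            expected = dist.get(spot, 99)
            if spot == nb:
                continue  # colony member keeps its own assignment
            assert rings.ring[spot] == (expected if expected <= 3 else -1)

    def test_tie_goes_to_lower_colony_id(self):
        lat = full_hex_lattice(3, 5)
        g = build_adjacency(lat)
        # two colonies whose centroids are 2 steps apart along a row
        row0 = np.flatnonzero(lat.table["array_row"].to_numpy() == 1)
        a, b, c = row0[1], row0[2], row0[3]
        states = np.zeros(g.n, bool)
        scores = np.zeros(g.n)
        # colony 0 = {a, a_nbr}, colony 1 = {c, c_nbr}; spot b equidistant
        a_nbr = [v for v in g.neighbors(a) if v not in (b,)][0]
        c_nbr = [v for v in g.neighbors(c) if v not in (b, a_nbr)][0]
        states[[a, a_nbr, c, c_nbr]] = True
        scores[[a, c]] = 5.0
        colonies = colony_stats(segment_colonies(states, g),
                                lat, scores=scores)
        rings = assign_rings(colonies, g, max_ring=3)
        assert rings.ring[b] == 1
        assert rings.colony_id[b] == 0


@pytest.fixture(scope="module")
def gradient_sample():
    # compact 2-spot colonies with a diffusive ISG halo: the field decays
    # ring by ring away from the centroid, as secreted interferon would
    cfg = SimulationConfig(
        seed=21, n_colonies=8, colony_size_range=(2, 2), isg_halo_decay=0.5
    )
    lat, counts, truth = make_lattice_sample(cfg)
    g = build_adjacency(lat)
    states = np.zeros(g.n, bool)
    for idx in truth.colony_spot_indices.values():
        states[idx] = True
    from ifniche.scoring import score_gene_set

    gs = GeneSet("isg", list(cfg.isg_genes), "ISG")
    scores = score_gene_set(counts, gs, "summed_counts")
    colonies = colony_stats(segment_colonies(states, g), lat, scores=scores.values)
    rings = assign_rings(colonies, g)
    return cfg, normalize_log10k(counts), rings


class TestRingDE:

    def test_isg_lnfc_negative_and_monotone_with_distance(self, gradient_sample):
        cfg, ln, rings = gradient_sample
        de = ring_de(ln, rings)
        fc = {
            k: de[k].table.set_index("gene").loc["Ifit1", "ln_fc"] for k in (1, 2, 3)
        }
        assert fc[1] < 0 and fc[2] < fc[1] and fc[3] < fc[2]

    def test_matricellular_elevated_away_from_centroid(self, gradient_sample):
        # colonies sit in the borderzone where the activated-fibroblast
        # program is high outside (but not inside) colonies
        cfg, ln, rings = gradient_sample
        de = ring_de(ln, rings)
        assert de[3].table.set_index("gene").loc["Postn", "ln_fc"] > 0

    def test_flat_gene_not_significant(self, gradient_sample):
        cfg, ln, rings = gradient_sample
        de = ring_de(ln, rings)
        # housekeeping background is flat across rings
        assert de[1].table.set_index("gene").loc["Gapdh", "p_adj"] > 0.05


class TestLineScan:
    def _scores(self, values):
        return ScoreVector(np.asarray(values, float), "summed_counts", GeneSet("s", ["g"]))

    def test_uniform_field_flat_profile(self, small_lattice):
        res = line_scan(self._scores(np.ones(small_lattice.n_spots)), small_lattice,
                        (0.0, 0.0), (800.0, 0.0))
        means = res.bins.loc[res.bins["n"] > 0, "mean"]
        assert np.allclose(means, 1.0)

    def test_step_field_recovered_in_correct_bin(self, small_lattice):
        x = small_lattice.coords_um[:, 0]
        values = (x >= 400).astype(float)
        res = line_scan(self._scores(values), small_lattice, (0.0, 0.0), (800.0, 0.0),
                        bin_um=100.0)
        lo = res.bins[res.bins["distance_hi_um"] <= 400]
        hi = res.bins[res.bins["distance_lo_um"] >= 400]
        assert (lo.loc[lo["n"] > 0, "mean"] == 0).all()
        assert (hi.loc[hi["n"] > 0, "mean"] == 1).all()

    def test_band_excludes_far_spots(self, small_lattice):
        values = np.ones(small_lattice.n_spots)
        res = line_scan(self._scores(values), small_lattice, (0.0, 0.0), (800.0, 0.0),
                        band_halfwidth_um=50.0)
        y = small_lattice.coords_um[:, 1]
        assert res.bins["n"].sum() == int((y <= 50.0).sum())

    def test_rotation_invariance(self):
        # rotate lattice coordinates and endpoints jointly by 37 degrees
        lat = full_hex_lattice(8, 8)
        values = np.arange(lat.n_spots, dtype=float)
        res1 = line_scan(self._scores(values), lat, (0.0, 0.0), (500.0, 100.0))
        th = np.deg2rad(37)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        table = lat.table.copy()
        rot = lat.coords_um @ R.T
        table["x_um"], table["y_um"] = rot[:, 0], rot[:, 1]
        from ifniche.lattice import SpotLattice

        lat2 = SpotLattice(table)
        res2 = line_scan(self._scores(values), lat2,
                         tuple(R @ np.array([0.0, 0.0])), tuple(R @ np.array([500.0, 100.0])))
        assert np.allclose(res1.bins["mean"], res2.bins["mean"], equal_nan=True)

    def test_degenerate_vector_rejected(self, small_lattice):
        with pytest.raises(ValidationError):
            line_scan(self._scores(np.ones(small_lattice.n_spots)), small_lattice,
                      (1.0, 1.0), (1.0, 1.0))


class TestNeighborFractions:
    def test_all_negative_and_all_positive_query(self, small_graph):
        ref = np.zeros(small_graph.n, bool)
        ref[0] = True
        zeros = neighbor_fraction_profile(ref, np.zeros(small_graph.n, bool), small_graph)
        ones = neighbor_fraction_profile(ref, np.ones(small_graph.n, bool), small_graph)
        assert (zeros.loc[zeros["n_spots"] > 0, "fraction"] == 0).all()
        assert (ones.loc[ones["n_spots"] > 0, "fraction"] == 1).all()

    def test_matches_shell_enumeration_oracle(self, small_graph, rng):
        ref = rng.random(small_graph.n) < 0.1
        if not ref.any():
            ref[0] = True
        query = ~ref
        res = neighbor_fraction_profile(ref, query, small_graph)
        dist = bfs_all_distances(small_graph, np.flatnonzero(ref))
        for _, row in res.iterrows():
            shell = [s for s, d in dist.items() if d == row["ring"]]
            assert row["n_spots"] == len(shell)
            if shell:
                assert row["fraction"] == pytest.approx(np.mean([query[s] for s in shell]))

    def test_shells_partition_union(self, small_graph, rng):
        ref = np.zeros(small_graph.n, bool)
        ref[rng.choice(small_graph.n, 3, replace=False)] = True
        res = neighbor_fraction_profile(ref, ~ref, small_graph, max_distance_um=400.0)
        dist = bfs_all_distances(small_graph, np.flatnonzero(ref))
        union = sum(1 for d in dist.values() if 1 <= d <= 4)
        assert res["n_spots"].sum() == union

    def test_empty_reference_rejected(self, small_graph):
        with pytest.raises(ValidationError):
            neighbor_fraction_profile(
                np.zeros(small_graph.n, bool), np.ones(small_graph.n, bool), small_graph
            )
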