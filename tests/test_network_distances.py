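"""Geodesic distances and disc-boundary counts vs brute-force oracles."""

import math

import numpy as np
import pytest

from mitonet.network_distances import (
    GeodesicStructure,
    NetworkLocation,
    disc_boundary_count,
    geodesic_distance,
)

from conftest import random_tree


def _subdivide(network, step=0.02):
    """Dense-subdivision oracle graph: nodes every `step` um along each edge.

    Returns (adjacency dict, node coordinates dict, locator) where locator
    maps (edge_id, offset) to the nearest subdivision node.
    """
    import networkx as nx

    g = nx.Graph()
    node_of = {}
    for e in network.edges:
        n_seg = max(1, int(round(e.length_um / step)))
        ds = np.linspace(0.0, e.length_um, n_seg + 1)
        names = []
        for k, d in enumerate(ds):
            if k == 0:
                names.append(("v", e.u))
            elif k == n_seg:
                names.append(("v", e.v))
            else:
                names.append(("e", e.id, k))
        for a, b, da, db in zip(names[:-1], names[1:], ds[:-1], ds[1:]):
            g.add_edge(a, b, weight=db - da)
        node_of[e.id] = (names, ds)

    def locate(loc):
        names, ds = node_of[loc.edge_id]
        return names[int(np.argmin(np.abs(ds - loc.offset_um)))]

    return g, locate


class TestGeodesicDistance:
    def test_same_edge_straight(self, segment_10um):
        e = segment_10um.edges[0].id
        d = geodesic_distance(segment_10um, NetworkLocation(e, 2.0), NetworkLocation(e, 7.0))
        assert d == pytest.approx(5.0)

    def test_cycle_takes_shorter_way_round(self, cycle_10um):
        e = cycle_10um.edges[0].id
        L = cycle_10um.edges[0].length_um
        a = NetworkLocation(e, 0.0)
        b = NetworkLocation(e, 0.7 * L)
        assert geodesic_distance(cycle_10um, a, b) == pytest.approx(0.3 * L, rel=1e-6)

    def test_different_clusters_infinite(self, two_segment_network):
        ids = [e.id for e in two_segment_network.edges]
        d = geodesic_distance(
            two_segment_network, NetworkLocation(ids[0], 0.5), NetworkLocation(ids[1], 0.5)
        )
        assert math.isinf(d)

    def test_invalid_offset_rejected(self, segment_10um):
        e = segment_10um.edges[0].id
        with pytest.raises(ValueError):
            geodesic_distance(segment_10um, NetworkLocation(e, 99.0), NetworkLocation(e, 1.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_subdivision_oracle(self, seed):
        import networkx as nx

        net = random_tree(seed)
        geo = GeodesicStructure(net)
        g, locate = _subdivide(net, step=0.02)
        rng = np.random.default_rng(100 + seed)
        eids = [e.id for e in net.edges]
        for _ in range(20):
            ea, eb = rng.choice(eids, size=2)
            a = NetworkLocation(int(ea), rng.uniform(0, net.edge(int(ea)).length_um))
            b = NetworkLocation(int(eb), rng.uniform(0, net.edge(int(eb)).length_um))
            want = nx.shortest_path_length(g, locate(a), locate(b), weight="weight")
            got = geo.point_distance(a, b)
            assert got == pytest.approx(want, abs=0.05)

    def test_symmetry_and_triangle_inequality(self):
        net = random_tree(7)
        geo = GeodesicStructure(net)
        rng = np.random.default_rng(7)
        eids = [e.id for e in net.edges]
        locs = [
            NetworkLocation(int(e), rng.uniform(0, net.edge(int(e)).length_um))
            for e in rng.choice(eids, size=12)
        ]
        for a in locs[:4]:
            for b in locs[4:8]:
                dab = geo.point_distance(a, b)
                assert dab == pytest.approx(geo.point_distance(b, a), rel=1e-9)
                for c in locs[8:]:
                    assert dab <= geo.point_distance(a, c) + geo.point_distance(c, b) + 1e-9


class TestDiscBoundaryCount:
    def test_segment_interior(self, segment_10um):
        e = segment_10um.edges[0].id
        u = NetworkLocation(e, 5.0)
        assert disc_boundary_count(segment_10um, u, 3.0) == 2
        assert disc_boundary_count(segment_10um, u, 6.0) == 0

    def test_local_degree_at_zero(self, segment_10um, y_network):
        e = segment_10um.edges[0].id
        assert disc_boundary_count(segment_10um, NetworkLocation(e, 5.0), 0.0) == 2
        assert disc_boundary_count(segment_10um, NetworkLocation(e, 0.0), 0.0) == 1
        # a point at the junction of the Y has local degree 3
        geo = GeodesicStructure(y_network)
        for ee in y_network.edges:
            for off in (0.0, ee.length_um):
                loc = NetworkLocation(ee.id, off)
                if geo.local_degree(loc) == 3:
                    assert geo.boundary_counts(loc, 0.0) == 3
                    return
        pytest.fail("no junction-end location found")

    def test_y_network_hand_count(self, y_network):
        # u on one arm, 2 um from the junction; t = 5 reaches one point
        # outward on its own arm and one on each of the other two arms
        geo = GeodesicStructure(y_network)
        junction = next(v.id for v in y_network.vertices if v.kind == "junction")
        e = y_network.edges[0]
        off = 2.0 if e.u == junction else e.length_um - 2.0
        assert geo.boundary_counts(NetworkLocation(e.id, off), 5.0) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_subdivision_oracle(self, seed):
        """m(u, t) equals the derivative of covered length from brute force."""
        import networkx as nx

        net = random_tree(200 + seed, n_nodes=8)
        geo = GeodesicStructure(net)
        step = 0.01
        g, locate = _subdivide(net, step=step)
        rng = np.random.default_rng(seed)
        eids = [e.id for e in net.edges]
        e = int(rng.choice(eids))
        u = NetworkLocation(e, rng.uniform(0.2, net.edge(e).length_um - 0.2))
        dist = nx.single_source_dijkstra_path_length(g, locate(u), weight="weight")
        dvals = np.array(list(dist.values()))
        eps = 0.05
        for t in rng.uniform(0.5, 8.0, size=6):
            # covered-length derivative: (L(t+eps) - L(t-eps)) / (2 eps)
            want = ((dvals <= t + eps).sum() - (dvals <= t - eps).sum()) * step / (2 * eps)
            got = float(geo.boundary_counts(u, float(t)))
            assert got == pytest.approx(want, abs=0.6)

    @pytest.mark.parametrize("seed", range(3))
    def test_integral_of_m_equals_cluster_length(self, seed):
        net = random_tree(300 + seed, n_nodes=8)
        geo = GeodesicStructure(net)
        rng = np.random.default_rng(seed)
        e = int(rng.choice([ed.id for ed in net.edges]))
        u = NetworkLocation(e, rng.uniform(0, net.edge(e).length_um))
        cl = net.clusters[net.cluster_of_edge[e]]
        dt = 0.003
        ts = np.arange(dt / 2, 200.0, dt)  # beyond any eccentricity
        total = float(geo.boundary_counts(u, ts).sum() * dt)
        assert total == pytest.approx(cl.length_um, rel=0.01)

    def test_m_at_least_one_for_realized_pairs(self):
        net = random_tree(11)
        geo = GeodesicStructure(net)
        rng = np.random.default_rng(11)
        from mitonet.linear_pcf import simulate_irp

        pat = simulate_irp(net, 15, rng)
        D = geo.pairwise_matrix(pat.points)
        for i in range(15):
            d = np.delete(D[i], i)
            m = geo.boundary_counts(pat.points[i], d)
            assert np.all(m >= 1)
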