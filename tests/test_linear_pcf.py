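"""Linear-network pcf, nndist, IRP simulation and normalization."""

import math

import numpy as np
import pytest

from mitonet.network_distances import GeodesicStructure, NetworkLocation
from mitonet.linear_pcf import (
    NetworkPointPattern,
    PcfConfig,
    cluster_pcf,
    nndist,
    normalize_to_irp,
    pooled_pcf,
    random_removal,
    simulate_irp,
)
from mitonet.synthetic import FixtureSpec, make_network, network_from_polylines, sample_point_process

from conftest import PIXEL_SIZE


def _segment(length_um, y=1.0, pixel_size=PIXEL_SIZE):
    return network_from_polylines([np.array([[y, 0.0], [y, length_um]])], pixel_size)


class TestClusterPcf:
    def test_two_point_closed_form(self):
        """Two points at distance d on a segment: the curve at r = d equals
        (l/2) * kappa(0) * (1/m(x1,d) + 1/m(x2,d)) with kappa(0) the Gaussian
        peak -- evaluated by hand from the estimator definition."""
        net = _segment(30.0)
        e = net.edges[0].id
        pts = [NetworkLocation(e, 12.0), NetworkLocation(e, 22.0)]
        pat = NetworkPointPattern(net, pts)
        geo = GeodesicStructure(net)
        cfg = PcfConfig(bandwidth_px=5.0, r_max_px=300.0)
        curve = cluster_pcf(pat, 0, geo=geo, config=cfg)
        d = 10.0
        sigma = cfg.bandwidth_um(PIXEL_SIZE)
        # by hand: the r=10 sphere around x1=12 hits offsets 2 and 22 (m=2);
        # around x2=22 it hits offset 12 only, 32 being off the segment (m=1)
        kappa0 = 1.0 / (sigma * math.sqrt(2 * math.pi))
        want = (30.0 / 2.0) * kappa0 * (1.0 / 2 + 1.0 / 1)
        i = int(np.argmin(np.abs(curve.r - d)))
        assert curve.r[i] == pytest.approx(d)
        assert curve.g[i] == pytest.approx(want, rel=1e-6)

    def test_single_point_cluster_rejected(self):
        net = _segment(10.0)
        pat = NetworkPointPattern(net, [NetworkLocation(net.edges[0].id, 3.0)])
        with pytest.raises(ValueError):
            cluster_pcf(pat, 0)

    def test_irp_on_long_segment_averages_to_one(self):
        """Estimator calibration: mean over replicates of g on uniform points
        stays within 5% of 1 over [sigma, r_max/2]."""
        net = _segment(300.0, pixel_size=0.06)
        geo = GeodesicStructure(net)
        cfg = PcfConfig()
        rng = np.random.default_rng(42)
        curves = []
        for _ in range(20):
            pat = simulate_irp(net, 100, rng)
            curves.append(cluster_pcf(pat, 0, geo=geo, config=cfg).g)
        g = np.mean(curves, axis=0)
        r = cfg.r_grid_um(0.06)
        sigma = cfg.bandwidth_um(0.06)
        win = (r >= sigma) & (r <= r.max() / 2)
        assert np.abs(g[win].mean() - 1.0) < 0.05


class TestPooledPcf:
    def test_single_cluster_identity(self):
        net = _segment(50.0)
        geo = GeodesicStructure(net)
        rng = np.random.default_rng(0)
        pat = simulate_irp(net, 12, rng)
        a = cluster_pcf(pat, 0, geo=geo)
        b = pooled_pcf(pat, net, geo=geo)
        assert np.allclose(a.g, b.g)

    def test_two_identical_clusters_double_by_printed_formula(self):
        """The printed pooling formula scales with the number of clusters:
        duplicating the cluster and its points doubles the curve."""
        one = _segment(40.0)
        two = network_from_polylines(
            [np.array([[1.0, 0.0], [1.0, 40.0]]), np.array([[5.0, 0.0], [5.0, 40.0]])],
            PIXEL_SIZE,
        )
        offs = [5.0, 11.0, 19.0, 30.0]
        pat1 = NetworkPointPattern(one, [NetworkLocation(one.edges[0].id, o) for o in offs])
        pts2 = [NetworkLocation(e.id, o) for e in two.edges for o in offs]
        pat2 = NetworkPointPattern(two, pts2)
        g1 = pooled_pcf(pat1, one).g
        g2 = pooled_pcf(pat2, two).g
        assert np.allclose(g2, 2.0 * g1, rtol=1e-9)

    def test_weighted_variant_is_duplication_invariant(self):
        two = network_from_polylines(
            [np.array([[1.0, 0.0], [1.0, 40.0]]), np.array([[5.0, 0.0], [5.0, 40.0]])],
            PIXEL_SIZE,
        )
        one = _segment(40.0)
        offs = [5.0, 11.0, 19.0, 30.0]
        pat1 = NetworkPointPattern(one, [NetworkLocation(one.edges[0].id, o) for o in offs])
        pat2 = NetworkPointPattern(two, [NetworkLocation(e.id, o) for e in two.edges for o in offs])
        g1 = pooled_pcf(pat1, one, method="weighted").g
        g2 = pooled_pcf(pat2, two, method="weighted").g
        assert np.allclose(g2, g1, rtol=1e-9)

    def test_singleton_clusters_are_ignored(self, two_segment_network):
        net = two_segment_network
        e_big = net.clusters[0].edge_ids[0]
        e_small = net.clusters[1].edge_ids[0]
        pts = [
            NetworkLocation(e_big, 0.5),
            NetworkLocation(e_big, 1.5),
            NetworkLocation(e_small, 0.5),  # lone point: zero weight
        ]
        pat = NetworkPointPattern(net, pts)
        pat_no_lone = NetworkPointPattern(net, pts[:2])
        assert np.allclose(pooled_pcf(pat, net).g, pooled_pcf(pat_no_lone, net).g)

    def test_no_eligible_cluster_errors(self, two_segment_network):
        net = two_segment_network
        pat = NetworkPointPattern(net, [NetworkLocation(net.clusters[0].edge_ids[0], 1.0)])
        with pytest.raises(ValueError):
            pooled_pcf(pat, net)


class TestNndist:
    def test_hand_computed_segment(self):
        net = _segment(10.0)
        e = net.edges[0].id
        pat = NetworkPointPattern(net, [NetworkLocation(e, o) for o in (0.0, 3.0, 4.0)])
        res = nndist(pat)
        assert sorted(res.distances.tolist()) == pytest.approx([1.0, 1.0, 3.0])
        assert res.mean == pytest.approx(5.0 / 3.0)

    def test_lone_point_excluded(self, two_segment_network):
        net = two_segment_network
        e_big = net.clusters[0].edge_ids[0]
        e_small = net.clusters[1].edge_ids[0]
        pat = NetworkPointPattern(
            net,
            [NetworkLocation(e_big, 0.2), NetworkLocation(e_big, 1.0), NetworkLocation(e_small, 0.5)],
        )
        res = nndist(pat)
        assert len(res.distances) == 2
        assert res.mean == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self, comb_network):
        geo = GeodesicStructure(comb_network)
        pat = simulate_irp(comb_network, 40, np.random.default_rng(5))
        res = nndist(pat, geo=geo)
        # O(n^2) oracle via point-by-point geodesic distances
        want = []
        for i, p in enumerate(pat.points):
            d = [geo.point_distance(p, q) for j, q in enumerate(pat.points) if j != i]
            want.append(min(d))
        assert res.mean == pytest.approx(np.mean(want), rel=1e-9)

    def test_raw_nndist_decreases_with_density(self, comb_network):
        rng = np.random.default_rng(9)
        geo = GeodesicStructure(comb_network)
        sparse = np.mean([nndist(simulate_irp(comb_network, 25, rng), geo=geo).mean for _ in range(5)])
        dense = np.mean([nndist(simulate_irp(comb_network, 150, rng), geo=geo).mean for _ in range(5)])
        assert dense < sparse


class TestSimulateIrp:
    def test_length_proportional_allocation(self):
        net = network_from_polylines(
            [np.array([[1.0, 0.0], [1.0, 9.0]]), np.array([[3.0, 0.0], [3.0, 1.0]])], PIXEL_SIZE
        )
        long_edge = max(net.edges, key=lambda e: e.length_um).id
        pat = simulate_irp(net, 10_000, np.random.default_rng(0))
        frac = np.mean([p.edge_id == long_edge for p in pat.points])
        assert frac == pytest.approx(0.9, abs=0.01)

    def test_points_lie_on_network_and_seed_reproducible(self, comb_network):
        pat1 = simulate_irp(comb_network, 50, np.random.default_rng(3))
        pat2 = simulate_irp(comb_network, 50, np.random.default_rng(3))
        assert pat1.points == pat2.points
        for p in pat1.points:
            assert 0 <= p.offset_um <= comb_network.edge(p.edge_id).length_um

    def test_empty_network_rejected(self):
        from mitonet.network_graph import LinearNetwork, Vertex

        net = LinearNetwork([Vertex(0, 0.0, 0.0, "isolated")], [], 0.1)
        with pytest.raises(ValueError):
            simulate_irp(net, 3, np.random.default_rng(0))


class TestNormalizeToIrp:
    def test_default_replicates_is_six(self):
        assert PcfConfig().irp_replicates == 6

    def test_irp_ratio_fluctuates_about_one(self, comb_network):
        """An IRP normalized by the 6-IRP average gives a ratio near 1 when
        averaged over [sigma, 3 um] and several patterns."""
        geo = GeodesicStructure(comb_network)
        rng = np.random.default_rng(11)
        cfg = PcfConfig(rng_seed=11)
        ps = comb_network.pixel_size
        vals = []
        for k in range(6):
            pat = simulate_irp(comb_network, 120, rng)
            raw = pooled_pcf(pat, comb_network, config=cfg, geo=geo)
            ratio = normalize_to_irp(raw, pat, comb_network, config=cfg, geo=geo)
            win = (ratio.r >= cfg.bandwidth_um(ps)) & (ratio.r <= 3.0)
            vals.append(np.nanmean(ratio.g[win]))
        assert abs(np.mean(vals) - 1.0) < 0.1

    def test_nndist_ratio_near_one_for_irp(self, comb_network):
        geo = GeodesicStructure(comb_network)
        rng = np.random.default_rng(13)
        cfg = PcfConfig(rng_seed=13)
        ratios = []
        for _ in range(10):
            pat = simulate_irp(comb_network, 60, rng)
            res = normalize_to_irp(nndist(pat, geo=geo), pat, comb_network, config=cfg, geo=geo)
            ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_zero_denominator_gives_nan_not_inf(self):
        # two close points on a long segment: IRP average is 0 at large r
        net = _segment(300.0, pixel_size=0.06)
        e = net.edges[0].id
        pat = NetworkPointPattern(net, [NetworkLocation(e, 10.0), NetworkLocation(e, 10.4)])
        cfg = PcfConfig(rng_seed=1)
        raw = pooled_pcf(pat, net, config=cfg)
        ratio = normalize_to_irp(raw, pat, net, config=cfg)
        assert not np.any(np.isinf(ratio.g))
        assert np.any(np.isnan(ratio.g))

    def test_deterministic_given_seed(self, comb_network):
        pat = simulate_irp(comb_network, 40, np.random.default_rng(2))
        cfg = PcfConfig(rng_seed=7)
        raw = pooled_pcf(pat, comb_network, config=cfg)
        a = normalize_to_irp(raw, pat, comb_network, config=cfg)
        b = normalize_to_irp(raw, pat, comb_network, config=cfg)
        assert np.array_equal(a.g, b.g, equal_nan=True)


class TestRandomRemoval:
    def test_keep_all_is_identity(self, comb_network):
        pat = simulate_irp(comb_network, 30, np.random.default_rng(1))
        out = random_removal(pat, 30, np.random.default_rng(2))
        assert out.points == pat.points

    def test_keep_k_subset(self, comb_network):
        pat = simulate_irp(comb_network, 30, np.random.default_rng(1))
        out = random_removal(pat, 12, np.random.default_rng(2))
        assert out.n_total == 12
        assert set(out.points) <= set(pat.points)

    def test_keep_too_many_rejected(self, comb_network):
        pat = simulate_irp(comb_network, 5, np.random.default_rng(1))
        with pytest.raises(ValueError):
            random_removal(pat, 9, np.random.default_rng(2))


class TestStructuredPatterns:
    def test_hardcore_ratio_below_half_at_short_range(self, comb_network):
        """Minimum spacing of 1 um empties the pcf below the spacing."""
        spec = FixtureSpec(point_kind="hardcore", hardcore_delta_um=1.0, n_points=100)
        geo = GeodesicStructure(comb_network)
        cfg = PcfConfig(rng_seed=21)
        vals = []
        for s in range(3):
            pat = sample_point_process(comb_network, spec, np.random.default_rng(100 + s))
            raw = pooled_pcf(pat, comb_network, config=cfg, geo=geo)
            ratio = normalize_to_irp(raw, pat, comb_network, config=cfg, geo=geo)
            win = ratio.r <= 0.5
            vals.append(np.nanmean(ratio.g[win]))
        assert np.mean(vals) < 0.5

    def test_cluster_process_ratio_above_one_at_short_range(self, comb_network):
        spec = FixtureSpec(
            point_kind="cluster", cluster_parents=6, cluster_radius_um=1.0, cluster_offspring=12
        )
        geo = GeodesicStructure(comb_network)
        cfg = PcfConfig(rng_seed=22)
        pat = sample_point_process(comb_network, spec, np.random.default_rng(22))
        raw = pooled_pcf(pat, comb_network, config=cfg, geo=geo)
        ratio = normalize_to_irp(raw, pat, comb_network, config=cfg, geo=geo)
        win = (ratio.r > 0) & (ratio.r <= 1.0)
        assert np.nanmean(ratio.g[win]) > 1.0
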