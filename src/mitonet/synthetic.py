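"""Ground-truth fixtures: networks, point processes on them, raster images.

Every stage of the pipeline can be exercised without microscopy data:

* ``make_network`` builds exact :class:`LinearNetwork` geometries (segments,
  cycles, disjoint chains, branched trees, grids, random skeletons) with
  known junction/end counts and lengths;
* ``sample_point_process`` places points on them as a uniform random process
  (IRP), a hard-core process with a minimum geodesic spacing (emulating the
  observed inter-nucleoid avoidance), or a cluster process (aggregation);
* ``rasterize`` paints the pair into a two-channel image with tube-like
  mitochondria and Gaussian nucleoid spots plus Poisson noise, retaining the
  ground truth for oracle tests.

Default scales mimic flat fibroblast-like cells: total network length in the
hundreds of um, nucleoid densities of ~0.05/um (sparse) to ~0.3/um (dense),
pixel size 0.06 um so that a 5 px kernel bandwidth corresponds to a ~0.3 um
nucleoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_pipeline import ImageSet
from .network_graph import Edge, LinearNetwork, Vertex
from .network_distances import GeodesicStructure, NetworkLocation
from .linear_pcf import NetworkPointPattern, simulate_irp

__all__ = [
    "FixtureSpec",
    "make_network",
    "sample_point_process",
    "rasterize",
    "network_from_polylines",
    "location_to_xy",
    "DEFAULT_PIXEL_SIZE_UM",
]

DEFAULT_PIXEL_SIZE_UM = 0.06


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture (network + points + raster)."""

    network_kind: str = "tree"  # segment|cycle|chain_of_segments|tree|grid|random_skeleton
    total_length_um: float = 500.0
    n_branches: int = 16
    n_chains: int = 10
    radius_um: float = 20.0
    grid_shape: tuple[int, int] = (4, 4)
    grid_spacing_um: float = 10.0
    n_nodes: int = 20
    box_um: float = 60.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    point_kind: str = "irp"  # irp|hardcore|cluster
    density_per_um: float = 0.1
    n_points: int | None = None
    hardcore_delta_um: float = 1.0
    cluster_parents: int = 5
    cluster_radius_um: float = 1.0
    cluster_offspring: int = 10

    tube_width_px: int = 4
    spot_sigma_px: float = 2.0
    snr: float = 10.0
    background: float = 5.0
    noise: bool = True
    margin_px: int = 12
    seed: int = 0


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def network_from_polylines(polylines_um: list[np.ndarray], pixel_size: float) -> LinearNetwork:
    """Assemble a LinearNetwork from polylines given in um coordinates.

    Coincident polyline endpoints (within 1e-6 um) merge into shared
    vertices; vertex kinds follow the final degree (1 end, >= 3 junction).
    A closed polyline (first point == last) becomes a self-loop on a single
    degree-2 anchor vertex.
    """
    key_of: dict[tuple[int, int], int] = {}
    verts: list[list[float]] = []

    def vertex_at(p) -> int:
        key = (int(round(p[0] * 1e6)), int(round(p[1] * 1e6)))
        if key not in key_of:
            key_of[key] = len(verts)
            verts.append([p[0] / pixel_size, p[1] / pixel_size])
        return key_of[key]

    edges_raw = []
    for poly in polylines_um:
        poly = np.asarray(poly, dtype=float)
        if len(poly) < 2:
            raise ValueError("polyline needs >= 2 points")
        u = vertex_at(poly[0])
        v = vertex_at(poly[-1])
        steps = np.diff(poly, axis=0)
        length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        if length <= 0:
            raise ValueError("degenerate polyline of zero length")
        edges_raw.append((u, v, poly / pixel_size, length))

    degree = [0] * len(verts)
    for u, v, _, _ in edges_raw:
        degree[u] += 1
        degree[v] += 1

    vertices = []
    for i, (y, x) in enumerate(verts):
        if degree[i] == 1:
            kind = "end"
        elif degree[i] >= 3:
            kind = "junction"
        elif degree[i] == 2:
            # either a cycle anchor (self-loop) or a corner; both degree 2
            kind = "anchor"
        else:
            kind = "isolated"
        vertices.append(Vertex(i, y, x, kind))
    edges = [Edge(i, u, v, poly, length) for i, (u, v, poly, length) in enumerate(edges_raw)]
    return LinearNetwork(vertices, edges, pixel_size)


def _comb_tree(total_um: float, n_branches: int) -> list[np.ndarray]:
    """A connected branched 'comb': straight backbone with alternating teeth.

    J = n_branches, E = n_branches + 2, total length exact.
    """
    if n_branches < 1:
        raise ValueError("tree needs >= 1 branch")
    backbone = 0.36 * total_um
    tooth = (total_um - backbone) / n_branches
    xs = np.linspace(backbone / (n_branches + 1), backbone * n_branches / (n_branches + 1), n_branches)
    y0 = max(tooth, 1.0) + 1.0
    polys = []
    # backbone split at tooth attachment points so junctions are endpoints
    knots = np.concatenate([[0.0], xs, [backbone]])
    for a, b in zip(knots[:-1], knots[1:]):
        polys.append(np.array([[y0, a], [y0, b]]))
    for i, x in enumerate(xs):
        sign = 1.0 if i % 2 == 0 else -1.0
        polys.append(np.array([[y0, x], [y0 + sign * tooth, x]]))
    return polys


def make_network(spec: FixtureSpec) -> LinearNetwork:
    """Build the exact network geometry described by the spec."""
    k = spec.network_kind
    if k == "segment":
        L = spec.total_length_um
        if L <= 0:
            raise ValueError("segment length must be positive")
        polys = [np.array([[1.0, 0.0], [1.0, L]])]
    elif k == "cycle":
        r = spec.radius_um
        if r <= 0:
            raise ValueError("cycle radius must be positive")
        th = np.linspace(0, 2 * math.pi, 257)
        polys = [np.stack([r + r * np.sin(th), r + r * np.cos(th)], axis=1)]
    elif k == "chain_of_segments":
        n = spec.n_chains
        if n < 1:
            raise ValueError("need >= 1 chain")
        L = spec.total_length_um / n
        polys = [np.array([[2.0 + 5.0 * i, 0.0], [2.0 + 5.0 * i, L]]) for i in range(n)]
    elif k == "tree":
        polys = _comb_tree(spec.total_length_um, spec.n_branches)
    elif k == "grid":
        gy, gx = spec.grid_shape
        s = spec.grid_spacing_um
        if gy < 2 or gx < 2 or s <= 0:
            raise ValueError("grid needs shape >= 2x2 and positive spacing")
        polys = []
        for i in range(gy):
            for j in range(gx):
                if j + 1 < gx:
                    polys.append(np.array([[i * s + 1, j * s + 1], [i * s + 1, (j + 1) * s + 1]]))
                if i + 1 < gy:
                    polys.append(np.array([[i * s + 1, j * s + 1], [(i + 1) * s + 1, j * s + 1]]))
    elif k == "random_skeleton":
        rng = np.random.default_rng(spec.seed)
        pts = rng.uniform(2.0, spec.box_um, size=(spec.n_nodes, 2))
        # Euclidean minimum spanning tree: connected, no crossings of concern
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(pts))
        mst = minimum_spanning_tree(D).tocoo()
        polys = [np.array([pts[i], pts[j]]) for i, j in zip(mst.row, mst.col)]
    else:
        raise ValueError(f"unknown network kind: {spec.network_kind!r}")
    return network_from_polylines(polys, spec.pixel_size)


# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------

def _walk_from(
    network: LinearNetwork,
    loc: NetworkLocation,
    dist_um: float,
    rng: np.random.Generator,
) -> NetworkLocation:
    """Walk a geodesic distance from loc, choosing uniformly at junctions;
    clamps at dead ends."""
    e = network.edge(loc.edge_id)
    direction = 1 if rng.random() < 0.5 else -1
    pos = loc.offset_um
    remaining = dist_um
    for _ in range(1000):
        if direction > 0:
            room = e.length_um - pos
            if remaining <= room:
                return NetworkLocation(e.id, pos + remaining)
            remaining -= room
            vid = e.v
        else:
            if remaining <= pos:
                return NetworkLocation(e.id, pos - remaining)
            remaining -= pos
            vid = e.u
        options = network.incident_edges(vid)
        if len(options) <= 1:
            end_off = e.length_um if direction > 0 else 0.0
            return NetworkLocation(e.id, end_off)  # dead end: clamp
        eid, end = options[rng.integers(len(options))]
        e = network.edge(eid)
        pos = 0.0 if end == 0 else e.length_um
        direction = 1 if end == 0 else -1
    return NetworkLocation(e.id, pos)


def sample_point_process(
    network: LinearNetwork, spec: FixtureSpec, rng: np.random.Generator
) -> NetworkPointPattern:
    """Sample the spec's point process on the network."""
    total = network.total_length_um
    n = spec.n_points if spec.n_points is not None else int(round(spec.density_per_um * total))
    if spec.point_kind == "irp":
        return simulate_irp(network, n, rng)
    if spec.point_kind == "hardcore":
        delta = spec.hardcore_delta_um
        if delta <= 0:
            raise ValueError("hardcore delta must be positive")
        if n * delta > 0.8 * total:
            raise ValueError("hardcore packing not achievable (n * delta > 0.8 * length)")
        geo = GeodesicStructure(network)
        accepted: list[NetworkLocation] = []
        attempts = 0
        max_attempts = 500 * max(n, 1)
        while len(accepted) < n and attempts < max_attempts:
            attempts += 1
            cand = simulate_irp(network, 1, rng).points[0]
            if all(geo.point_distance(cand, q) >= delta for q in accepted):
                accepted.append(cand)
        if len(accepted) < n:
            raise RuntimeError("hardcore sampling failed to place all points")
        return NetworkPointPattern(network, accepted)
    if spec.point_kind == "cluster":
        parents = simulate_irp(network, spec.cluster_parents, rng).points
        pts: list[NetworkLocation] = []
        target = n if spec.n_points is not None else spec.cluster_parents * spec.cluster_offspring
        for i in range(target):
            parent = parents[rng.integers(len(parents))]
            u = rng.uniform(0.0, spec.cluster_radius_um)
            pts.append(_walk_from(network, parent, u, rng))
        return NetworkPointPattern(network, pts)
    raise ValueError(f"unknown point process: {spec.point_kind!r}")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def location_to_xy(network: LinearNetwork, loc: NetworkLocation) -> tuple[float, float]:
    """(y, x) pixel coordinates of an on-network location."""
    e = network.edge(loc.edge_id)
    poly = e.polyline
    steps = np.diff(poly, axis=0)
    seglen = np.hypot(steps[:, 0], steps[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    target = np.clip(loc.offset_um / network.pixel_size, 0.0, cum[-1])
    k = int(np.searchsorted(cum, target, side="right")) - 1
    k = min(k, len(seglen) - 1)
    frac = (target - cum[k]) / seglen[k] if seglen[k] > 0 else 0.0
    p = poly[k] + frac * steps[k]
    return float(p[0]), float(p[1])


@dataclass
class RasterizedFixture:
    """A rasterized fixture with its ground truth."""

    images: ImageSet
    network: LinearNetwork
    pattern: NetworkPointPattern
    spot_px: np.ndarray  # (n, 2) ground-truth (y, x) of planted spots


def _shift_network(network: LinearNetwork, dy: float, dx: float) -> LinearNetwork:
    vertices = [Vertex(v.id, v.y + dy, v.x + dx, v.kind) for v in network.vertices]
    edges = [
        Edge(e.id, e.u, e.v, e.polyline + np.array([dy, dx]), e.length_um)
        for e in network.edges
    ]
    return LinearNetwork(vertices, edges, network.pixel_size)


def rasterize(
    network: LinearNetwork, pattern: NetworkPointPattern, spec: FixtureSpec
) -> RasterizedFixture:
    """Paint a network + point pattern into a two-channel image.

    The mitochondrial channel draws each edge polyline, dilates it to the
    tube width, blurs lightly and (optionally) adds Poisson noise; the DNA
    channel places a Gaussian spot of ``spot_sigma_px`` at each point.
    Signal amplitude is ``snr**2`` so that the Poisson SNR at peak is about
    ``snr``. The returned network/pattern are shifted into the image frame.
    """
    from skimage.draw import line as draw_line
    from skimage.morphology import dilation, disk
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed + 7)
    all_pts = np.concatenate([e.polyline for e in network.edges])
    lo = all_pts.min(axis=0)
    hi = all_pts.max(axis=0)
    m = spec.margin_px
    shift = m - lo
    H = int(math.ceil(hi[0] - lo[0])) + 2 * m + 1
    W = int(math.ceil(hi[1] - lo[1])) + 2 * m + 1
    net = _shift_network(network, shift[0], shift[1])
    pat = NetworkPointPattern(net, list(pattern.points))

    skel = np.zeros((H, W), dtype=bool)
    for e in net.edges:
        pts = np.round(e.polyline).astype(int)
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            skel[rr, cc] = True
    tube = dilation(skel, disk(max(1, spec.tube_width_px // 2)))
    amp = spec.snr**2
    mito = gaussian_filter(tube.astype(float), 1.0) * amp

    nucl = np.zeros((H, W), dtype=float)
    yy, xx = np.mgrid[0:H, 0:W]
    spot_px = []
    s = spec.spot_sigma_px
    for p in pat.points:
        y0, x0 = location_to_xy(net, p)
        spot_px.append((y0, x0))
        win = int(math.ceil(4 * s))
        ylo, yhi = max(0, int(y0) - win), min(H, int(y0) + win + 1)
        xlo, xhi = max(0, int(x0) - win), min(W, int(x0) + win + 1)
        sub_y = yy[ylo:yhi, xlo:xhi]
        sub_x = xx[ylo:yhi, xlo:xhi]
        nucl[ylo:yhi, xlo:xhi] += amp * np.exp(
            -((sub_y - y0) ** 2 + (sub_x - x0) ** 2) / (2 * s**2)
        )
    if spec.noise:
        mito = rng.poisson(mito + spec.background).astype(float)
        nucl = rng.poisson(nucl + spec.background).astype(float)
    images = ImageSet(mito_channel=mito, nucleoid_channel=nucl, pixel_size=spec.pixel_size)
    return RasterizedFixture(
        images=images,
        network=net,
        pattern=pat,
        spot_px=np.asarray(spot_px).reshape(-1, 2),
    )
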