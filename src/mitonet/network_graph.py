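"""Skeleton-graph extraction and measurement of mitochondrial linear networks.

A segmented mitochondrial mask is reduced to a one-pixel medial skeleton and
converted to a :class:`LinearNetwork`: a measured multigraph whose vertices
are tubule ends (degree 1) and junctions (degree >= 3) and whose edges carry
the pixel polyline and physical arclength of the tubule connecting them.
Connected components of the graph are "clusters" -- the individual
mitochondria of the cell -- and all nucleoid statistics downstream are
computed within clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_pipeline import BinaryMask

__all__ = [
    "Vertex",
    "Edge",
    "Cluster",
    "LinearNetwork",
    "NetworkMetrics",
    "skeletonize",
    "build_network",
    "connectivity",
    "clusters",
    "length_metrics",
    "SHORT_MITO_CUTOFF_UM",
]

#: clusters shorter than this (in um) count as "short mitochondria"
SHORT_MITO_CUTOFF_UM = 2.0

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class Vertex:
    """A network vertex at pixel coordinates (y, x).

    kind is "end" (degree 1), "junction" (degree >= 3), "anchor" (the
    degree-2 anchor placed on an isolated cycle) or "isolated" (a lone
    skeleton pixel with no edges).
    """

    id: int
    y: float
    x: float
    kind: str


@dataclass(frozen=True)
class Edge:
    """A tubule between two vertices.

    polyline is an (N, 2) float array of (y, x) pixel coordinates running
    from vertex u to vertex v; length_um is its arclength times the pixel
    size. Self-loops (u == v) represent isolated cycles.
    """

    id: int
    u: int
    v: int
    polyline: np.ndarray
    length_um: float


@dataclass(frozen=True)
class Cluster:
    """One connected component G_k of the network."""

    id: int
    vertex_ids: tuple[int, ...]
    edge_ids: tuple[int, ...]
    length_um: float


def _polyline_arclength_px(polyline: np.ndarray) -> float:
    if len(polyline) < 2:
        return 0.0
    steps = np.diff(np.asarray(polyline, dtype=float), axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


class LinearNetwork:
    """Measured linear-network graph of the mitochondrial skeleton.

    Parameters
    ----------
    vertices, edges:
        The graph elements; edge polylines are in pixel coordinates and
        lengths in micrometres.
    pixel_size:
        Micrometres per pixel (> 0).

    Clusters (connected components) are computed on construction and given
    deterministic ids: sorted by decreasing total length, ties broken by the
    smallest (y, x) vertex coordinate in the component.
    """

    def __init__(self, vertices: list[Vertex], edges: list[Edge], pixel_size: float):
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for e in edges:
            if e.length_um <= 0:
                raise ValueError(f"edge {e.id} has non-positive length")
        self.vertices = list(vertices)
        self.edges = list(edges)
        self.pixel_size = float(pixel_size)
        self._vertex_by_id = {v.id: v for v in self.vertices}
        self._edge_by_id = {e.id: e for e in self.edges}
        self.clusters = self._compute_clusters()
        self.cluster_of_edge = {
            eid: c.id for c in self.clusters for eid in c.edge_ids
        }
        self.cluster_of_vertex = {
            vid: c.id for c in self.clusters for vid in c.vertex_ids
        }

    # -- basic accessors ---------------------------------------------------
    def vertex(self, vid: int) -> Vertex:
        return self._vertex_by_id[vid]

    def edge(self, eid: int) -> Edge:
        return self._edge_by_id[eid]

    @property
    def total_length_um(self) -> float:
        return sum(e.length_um for e in self.edges)

    def degree(self, vid: int) -> int:
        """Graph degree; a self-loop contributes 2."""
        d = 0
        for e in self.edges:
            d += (e.u == vid) + (e.v == vid)
        return d

    def incident_edges(self, vid: int) -> list[tuple[int, int]]:
        """(edge_id, end) pairs at a vertex; end 0 means the u-side."""
        out = []
        for e in self.edges:
            if e.u == vid:
                out.append((e.id, 0))
            if e.v == vid:
                out.append((e.id, 1))
        return out

    def _compute_clusters(self) -> list[Cluster]:
        parent = {v.id: v.id for v in self.vertices}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for e in self.edges:
            union(e.u, e.v)
        groups: dict[int, list[int]] = {}
        for v in self.vertices:
            groups.setdefault(find(v.id), []).append(v.id)
        comps = []
        for vids in groups.values():
            vset = set(vids)
            eids = [e.id for e in self.edges if e.u in vset]
            length = sum(self._edge_by_id[i].length_um for i in eids)
            coord = min((self._vertex_by_id[i].y, self._vertex_by_id[i].x) for i in vids)
            comps.append((length, coord, tuple(sorted(vids)), tuple(sorted(eids))))
        comps.sort(key=lambda c: (-c[0], c[1]))
        return [
            Cluster(id=i, vertex_ids=vids, edge_ids=eids, length_um=length)
            for i, (length, _coord, vids, eids) in enumerate(comps)
        ]


@dataclass
class NetworkMetrics:
    """Per-cell summary of network architecture.

    connectivity = J/E is NaN when the network has no ends (pure cycles);
    inv_short = 1 / (number of clusters shorter than 2 um) is NaN when no
    cluster is that short.
    """

    total_length_um: float
    n_junctions: int
    n_ends: int
    connectivity: float
    n_clusters: int
    n_short_mito: int
    inv_short: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def skeletonize(mask: BinaryMask | np.ndarray) -> BinaryMask:
    """Reduce a binary mask to a one-pixel-wide, topology-preserving skeleton."""
    from skimage.morphology import skeletonize as _sk

    if isinstance(mask, BinaryMask):
        grid, ps = mask.grid, mask.pixel_size
    else:
        grid, ps = np.asarray(mask, dtype=bool), 1.0
    if grid.ndim != 2:
        raise ValueError("mask must be 2-D")
    return BinaryMask(_sk(grid), ps)


def _neighbor_degrees(grid: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    nb = ndimage.convolve(grid.astype(np.uint8), kernel, mode="constant", cval=0)
    return nb * grid


def build_network(skeleton: BinaryMask | np.ndarray, pixel_size: float | None = None) -> LinearNetwork:
    """Convert a 1-px skeleton raster to a measured :class:`LinearNetwork`.

    Pixels with one 8-neighbour become end vertices; 8-connected blobs of
    pixels with >= 3 neighbours collapse to a single junction vertex at
    their centroid. Maximal paths of degree-2 pixels between vertices become
    edges, with arclength counting 1 px per axial step and sqrt(2) px per
    diagonal step. Isolated cycles receive one degree-2 anchor vertex.
    """
    if isinstance(skeleton, BinaryMask):
        grid = skeleton.grid
        if pixel_size is None:
            pixel_size = skeleton.pixel_size
    else:
        grid = np.asarray(skeleton, dtype=bool)
        if pixel_size is None:
            pixel_size = 1.0
    if grid.ndim != 2:
        raise ValueError("skeleton must be 2-D")
    if np.any(grid[:-1, :-1] & grid[1:, :-1] & grid[:-1, 1:] & grid[1:, 1:]):
        raise ValueError("input is not a 1-px skeleton (contains a solid 2x2 block)")

    deg = _neighbor_degrees(grid)
    junction_pixels = deg >= 3
    jlab, njunc = ndimage.label(junction_pixels, structure=np.ones((3, 3)))

    vertices: list[Vertex] = []
    vertex_of_pixel: dict[tuple[int, int], int] = {}
    for j in range(1, njunc + 1):
        ys, xs = np.nonzero(jlab == j)
        vid = len(vertices)
        vertices.append(Vertex(vid, float(ys.mean()), float(xs.mean()), "junction"))
        for y, x in zip(ys, xs):
            vertex_of_pixel[(int(y), int(x))] = vid
    for y, x in zip(*np.nonzero((deg == 1) & grid)):
        vid = len(vertices)
        vertices.append(Vertex(vid, float(y), float(x), "end"))
        vertex_of_pixel[(int(y), int(x))] = vid
    for y, x in zip(*np.nonzero((deg == 0) & grid)):
        vertices.append(Vertex(len(vertices), float(y), float(x), "isolated"))

    H, W = grid.shape

    def neighbors(p):
        y, x = p
        for dy, dx in _NEIGH8:
            q = (y + dy, x + dx)
            if 0 <= q[0] < H and 0 <= q[1] < W and grid[q]:
                yield q

    edges: list[Edge] = []
    consumed: set[tuple[int, int]] = set()
    direct_seen: set[frozenset] = set()

    def add_edge(u, v, poly_pixels):
        poly = np.asarray(poly_pixels, dtype=float)
        length = _polyline_arclength_px(poly) * pixel_size
        edges.append(Edge(len(edges), u, v, poly, length))

    vertex_pixels = sorted(vertex_of_pixel)
    for p in vertex_pixels:
        u = vertex_of_pixel[p]
        for q in neighbors(p):
            if q in vertex_of_pixel:
                v = vertex_of_pixel[q]
                if v == u:
                    continue  # internal pair of one junction blob
                key = frozenset((p, q))
                if key not in direct_seen:
                    direct_seen.add(key)
                    add_edge(u, v, [p, q])
                continue
            if q in consumed:
                continue
            # walk along degree-2 pixels until the next vertex pixel
            poly = [p, q]
            consumed.add(q)
            prev, cur = p, q
            while cur not in vertex_of_pixel:
                nxt = [r for r in neighbors(cur) if r != prev and r not in consumed]
                nxt = [r for r in nxt if r in vertex_of_pixel or deg[r] == 2]
                if not nxt:
                    break
                # prefer vertex pixels so walks terminate at junction blobs
                nxt.sort(key=lambda r: (r not in vertex_of_pixel, r))
                cur, prev = nxt[0], cur
                poly.append(cur)
                if cur not in vertex_of_pixel:
                    consumed.add(cur)
            if poly[-1] in vertex_of_pixel:
                add_edge(u, vertex_of_pixel[poly[-1]], poly)
            else:
                # dead-ended into consumed pixels: dangling stub, keep as end
                vid = len(vertices)
                vertices.append(Vertex(vid, float(poly[-1][0]), float(poly[-1][1]), "end"))
                vertex_of_pixel[poly[-1]] = vid
                add_edge(u, vid, poly)

    # isolated cycles: remaining unconsumed degree-2 pixels
    remaining = (deg == 2) & grid
    for p in consumed:
        remaining[p] = False
    for p in vertex_pixels:
        remaining[p] = False
    rlab, nrem = ndimage.label(remaining, structure=np.ones((3, 3)))
    for c in range(1, nrem + 1):
        ys, xs = np.nonzero(rlab == c)
        pix = sorted(zip(ys.tolist(), xs.tolist()))
        anchor = pix[0]
        vid = len(vertices)
        vertices.append(Vertex(vid, float(anchor[0]), float(anchor[1]), "anchor"))
        poly = [anchor]
        consumed.add(anchor)
        prev, cur = anchor, None
        nbrs = [q for q in neighbors(anchor) if rlab[q] == c]
        if nbrs:
            cur = nbrs[0]
            while cur is not None and cur != anchor:
                poly.append(cur)
                consumed.add(cur)
                nxt = [q for q in neighbors(cur) if q != prev and rlab[q] == c and (q == anchor or q not in consumed)]
                if not nxt:
                    cur = None
                    break
                prev, cur = cur, nxt[0]
            poly.append(anchor)
            add_edge(vid, vid, poly)

    return LinearNetwork(vertices, edges, pixel_size)


def connectivity(network: LinearNetwork) -> float:
    """Network connectivity J/E: junction count over end count.

    Returns NaN when the network has no end vertices (pure cycles), where
    the ratio is undefined.
    """
    J = sum(1 for v in network.vertices if v.kind == "junction")
    E = sum(1 for v in network.vertices if v.kind == "end")
    if E == 0:
        return math.nan
    return J / E


def clusters(network: LinearNetwork) -> list[tuple[int, float]]:
    """(cluster id, length um) pairs in the network's deterministic order."""
    return [(c.id, c.length_um) for c in network.clusters]


def length_metrics(network: LinearNetwork) -> NetworkMetrics:
    J = sum(1 for v in network.vertices if v.kind == "junction")
    E = sum(1 for v in network.vertices if v.kind == "end")
    lengths = [c.length_um for c in network.clusters]
    n_short = sum(1 for l in lengths if l < SHORT_MITO_CUTOFF_UM)
    return NetworkMetrics(
        total_length_um=network.total_length_um,
        n_junctions=J,
        n_ends=E,
        connectivity=(J / E) if E else math.nan,
        n_clusters=len(lengths),
        n_short_mito=n_short,
        inv_short=(1.0 / n_short) if n_short else math.nan,
    )
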