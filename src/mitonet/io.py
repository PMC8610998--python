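"""Exchange formats: GraphML networks, CSV point patterns / curves / tables.

GraphML + points CSV are the round-trip formats connecting the image stages
to the statistics stages, so pre-built networks and patterns can be analysed
without any image input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network_graph import Edge, LinearNetwork, Vertex
from .network_distances import NetworkLocation
from .linear_pcf import NetworkPointPattern, PcfCurve

__all__ = [
    "write_graphml",
    "read_graphml",
    "write_edge_csv",
    "write_points_csv",
    "read_points_csv",
    "write_curve_csv",
    "nucleoid_table",
]


def _poly_to_str(poly: np.ndarray) -> str:
    return ";".join(f"{y:.6g}:{x:.6g}" for y, x in poly)


def _poly_from_str(s: str) -> np.ndarray:
    pts = [tuple(map(float, p.split(":"))) for p in s.split(";")]
    return np.asarray(pts, dtype=float)


def write_graphml(network: LinearNetwork, path: str | Path) -> None:
    import networkx as nx

    g = nx.MultiGraph(pixel_size=network.pixel_size)
    for v in network.vertices:
        g.add_node(v.id, y=v.y, x=v.x, kind=v.kind)
    for e in network.edges:
        g.add_edge(
            e.u,
            e.v,
            key=e.id,
            edge_id=e.id,
            length_um=e.length_um,
            polyline=_poly_to_str(e.polyline),
        )
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> LinearNetwork:
    import networkx as nx

    g = nx.read_graphml(path, node_type=int, force_multigraph=True)
    pixel_size = float(g.graph["pixel_size"])
    vertices = [
        Vertex(int(n), float(d["y"]), float(d["x"]), str(d["kind"]))
        for n, d in sorted(g.nodes(data=True))
    ]
    edges = []
    for u, v, d in g.edges(data=True):
        edges.append(
            Edge(
                int(d["edge_id"]),
                int(u),
                int(v),
                _poly_from_str(d["polyline"]),
                float(d["length_um"]),
            )
        )
    edges.sort(key=lambda e: e.id)
    return LinearNetwork(vertices, edges, pixel_size)


def write_edge_csv(network: LinearNetwork, path: str | Path) -> None:
    rows = [
        {
            "edge_id": e.id,
            "u": e.u,
            "v": e.v,
            "length_um": e.length_um,
            "cluster_id": network.cluster_of_edge[e.id],
        }
        for e in network.edges
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_points_csv(pattern: NetworkPointPattern, path: str | Path) -> None:
    rows = [
        {
            "cluster_id": pattern.cluster_of_point(i),
            "edge_id": p.edge_id,
            "offset_um": p.offset_um,
        }
        for i, p in enumerate(pattern.points)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "edge_id", "offset_um"]).to_csv(path, index=False)


def read_points_csv(network: LinearNetwork, path: str | Path) -> NetworkPointPattern:
    df = pd.read_csv(path)
    pts = [
        NetworkLocation(int(r.edge_id), float(r.offset_um)) for r in df.itertuples()
    ]
    return NetworkPointPattern(network, pts)


def write_curve_csv(curve: PcfCurve, path: str | Path) -> None:
    """Ratio curves export numerator/denominator too."""
    df = pd.DataFrame({"r_um": curve.r})
    if curve.variant == "ratio":
        df["g_actual"] = curve.g_actual
        df["g_irp_mean"] = curve.g_irp_mean
        df["g_ratio"] = curve.g
    else:
        df["g_actual"] = curve.g
    df["flag_below_resolution"] = curve.below_resolution.astype(int)
    df.to_csv(path, index=False)


def plot_curve(curve: PcfCurve, path: str | Path, r_max_um: float | None = None) -> None:
    """Static figure of a pcf curve (ratio curves show the random baseline)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    sel = np.ones_like(curve.r, dtype=bool) if r_max_um is None else curve.r <= r_max_um
    ax.plot(curve.r[sel], curve.g[sel], lw=1.2, color="crimson", label=curve.variant)
    if curve.variant == "ratio":
        ax.axhline(1.0, ls="--", color="k", lw=0.8, label="random (IRP)")
    ax.axvspan(0, curve.resolution_floor_um, color="0.85", label="below resolution")
    ax.set_xlabel("geodesic distance r (µm)")
    ax.set_ylabel("pcf")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def nucleoid_table(records) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        rows.append(
            {
                "nucleoid_id": i,
                "x_px": rec.spot.x,
                "y_px": rec.spot.y,
                "quality": rec.spot.quality,
                "cluster_id": rec.cluster_id if rec.cluster_id is not None else -1,
                "edge_id": rec.location.edge_id if rec.location else -1,
                "offset_um": rec.location.offset_um if rec.location else np.nan,
                "dist_to_network_px": rec.distance_px,
                "area_um2": rec.area_um2,
                "equivalent_diameter_um": rec.equivalent_diameter_um,
                "region": rec.region,
            }
        )
    cols = [
        "nucleoid_id", "x_px", "y_px", "quality", "cluster_id", "edge_id",
        "offset_um", "dist_to_network_px", "area_um2", "equivalent_diameter_um", "region",
    ]
    return pd.DataFrame(rows, columns=cols)
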