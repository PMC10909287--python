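"""Road-network preparation and closest-facility routing.

The pipeline mirrors how national road databases are turned into a
routable graph: polyline segments are split wherever an interior vertex
coincides exactly with a vertex of another segment (connectivity in such
databases is encoded by shared vertices — geometric crossing would
falsely connect bridges and overpasses), walking roads (speed limit
below 10 km/h) are removed, and each remaining segment becomes one
undirected edge weighted by its travel time in minutes
(``length_m / (speed_kmh * 1000 / 60)``).

Grid-cell centroids within ``max_dist_m`` (default 5000 m) of a graph
node are snapped to their Euclidean-nearest node; the rest are flagged
unreachable and excluded downstream.  Closest-facility routing assigns
every reachable cell the minimum shortest-path travel time over all EDs,
with ties broken toward the lowest ED id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RoadSegment",
    "split_segments_at_intersections",
    "filter_walking_roads",
    "build_graph",
    "snap_cells",
    "closest_facility",
]

WALKING_LIMIT_KMH = 10.0  # strictly below => walking road, removed


@dataclass(frozen=True)
class RoadSegment:
    """A polyline road segment in projected planar metres."""

    id: str
    coords: list[tuple[float, float]]
    speed_kmh: float

    @property
    def length_m(self) -> float:
        return sum(
            math.dist(a, b) for a, b in zip(self.coords[:-1], self.coords[1:])
        )

    def validate(self) -> None:
        if len(self.coords) < 2:
            raise ValueError(f"segment {self.id}: needs >= 2 coordinates")
        if self.speed_kmh <= 0:
            raise ValueError(f"segment {self.id}: speed_kmh must be > 0")
        if self.length_m <= 0:
            raise ValueError(f"segment {self.id}: zero length")


def split_segments_at_intersections(
    segments: list[RoadSegment],
) -> list[RoadSegment]:
    """Split segments at interior vertices shared with other segments.

    A split point is any coordinate interior to one segment that
    coincides exactly with an endpoint *or* vertex of a different
    segment.  Children inherit the parent's speed; total length is
    conserved.  Zero-length pieces (consecutive duplicate coordinates)
    are dropped with a warning.
    """
    owners: dict[tuple[float, float], set[str]] = {}
    for seg in segments:
        for c in seg.coords:
            owners.setdefault(tuple(c), set()).add(seg.id)

    out: list[RoadSegment] = []
    for seg in segments:
        cut = [0]
        for k in range(1, len(seg.coords) - 1):
            if owners.get(tuple(seg.coords[k]), set()) - {seg.id}:
                cut.append(k)
        cut.append(len(seg.coords) - 1)
        pieces = [seg.coords[a : b + 1] for a, b in zip(cut[:-1], cut[1:])]
        many = len(pieces) > 1
        kept = 0
        for p, coords in enumerate(pieces):
            piece = RoadSegment(
                id=f"{seg.id}#{p}" if many else seg.id,
                coords=list(coords),
                speed_kmh=seg.speed_kmh,
            )
            if piece.length_m <= 0:
                logger.warning("dropping zero-length piece of segment %s", seg.id)
                continue
            out.append(piece)
            kept += 1
        if kept == 0:
            logger.warning("segment %s vanished entirely after splitting", seg.id)
    return out


def filter_walking_roads(segments: list[RoadSegment]) -> list[RoadSegment]:
    """Remove walking roads: speed limits strictly below 10 km/h."""
    return [s for s in segments if s.speed_kmh >= WALKING_LIMIT_KMH]


def build_graph(segments: list[RoadSegment]) -> nx.Graph:
    """Undirected travel-time graph from split, filtered segments.

    Nodes are unique segment endpoints, numbered in lexicographic
    coordinate order (so node ids are deterministic).  Each segment
    contributes one edge with ``travel_time_min`` and ``length_m``;
    parallel edges collapse to the minimum travel time.
    """
    for s in segments:
        s.validate()
    endpoints = sorted(
        {tuple(s.coords[0]) for s in segments} | {tuple(s.coords[-1]) for s in segments}
    )
    node_of = {c: k for k, c in enumerate(endpoints)}
    G = nx.Graph()
    for c, k in node_of.items():
        G.add_node(k, x=c[0], y=c[1])
    for s in segments:
        u, v = node_of[tuple(s.coords[0])], node_of[tuple(s.coords[-1])]
        if u == v:
            continue  # degenerate loop: no routing value
        tt = s.length_m / (s.speed_kmh * 1000.0 / 60.0)
        if G.has_edge(u, v) and G[u][v]["travel_time_min"] <= tt:
            continue
        G.add_edge(u, v, travel_time_min=tt, length_m=s.length_m)
    return G


def _node_coords(G: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.array(sorted(G.nodes))
    xy = np.array([[G.nodes[n]["x"], G.nodes[n]["y"]] for n in nodes], dtype=float)
    return nodes, xy


def _snap_point(
    x: float, y: float, nodes: np.ndarray, xy: np.ndarray
) -> tuple[int, float]:
    d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
    dmin = d.min()
    # equidistant nodes: lowest node id wins
    return int(nodes[d <= dmin + 1e-9].min()), float(dmin)


def snap_cells(
    cells: pd.DataFrame, G: nx.Graph, max_dist_m: float = 5000.0
) -> pd.DataFrame:
    """Snap cell centroids to the nearest graph node.

    ``cells`` needs ``cell_id, x0, y0, size_m`` (centroid is the cell
    centre).  Cells whose nearest node is farther than ``max_dist_m``
    are marked unreachable, mirroring the omission of off-network cells
    from the analysis.  Returns ``cell_id, snapped_node,
    snap_distance_m, reachable``.
    """
    if G.number_of_nodes() == 0:
        logger.warning("empty road graph: all %d cells unreachable", len(cells))
        return pd.DataFrame(
            {
                "cell_id": cells["cell_id"],
                "snapped_node": -1,
                "snap_distance_m": np.inf,
                "reachable": False,
            }
        )
    nodes, xy = _node_coords(G)
    rows = []
    for cell_id, x0, y0, size in cells[["cell_id", "x0", "y0", "size_m"]].itertuples(
        index=False
    ):
        node, dist = _snap_point(x0 + size / 2.0, y0 + size / 2.0, nodes, xy)
        rows.append((cell_id, node, dist, dist <= max_dist_m))
    out = pd.DataFrame(
        rows, columns=["cell_id", "snapped_node", "snap_distance_m", "reachable"]
    )
    n_un = int((~out["reachable"]).sum())
    if n_un:
        logger.info(
            "%d of %d cells (%.1f%%) beyond %.0f m of the network: omitted",
            n_un,
            len(out),
            100.0 * n_un / len(out),
            max_dist_m,
        )
    return out


def closest_facility(
    G: nx.Graph,
    eds: pd.DataFrame,
    assignments: pd.DataFrame,
    max_dist_m: float = 5000.0,
) -> pd.DataFrame:
    """Travel time and identity of the closest ED for every cell.

    EDs (``ed_id, x, y``) are snapped with the same nearest-node rule as
    the cells.  For each reachable cell the travel time is the minimum
    over EDs of the shortest-path time from the cell's node to the ED's
    node (one Dijkstra per ED); ties go to the lowest ``ed_id``.  Cells
    in components containing no ED become unreachable.
    """
    if len(eds) == 0:
        raise ValueError("no EDs supplied")
    nodes, xy = _node_coords(G)
    ed_nodes: dict[str, int] = {}
    for ed_id, x, y in eds[["ed_id", "x", "y"]].itertuples(index=False):
        node, dist = _snap_point(x, y, nodes, xy)
        if dist > max_dist_m:
            logger.warning("ED %s is %.0f m from the network", ed_id, dist)
        ed_nodes[str(ed_id)] = node

    times_per_ed = {
        ed_id: nx.single_source_dijkstra_path_length(
            G, node, weight="travel_time_min"
        )
        for ed_id, node in sorted(ed_nodes.items())
    }

    out = assignments.copy()
    tt, ed_col, reach = [], [], []
    for node, reachable in out[["snapped_node", "reachable"]].itertuples(index=False):
        best_t, best_ed = math.inf, None
        if reachable:
            for ed_id in sorted(times_per_ed):  # ascending id => tie-break
                t = times_per_ed[ed_id].get(node)
                if t is not None and t < best_t - 1e-12:
                    best_t, best_ed = t, ed_id
        ok = best_ed is not None
        tt.append(best_t if ok else math.nan)
        ed_col.append(best_ed)
        reach.append(ok)
    out["travel_time_min"] = tt
    out["ed_id"] = ed_col
    out["reachable"] = reach
    return out
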