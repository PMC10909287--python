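"""Road preparation and closest-facility routing, incl. brute-force oracle."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dynaccess import synthetic
from dynaccess.config import ScenarioConfig
from dynaccess.roads import (
    RoadSegment,
    build_graph,
    closest_facility,
    filter_walking_roads,
    snap_cells,
    split_segments_at_intersections,
)


def seg(sid, coords, speed=50.0):
    return RoadSegment(id=sid, coords=[tuple(map(float, c)) for c in coords], speed_kmh=speed)


# ---------------------------------------------------------------------------
# splitting


class TestSplitting:
    def test_segments_sharing_only_endpoints_unchanged(self):
        segs = [seg("a", [(0, 0), (1, 0)]), seg("b", [(1, 0), (2, 0)])]
        assert split_segments_at_intersections(segs) == segs

    def test_interior_vertex_meeting_endpoint_splits(self):
        segs = [seg("abc", [(0, 0), (1, 0), (2, 0)]), seg("bd", [(1, 0), (1, 1)])]
        out = split_segments_at_intersections(segs)
        assert len(out) == 3
        lengths = sorted(round(s.length_m, 9) for s in out)
        assert lengths == [1.0, 1.0, 1.0]
        assert {s.speed_kmh for s in out} == {50.0}

    def test_length_conserved_on_lattice(self):
        cfg = ScenarioConfig(grid_extent=6, seed=5, walking_fraction=0.0)
        segs = synthetic.generate_road_network(cfg)
        out = split_segments_at_intersections(segs)
        assert len(out) >= len(segs)
        assert sum(s.length_m for s in out) == pytest.approx(
            sum(s.length_m for s in segs), abs=1e-9
        )

    def test_zero_length_piece_dropped(self, caplog):
        segs = [seg("dup", [(0, 0), (1, 0), (1, 0)]), seg("x", [(1, 0), (2, 0)])]
        with caplog.at_level("WARNING"):
            out = split_segments_at_intersections(segs)
        assert all(s.length_m > 0 for s in out)


class TestWalkingFilter:
    @pytest.mark.parametrize(
        "speed,kept", [(5.0, False), (9.99, False), (10.0, True), (110.0, True)]
    )
    def test_strict_below_ten_removed(self, speed, kept):
        out = filter_walking_roads([seg("s", [(0, 0), (1, 0)], speed)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert filter_walking_roads([]) == []


class TestBuildGraph:
    @pytest.mark.parametrize(
        "length,speed,expected",
        [(1000.0, 60.0, 1.0), (1500.0, 90.0, 1.0), (2000.0, 60.0, 2.0)],
    )
    def test_travel_time_minutes(self, length, speed, expected):
        G = build_graph([seg("s", [(0, 0), (length, 0)], speed)])
        (u, v, data), = G.edges(data=True)
        assert data["travel_time_min"] == pytest.approx(expected)

    def test_parallel_edges_keep_fastest(self):
        segs = [
            seg("slow", [(0, 0), (1000, 0)], 30.0),
            seg("fast", [(0, 0), (1000, 0)], 60.0),
        ]
        G = build_graph(segs)
        assert G.number_of_edges() == 1
        (_, _, data), = G.edges(data=True)
        assert data["travel_time_min"] == pytest.approx(1.0)


class TestSnapping:
    def test_coincident_centroid(self, path_graph, path_cells):
        out = snap_cells(path_cells, path_graph)
        assert out["snapped_node"].tolist() == [0, 1, 2, 3, 4]
        assert (out["snap_distance_m"] == 0).all()
        assert out["reachable"].all()

    def test_beyond_threshold_unreachable(self, path_graph):
        cells = pd.DataFrame(
            {"cell_id": ["far"], "x0": [0.0], "y0": [9950.0], "size_m": [100.0]}
        )
        out = snap_cells(cells, path_graph, max_dist_m=5000.0)
        assert not out["reachable"].iloc[0]

    def test_equidistant_tie_takes_lower_node_id(self, path_graph):
        # midway between nodes 1 and 2
        cells = pd.DataFrame(
            {"cell_id": ["mid"], "x0": [1450.0], "y0": [-50.0], "size_m": [100.0]}
        )
        out = snap_cells(cells, path_graph)
        assert out["snapped_node"].iloc[0] == 1

    def test_empty_graph_warns_all_unreachable(self, path_cells, caplog):
        with caplog.at_level("WARNING"):
            out = snap_cells(path_cells, nx.Graph())
        assert not out["reachable"].any()


# ---------------------------------------------------------------------------
# closest facility


def eds_at_nodes(G, nodes, level=2):
    return pd.DataFrame(
        {
            "ed_id": [f"e{k:02d}" for k in range(len(nodes))],
            "x": [G.nodes[n]["x"] for n in nodes],
            "y": [G.nodes[n]["y"] for n in nodes],
            "level": level,
        }
    )


def assignments_at_nodes(G):
    nodes = sorted(G.nodes)
    return pd.DataFrame(
        {
            "cell_id": [f"c{n}" for n in nodes],
            "snapped_node": nodes,
            "snap_distance_m": 0.0,
            "reachable": True,
        }
    )


def brute_force_times(G, sources, origin):
    """Minimum travel time from origin to any source, over all simple paths."""
    best = math.inf
    for target in sources:
        if origin == target:
            return 0.0
        stack = [(origin, {origin}, 0.0)]
        while stack:
            node, seen, t = stack.pop()
            for nb in G.neighbors(node):
                if nb in seen:
                    continue
                t2 = t + G[node][nb]["travel_time_min"]
                if nb == target:
                    best = min(best, t2)
                else:
                    stack.append((nb, seen | {nb}, t2))
    return best


class TestClosestFacility:
    def test_cell_on_ed_node(self, path_graph):
        out = closest_facility(
            path_graph, eds_at_nodes(path_graph, [2]), assignments_at_nodes(path_graph)
        )
        row = out[out["snapped_node"] == 2].iloc[0]
        assert row["travel_time_min"] == 0.0
        assert row["ed_id"] == "e00"

    def test_symmetric_tie_goes_to_lower_ed_id(self, path_graph):
        out = closest_facility(
            path_graph, eds_at_nodes(path_graph, [0, 4]), assignments_at_nodes(path_graph)
        )
        mid = out[out["snapped_node"] == 2].iloc[0]
        assert mid["travel_time_min"] == pytest.approx(2.0)
        assert mid["ed_id"] == "e00"

    def test_no_eds_is_an_error(self, path_graph):
        with pytest.raises(ValueError, match="no EDs"):
            closest_facility(
                path_graph, pd.DataFrame(columns=["ed_id", "x", "y", "level"]),
                assignments_at_nodes(path_graph),
            )

    def test_component_without_ed_unreachable(self, path_graph):
        G = path_graph.copy()
        G.add_node(9, x=99000.0, y=0.0)
        G.add_node(10, x=100000.0, y=0.0)
        G.add_edge(9, 10, travel_time_min=1.0, length_m=1000.0)
        assignments = assignments_at_nodes(G)
        out = closest_facility(G, eds_at_nodes(G, [0]), assignments)
        island = out[out["snapped_node"].isin([9, 10])]
        assert not island["reachable"].any()
        assert island["ed_id"].isna().all()

    def test_matches_brute_force_on_random_graph(self):
        rng = np.random.default_rng(3)
        G = random_graph(rng, 8)
        eds = eds_at_nodes(G, [1, 6])
        out = closest_facility(G, eds, assignments_at_nodes(G))
        for row in out.itertuples(index=False):
            expected = brute_force_times(G, [1, 6], row.snapped_node)
            if math.isinf(expected):
                assert not row.reachable
            else:
                assert row.travel_time_min == pytest.approx(expected, abs=1e-9)


def random_graph(rng, n, p=0.35):
    G = nx.Graph()
    pts = rng.uniform(0, 10000, size=(n, 2))
    for k in range(n):
        G.add_node(k, x=float(pts[k, 0]), y=float(pts[k, 1]))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p:
            G.add_edge(
                u,
                v,
                travel_time_min=float(rng.uniform(0.5, 10.0)),
                length_m=float(rng.uniform(100, 5000)),
            )
    return G


class TestRoutingProperties:
    def test_multi_source_consistency(self):
        # per-ED Dijkstra + min equals one search from a virtual source
        rng = np.random.default_rng(11)
        for _ in range(10):
            G = random_graph(rng, 9)
            ed_nodes = sorted(rng.choice(9, size=2, replace=False).tolist())
            out = closest_facility(G, eds_at_nodes(G, ed_nodes), assignments_at_nodes(G))
            H = G.copy()
            H.add_node("virt")
            for n in ed_nodes:
                H.add_edge("virt", n, travel_time_min=0.0)
            combined = nx.single_source_dijkstra_path_length(
                H, "virt", weight="travel_time_min"
            )
            for row in out.itertuples(index=False):
                if row.reachable:
                    assert row.travel_time_min == pytest.approx(
                        combined[row.snapped_node], abs=1e-9
                    )
                else:
                    assert row.snapped_node not in combined

    def test_adding_ed_never_increases_time(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            G = random_graph(rng, 9)
            base = closest_facility(G, eds_at_nodes(G, [0]), assignments_at_nodes(G))
            more = closest_facility(G, eds_at_nodes(G, [0, 5]), assignments_at_nodes(G))
            both = base.merge(more, on="cell_id", suffixes=("_1", "_2"))
            both = both[both["reachable_1"]]
            assert (
                both["travel_time_min_2"] <= both["travel_time_min_1"] + 1e-9
            ).all()

    def test_removing_edge_never_decreases_time(self):
        rng = np.random.default_rng(23)
        G = random_graph(rng, 9, p=0.5)
        eds = eds_at_nodes(G, [0])
        base = closest_facility(G, eds, assignments_at_nodes(G))
        u, v = sorted(G.edges)[0]
        H = G.copy()
        H.remove_edge(u, v)
        cut = closest_facility(H, eds, assignments_at_nodes(G))
        both = base.merge(cut, on="cell_id", suffixes=("_1", "_2"))
        both = both[both["reachable_2"]]
        assert (both["travel_time_min_2"] >= both["travel_time_min_1"] - 1e-9).all()

    def test_triangle_property_on_adjacent_nodes(self):
        rng = np.random.default_rng(29)
        G = random_graph(rng, 10, p=0.4)
        out = closest_facility(G, eds_at_nodes(G, [2]), assignments_at_nodes(G))
        t = out.set_index("snapped_node")["travel_time_min"]
        for u, v, data in G.edges(data=True):
            if np.isfinite(t[u]) and np.isfinite(t[v]):
                assert abs(t[u] - t[v]) <= data["travel_time_min"] + 1e-9
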