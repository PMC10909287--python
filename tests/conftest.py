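import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dynaccess.config import ScenarioConfig


@pytest.fixture
def path_graph():
    """5-node path A-B-C-D-E with unit travel times, nodes 0..4 on a line."""
    G = nx.Graph()
    for k in range(5):
        G.add_node(k, x=float(k * 1000), y=0.0)
    for k in range(4):
        G.add_edge(k, k + 1, travel_time_min=1.0, length_m=1000.0)
    return G


@pytest.fixture
def path_cells():
    """One cell centred on each node of the path graph."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{k}" for k in range(5)],
            "x0": [k * 1000.0 - 50.0 for k in range(5)],
            "y0": [-50.0] * 5,
            "size_m": [100.0] * 5,
        }
    )


@pytest.fixture
def small_scenario():
    """Fast 8x8 scenario with both movement effects, noise off."""
    return ScenarioConfig(
        grid_extent=8,
        n_eds=4,
        commuting_fraction=0.3,
        vacation_fraction=0.25,
        core_peak=300.0,
        core_sigma_cells=1.5,
        core_radius_cells=1.0,
        seed=7,
    )


def make_static(pops, size=1000.0):
    """Static grid frame from a 2-D population array."""
    pops = np.asarray(pops, dtype=float)
    n, m = pops.shape
    rows = []
    for i in range(n):
        for j in range(m):
            rows.append(
                {
                    "cell_id": f"s{i}_{j}",
                    "i": i,
                    "j": j,
                    "x0": i * size,
                    "y0": j * size,
                    "size_m": size,
                    "static_pop": pops[i, j],
                }
            )
    return pd.DataFrame(rows)
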