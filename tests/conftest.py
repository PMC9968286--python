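import pytest

import liveability as lv
from liveability import pednet


@pytest.fixture(scope="session")
def small_config():
    return lv.CityConfig(
        seed=7,
        grid_rows=8,
        grid_cols=8,
        cell_size_m=200.0,
        n_addresses=150,
        open_space_fraction=0.2,
        disconnected_component_fraction=0.04,
    )


@pytest.fixture(scope="session")
def small_city(small_config):
    return lv.generate_city(small_config)


@pytest.fixture(scope="session")
def small_result(small_city):
    return lv.run_pipeline(small_city)


@pytest.fixture(scope="session")
def city500():
    """Default-condition city at the 500-address scale used for the
    composite-index checks."""
    return lv.generate_city(lv.CityConfig(seed=11, n_addresses=500))


@pytest.fixture(scope="session")
def result500(city500):
    return lv.run_pipeline(city500)


def line_network(length=4000.0, n_nodes=2):
    """Straight isolated line along the x axis."""
    step = length / (n_nodes - 1)
    nodes = [(f"n{i}", i * step, 0.0) for i in range(n_nodes)]
    edges = [(f"e{i}", f"n{i}", f"n{i+1}", None, None) for i in range(n_nodes - 1)]
    return pednet.build_network(nodes, edges)


def node_anchor(net, node_id, anchor_id=None):
    """Anchor placed exactly on a node via one of its incident edges (no
    geometric snapping, so graph connectivity is preserved exactly)."""
    from shapely.geometry import Point

    for eid in sorted(net.edges):
        e = net.edges[eid]
        if e.u == node_id:
            return pednet.Anchor(anchor_id or node_id, eid, 0.0, 0.0,
                                 Point(net.node_xy[node_id]))
        if e.v == node_id:
            return pednet.Anchor(anchor_id or node_id, eid, e.length_m, 0.0,
                                 Point(net.node_xy[node_id]))
    return None  # isolated node
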