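"""Network model: construction, intersection consolidation, snapping,
walkable catchments and their density/connectivity measures."""

import math

import numpy as np
import pytest
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall
from shapely.geometry import Point, box

from liveability import pednet
from liveability.pednet import (
    Catchment,
    IntersectionSet,
    NetworkStructureError,
    build_network,
    cluster_points,
    consolidate_intersections,
    dwelling_density,
    network_catchment,
    network_distances,
    snap_points,
    street_connectivity,
)

from conftest import line_network


# --- construction -----------------------------------------------------------


def test_path_graph_single_component():
    net = build_network(
        [("a", 0, 0), ("b", 1, 0), ("c", 2, 0), ("d", 3, 0)],
        [("e1", "a", "b"), ("e2", "b", "c"), ("e3", "c", "d")],
    )
    assert net.n_components == 1
    assert len(net.edges) == 3


def test_detached_edge_makes_second_component():
    net = build_network(
        [("a", 0, 0), ("b", 100, 0), ("c", 5000, 0), ("d", 5100, 0)],
        [("e1", "a", "b"), ("e2", "c", "d")],
    )
    assert net.n_components == 2
    assert net.component["a"] != net.component["c"]


def test_duplicate_edge_id_rejected():
    with pytest.raises(NetworkStructureError, match="duplicate"):
        build_network(
            [("a", 0, 0), ("b", 1, 0)], [("e1", "a", "b"), ("e1", "b", "a")]
        )


def test_dangling_endpoint_names_edge():
    with pytest.raises(NetworkStructureError, match="e9"):
        build_network([("a", 0, 0)], [("e9", "a", "zz")])


# --- intersection consolidation ---------------------------------------------


def star(prefix, cx, cy, arms=3, r=50.0):
    """Degree-`arms` node at (cx, cy) with leaf spokes."""
    nodes = [(f"{prefix}c", cx, cy)]
    edges = []
    for i in range(arms):
        ang = 2 * math.pi * i / arms + 0.5
        nodes.append((f"{prefix}l{i}", cx + r * math.cos(ang), cy + r * math.sin(ang)))
        edges.append((f"{prefix}e{i}", f"{prefix}c", f"{prefix}l{i}"))
    return nodes, edges


def test_close_pair_merges_to_midpoint():
    n1, e1 = star("a", 0, 0)
    n2, e2 = star("b", 8, 0)
    net = build_network(n1 + n2, e1 + e2)
    s = consolidate_intersections(net, tolerance_m=12)
    assert len(s) == 1
    _, pt, degree = s.points[0]
    assert (pt.x, pt.y) == pytest.approx((4.0, 0.0))
    assert degree >= 3


def test_distant_pair_stays_separate():
    n1, e1 = star("a", 0, 0)
    n2, e2 = star("b", 20, 0)
    net = build_network(n1 + n2, e1 + e2)
    assert len(consolidate_intersections(net, tolerance_m=12)) == 2


def test_wide_grid_count_unchanged():
    # degree-4 interior nodes of a 5x5 grid at 100 m spacing
    nodes, edges = [], []
    for r in range(5):
        for c in range(5):
            nodes.append((f"n{r}{c}", c * 100.0, r * 100.0))
    for r in range(5):
        for c in range(5):
            if c < 4:
                edges.append((f"h{r}{c}", f"n{r}{c}", f"n{r}{c+1}"))
            if r < 4:
                edges.append((f"v{r}{c}", f"n{r}{c}", f"n{r+1}{c}"))
    net = build_network(nodes, edges)
    n_high_degree = sum(1 for n in net.graph.nodes if net.graph.degree[n] >= 3)
    assert len(consolidate_intersections(net, tolerance_m=12)) == n_high_degree


def brute_force_single_linkage(coords, tol):
    """O(n^2) chained clustering oracle."""
    n = len(coords)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                d = math.dist(coords[i], coords[j])
                if d <= tol and labels[i] != labels[j]:
                    new = min(labels[i], labels[j])
                    old = max(labels[i], labels[j])
                    labels = [new if l == old else l for l in labels]
                    changed = True
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


@pytest.mark.parametrize("seed", range(5))
def test_clustering_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 100, size=(25, 2))
    got = sorted(frozenset(g) for g in cluster_points(coords, 12.0))
    assert got == brute_force_single_linkage(coords.tolist(), 12.0)


def test_consolidation_idempotent(small_result):
    s = small_result.intersections
    again = cluster_points(s.coordinates(), s.tolerance_m)
    assert all(len(g) == 1 for g in again)


def test_empty_network_consolidates_to_empty():
    net = build_network([("a", 0, 0), ("b", 1, 0)], [("e", "a", "b")])
    assert len(consolidate_intersections(net, 12)) == 0


# --- snapping ---------------------------------------------------------------


def test_snap_projection_onto_edge_midpoint():
    net = line_network(length=100.0)
    a = snap_points([("p", Point(50.0, 5.0))], net)["p"]
    assert a.offset_m == pytest.approx(50.0)
    assert a.snap_m == pytest.approx(5.0)
    assert a.edge_id == "e0"


def test_snap_on_node_zero_distance():
    net = line_network(length=100.0)
    a = snap_points([("p", Point(0.0, 0.0))], net)["p"]
    assert a.snap_m == 0.0
    assert a.offset_m == 0.0


def test_snap_tie_breaks_on_smallest_edge_id():
    # two parallel edges equidistant from the point
    net = build_network(
        [("a", 0, 10), ("b", 100, 10), ("c", 0, -10), ("d", 100, -10)],
        [("eB", "a", "b"), ("eA", "c", "d")],
    )
    a = snap_points([("p", Point(50.0, 0.0))], net)["p"]
    assert a.edge_id == "eA"


def test_snap_empty_network_rejected():
    net = build_network([("a", 0, 0)], [])
    with pytest.raises(NetworkStructureError):
        snap_points([("p", Point(0, 0))], net)


# --- shortest-path distances ------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_node_distances_match_floyd_warshall(seed):
    from conftest import node_anchor

    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    nodes = [(f"n{i}", *rng.uniform(0, 1000, 2)) for i in range(n)]
    pairs = {
        tuple(sorted(rng.choice(n, 2, replace=False)))
        for _ in range(2 * n)
    }
    edges = [(f"e{k}", f"n{i}", f"n{j}", None, None) for k, (i, j) in enumerate(sorted(pairs))]
    net = build_network(nodes, edges)

    w = np.full((n, n), np.inf)
    for _, u, v, _, _ in edges:
        i, j = int(u[1:]), int(v[1:])
        d = math.dist(nodes[i][1:], nodes[j][1:])
        w[i, j] = w[j, i] = min(w[i, j], d)
    oracle = floyd_warshall(csr_matrix(np.where(np.isinf(w), 0, w)), directed=False)

    anchors = {
        f"t{i}": node_anchor(net, f"n{i}", f"t{i}")
        for i in range(n)
        if node_anchor(net, f"n{i}") is not None
    }
    src = sorted(anchors)[int(rng.integers(len(anchors)))]
    s = int(src[1:])
    got = network_distances(net, anchors[src], anchors)
    for tid in anchors:
        i = int(tid[1:])
        if np.isfinite(oracle[s, i]):
            assert got[tid] == pytest.approx(oracle[s, i], abs=1e-9)
        else:
            assert tid not in got

    # symmetry spot check
    dst = sorted(anchors)[int(rng.integers(len(anchors)))]
    back = network_distances(net, anchors[dst], anchors)
    if dst in got:
        assert got[dst] == pytest.approx(back[src], abs=1e-9)


# --- catchments -------------------------------------------------------------


def test_sausage_buffer_closed_form_mid_anchor():
    # anchor mid an isolated straight 4000 m line: 1600 m reach each way
    net = line_network(length=4000.0)
    anchor = snap_points([("x", Point(2000.0, 0.0))], net)["x"]
    c = network_catchment(net, anchor)
    assert c.reached_length_m == pytest.approx(3200.0)
    expected = 2 * 3200.0 * 50 + math.pi * 50**2
    assert abs(c.area_m2 - expected) / expected < 0.005
    assert c.valid


def test_short_isolated_segment_below_plausible_minimum():
    net = line_network(length=100.0)
    anchor = snap_points([("x", Point(50.0, 0.0))], net)["x"]
    c = network_catchment(net, anchor)
    assert c.reached_length_m == pytest.approx(100.0)
    expected = 2 * 100.0 * 50 + math.pi * 50**2  # 17,854 m^2 < 16.5 ha
    assert abs(c.area_m2 - expected) / expected < 0.005
    assert not c.valid


def test_catchment_monotone_in_range_and_buffer():
    net = line_network(length=4000.0, n_nodes=5)
    anchor = snap_points([("x", Point(1000.0, 0.0))], net)["x"]
    areas = [network_catchment(net, anchor, range_m=r).area_m2 for r in (400, 800, 1600)]
    assert areas == sorted(areas)
    widths = [network_catchment(net, anchor, buffer_m=w).area_m2 for w in (25, 50, 100)]
    assert widths == sorted(widths)


def test_disconnected_anchor_invalid(small_city, small_result):
    for aid in small_city.disconnected_address_ids:
        assert not small_result.catchments[aid].valid


# --- density and connectivity ----------------------------------------------


def rect_catchment(area_ha=20.0):
    poly = box(0, 0, 400, area_ha * 10_000 / 400)
    return Catchment("x", poly, poly.area, 1000.0, valid=True)


def test_dwelling_density_whole_block_counting():
    import pandas as pd

    c = rect_catchment(20.0)
    blocks = pd.DataFrame(
        {
            "mb_code": ["m1", "m2", "m3", "m4"],
            "dwellings": [40, 60, 99, 7],
            "geometry": [
                box(10, 10, 50, 50),  # inside
                box(350, 10, 390, 50),  # inside
                box(9000, 9000, 9100, 9100),  # far away
                box(400, 0, 500, 100),  # touches the boundary only: counted
            ],
        }
    )
    assert dwelling_density(c, blocks) == pytest.approx((40 + 60 + 7) / 20.0)
    assert dwelling_density(c, blocks.iloc[2:3]) == 0.0


def test_street_connectivity_per_km2():
    c = rect_catchment(50.0)  # 0.5 km^2
    pts = [(f"i{k}", Point(5 + k, 5), 4) for k in range(24)]
    pts.append(("edge", Point(0, 5), 4))  # on the boundary: counted
    s = IntersectionSet(pts, 12.0)
    assert street_connectivity(c, s) == pytest.approx(25 / 0.5)


def test_invalid_catchment_yields_null_measures():
    import pandas as pd

    c = Catchment("x", box(0, 0, 10, 10), 100.0, 10.0, valid=False)
    assert dwelling_density(c, pd.DataFrame({"mb_code": [], "dwellings": [], "geometry": []})) is None
    assert street_connectivity(c, IntersectionSet([], 12.0)) is None
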