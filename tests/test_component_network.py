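"""Component coupling, network construction, and Girvan-Newman communities."""

import itertools
import math

import numpy as np
import pytest

from dyncomp.component_network import (
    ComponentGraph,
    CouplingMatrix,
    build_network,
    component_coupling,
    coupling_matrix,
    detect_communities,
)
from dyncomp.domain_motions import DCCMatrix, DynamicComponent, dcc_matrix
from dyncomp.exceptions import ValidationError
from helpers import correlated_pair, make_series


def _matrix(ids, r):
    return DCCMatrix(series_ids=list(ids), r=np.asarray(r, float))


def _comp(cid, members, kind="sidechain"):
    return DynamicComponent(cid, kind, tuple(members))


def test_coupling_single_pair_absolute_value():
    m = _matrix(["a", "b"], [[1.0, -0.8], [-0.8, 1.0]])
    c = component_coupling(_comp("x", ["a"]), _comp("y", ["b"]), m)
    assert c == pytest.approx(0.8, abs=1e-12)


def test_coupling_cancellation_average_then_absolute():
    # r(a,c) = +0.9 and r(b,c) = -0.9 must cancel to 0, not average to 0.9
    r = np.eye(3)
    r[0, 2] = r[2, 0] = 0.9
    r[1, 2] = r[2, 1] = -0.9
    m = _matrix(["a", "b", "c"], r)
    c = component_coupling(_comp("x", ["a", "b"], kind="domain"), _comp("y", ["c"]), m)
    assert c == pytest.approx(0.0, abs=1e-12)


def test_coupling_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    series = [make_series(rng.normal(size=50) + 6, idx=i) for i in range(7)]
    m = dcc_matrix(series)
    x = _comp("x", [s.series_id for s in series[:3]], kind="domain")
    y = _comp("y", [s.series_id for s in series[3:]], kind="domain")
    oracle = math.fsum(
        m.lookup(a, b) for a in x.member_series for b in y.member_series
    ) / (len(x.member_series) * len(y.member_series))
    assert component_coupling(x, y, m) == pytest.approx(abs(oracle), abs=1e-12)
    # averaging bound: coupling can never exceed the strongest cross pair
    assert component_coupling(x, y, m) <= max(
        abs(m.lookup(a, b)) for a in x.member_series for b in y.member_series
    )


def test_overlapping_components_rejected():
    m = _matrix(["a", "b"], np.eye(2))
    with pytest.raises(ValidationError):
        component_coupling(_comp("x", ["a"]), _comp("y", ["a", "b"], kind="domain"), m)


def test_network_single_component():
    g = build_network([_comp("x", ["a"])], coupling=CouplingMatrix(["x"], np.eye(1)))
    assert len(g.components) == 1 and g.edges == []


def test_inclusive_boundary_at_cutoff():
    c = np.array([[1.0, 0.75], [0.75, 1.0]])
    g = build_network([_comp("x", ["a"]), _comp("y", ["b"])],
                      coupling=CouplingMatrix(["x", "y"], c), coupling_cutoff=0.75)
    assert [(a, b) for a, b, _ in g.edges] == [("x", "y")]


def test_edges_shrink_as_cutoff_rises():
    rng = np.random.default_rng(1)
    series = [make_series(rng.normal(size=60) + rng.uniform(3, 9), idx=i) for i in range(8)]
    m = dcc_matrix(series)
    comps = [_comp(f"c{i}", [s.series_id]) for i, s in enumerate(series)]
    previous = None
    for cutoff in (0.05, 0.2, 0.5, 0.9):
        edges = {frozenset((a, b)) for a, b, _ in
                 build_network(comps, matrix=m, coupling_cutoff=cutoff).edges}
        if previous is not None:
            assert edges <= previous
        previous = edges


def test_edge_set_matches_thresholded_coupling_oracle():
    rng = np.random.default_rng(2)
    shared = rng.normal(size=100)
    series = [make_series(shared * rng.choice([1, -1]) + rng.normal(0, s, 100) + 8, idx=i)
              for i, s in enumerate(rng.uniform(0.1, 3.0, 9))]
    m = dcc_matrix(series)
    comps = [_comp(f"c{i}", [series[3 * i].series_id, series[3 * i + 1].series_id,
                             series[3 * i + 2].series_id], kind="domain")
             for i in range(3)]
    cutoff = 0.5
    g = build_network(comps, matrix=m, coupling_cutoff=cutoff)
    got = {frozenset((a, b)) for a, b, _ in g.edges}
    want = set()
    for x, y in itertools.combinations(comps, 2):
        mean = math.fsum(m.lookup(a, b) for a in x.member_series for b in y.member_series)
        mean /= x.size * y.size
        if abs(mean) >= cutoff:
            want.add(frozenset((x.component_id, y.component_id)))
    assert got == want


def _graph_from_edges(n, edges):
    comps = [_comp(f"n{i}", [f"s{i}"]) for i in range(n)]
    return ComponentGraph(
        components=comps,
        edges=[(f"n{a}", f"n{b}", 1.0) for a, b in edges],
        coupling_cutoff=0.0,
    )


def test_two_cliques_one_bridge_split_at_bridge():
    clique1 = list(itertools.combinations(range(4), 2))
    clique2 = list(itertools.combinations(range(4, 8), 2))
    g = detect_communities(_graph_from_edges(8, clique1 + clique2 + [(0, 4)]))
    labels = g.communities
    assert len(set(labels.values())) == 2
    assert len({labels[f"n{i}"] for i in range(4)}) == 1
    assert len({labels[f"n{i}"] for i in range(4, 8)}) == 1
    assert labels["n0"] != labels["n4"]


def test_complete_uniform_graph_single_community():
    g = detect_communities(_graph_from_edges(5, list(itertools.combinations(range(5), 2))))
    assert g.n_communities() == 1


def test_edgeless_and_empty_graphs():
    g = detect_communities(_graph_from_edges(4, []))
    assert g.n_communities() == 4  # disconnected nodes cannot share a community
    empty = detect_communities(ComponentGraph(components=[], edges=[], coupling_cutoff=0.0))
    assert empty.communities == {}


def test_community_labels_partition_and_are_deterministic():
    edges = list(itertools.combinations(range(4), 2)) + \
        list(itertools.combinations(range(4, 7), 2)) + [(2, 5)]
    a = detect_communities(_graph_from_edges(7, edges))
    b = detect_communities(_graph_from_edges(7, edges))
    assert a.communities == b.communities
    assert set(a.communities) == {f"n{i}" for i in range(7)}
    # disconnected graph components never share a community label
    g = detect_communities(_graph_from_edges(5, [(0, 1), (1, 2), (3, 4)]))
    left = {g.communities[f"n{i}"] for i in range(3)}
    right = {g.communities[f"n{i}"] for i in (3, 4)}
    assert not left & right


def test_graph_invariants_enforced():
    comps = [_comp("x", ["a"]), _comp("y", ["b"])]
    with pytest.raises(ValidationError):
        ComponentGraph(comps, [("x", "x", 1.0)], coupling_cutoff=0.0)  # self-loop
    with pytest.raises(ValidationError):
        ComponentGraph(comps, [("x", "z", 1.0)], coupling_cutoff=0.0)  # unknown node
    with pytest.raises(ValidationError):
        ComponentGraph(comps, [("x", "y", 0.5)], coupling_cutoff=0.75)  # below cutoff


def test_exact_correlation_construction_helper():
    a, b = correlated_pair(0.9, n=400, seed=3)
    m = dcc_matrix([make_series(a - a.min() + 1, idx=0), make_series(b - b.min() + 1, idx=1)])
    assert m.r[0, 1] == pytest.approx(0.9, abs=1e-9)
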