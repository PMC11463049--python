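"""Causal-loop diagram construction, cycle enumeration and polarity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pharmdyn.causal_graph import (
    BALANCING,
    REINFORCING,
    CausalGraph,
    ChallengeNode,
    GraphFormatError,
    SignedEdge,
    enumerate_feedback_loops,
    load_causal_graph,
    loop_polarity,
    structure_counts,
)


def brute_force_cycles(graph: CausalGraph) -> set[tuple[str, ...]]:
    """Independent oracle: try every ordering of every node subset."""
    edges = {(e.source, e.target) for e in graph.edges}
    ids = graph.node_ids()
    found = set()
    for size in range(2, len(ids) + 1):
        for subset in itertools.combinations(ids, size):
            first = min(subset)
            rest = [n for n in subset if n != first]
            for perm in itertools.permutations(rest):
                cycle = (first,) + perm
                if all(
                    (cycle[i], cycle[(i + 1) % size]) in edges for i in range(size)
                ):
                    found.add(cycle)
    return found


def small_graph(edge_spec):
    ids = sorted({n for e in edge_spec for n in e[:2]})
    nodes = [ChallengeNode(id=i, label=i, role="cause") for i in ids]
    edges = [SignedEdge(source=s, target=t, polarity=p) for s, t, p in edge_spec]
    return CausalGraph(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------
def test_load_empty_tables_gives_empty_graph():
    g = load_causal_graph(
        pd.DataFrame(columns=["id", "label", "role"]),
        pd.DataFrame(columns=["source", "target", "polarity"]),
    )
    assert len(g.nodes) == 0 and len(g.edges) == 0
    rep = structure_counts(g)
    assert (rep.n_nodes, rep.n_cause, rep.n_effect, rep.n_loops) == (0, 0, 0, 0)


def test_load_two_node_graph():
    nodes = pd.DataFrame(
        {"id": ["A", "B"], "label": ["a", "b"], "role": ["cause", "effect"]}
    )
    edges = pd.DataFrame(
        {"source": ["A", "B"], "target": ["B", "A"], "polarity": [1, -1]}
    )
    g = load_causal_graph(nodes, edges)
    assert len(g.nodes) == 2 and len(g.edges) == 2
    assert g.edge_polarity("B", "A") == -1


@pytest.mark.parametrize(
    "nodes, edges, match",
    [
        (  # unknown node reference
            {"id": ["A"], "label": ["a"], "role": ["cause"]},
            {"source": ["A"], "target": ["Z"], "polarity": [1]},
            "unknown node",
        ),
        (  # invalid polarity
            {"id": ["A", "B"], "label": ["a", "b"], "role": ["cause", "cause"]},
            {"source": ["A"], "target": ["B"], "polarity": [2]},
            "polarity",
        ),
        (  # duplicate edge
            {"id": ["A", "B"], "label": ["a", "b"], "role": ["cause", "cause"]},
            {"source": ["A", "A"], "target": ["B", "B"], "polarity": [1, 1]},
            "duplicate edge",
        ),
        (  # self edge
            {"id": ["A"], "label": ["a"], "role": ["cause"]},
            {"source": ["A"], "target": ["A"], "polarity": [1]},
            "self-edge",
        ),
        (  # bad role
            {"id": ["A"], "label": ["a"], "role": ["driver"]},
            {"source": [], "target": [], "polarity": []},
            "role",
        ),
        (  # non-integer polarity names the row
            {"id": ["A", "B"], "label": ["a", "b"], "role": ["cause", "cause"]},
            {"source": ["A"], "target": ["B"], "polarity": ["plus"]},
            "edge row 0",
        ),
    ],
)
def test_malformed_tables_rejected(nodes, edges, match):
    with pytest.raises(GraphFormatError, match=match):
        load_causal_graph(pd.DataFrame(nodes), pd.DataFrame(edges))


def test_duplicate_node_ids_rejected():
    with pytest.raises(GraphFormatError, match="duplicate node ids"):
        CausalGraph(
            nodes=[
                ChallengeNode("A", "a", "cause"),
                ChallengeNode("A", "a2", "effect"),
            ],
            edges=[],
        )


# ---------------------------------------------------------------------------
# cycle enumeration
# ---------------------------------------------------------------------------
def test_acyclic_chain_has_no_loops():
    g = small_graph([("A", "B", 1), ("B", "C", 1)])
    assert enumerate_feedback_loops(g) == []


def test_two_cycle_reported_once():
    g = small_graph([("A", "B", 1), ("B", "A", 1)])
    loops = enumerate_feedback_loops(g)
    assert len(loops) == 1
    assert loops[0].node_cycle == ("A", "B")
    assert loops[0].polarity == REINFORCING


def test_cycle_and_reverse_are_distinct():
    g = small_graph(
        [("A", "B", 1), ("B", "C", 1), ("C", "A", 1),
         ("A", "C", 1), ("C", "B", 1), ("B", "A", 1)]
    )
    loops = enumerate_feedback_loops(g)
    cycles = {lp.node_cycle for lp in loops}
    assert ("A", "B", "C") in cycles and ("A", "C", "B") in cycles


def test_random_graphs_match_brute_force_oracle():
    rng = np.random.default_rng(20240917)
    ids = list("ABCDE")
    for _ in range(25):
        edge_spec = [
            (s, t, int(rng.choice([1, -1])))
            for s in ids
            for t in ids
            if s != t and rng.random() < 0.3
        ]
        g = small_graph(edge_spec) if edge_spec else small_graph([("A", "B", 1)])
        loops = enumerate_feedback_loops(g)
        assert {lp.node_cycle for lp in loops} == brute_force_cycles(g)
        # deterministic canonical ordering: smallest node leads each cycle
        for lp in loops:
            assert lp.node_cycle[0] == min(lp.node_cycle)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------
def test_polarity_sign_rules():
    g = small_graph([("A", "B", 1), ("B", "A", 1), ("B", "C", -1), ("C", "B", 1)])
    assert loop_polarity(("A", "B"), g) == REINFORCING
    assert loop_polarity(("B", "C"), g) == BALANCING


def test_polarity_invariant_under_rotation():
    g = small_graph([("A", "B", 1), ("B", "C", -1), ("C", "A", -1)])
    orders = [("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B")]
    assert {loop_polarity(o, g) for o in orders} == {REINFORCING}


def test_flipping_one_edge_sign_flips_loop_polarity():
    rng = np.random.default_rng(7)
    for _ in range(10):
        signs = [int(rng.choice([1, -1])) for _ in range(4)]
        cycle_edges = list(zip("ABCD", "BCDA", signs))
        g = small_graph(cycle_edges)
        before = loop_polarity(tuple("ABCD"), g)
        k = int(rng.integers(4))
        flipped = [
            (s, t, -p if i == k else p) for i, (s, t, p) in enumerate(cycle_edges)
        ]
        g2 = small_graph(flipped)
        after = loop_polarity(tuple("ABCD"), g2)
        assert {before, after} == {REINFORCING, BALANCING}


def test_non_cycle_input_rejected():
    g = small_graph([("A", "B", 1), ("B", "C", 1)])
    with pytest.raises(KeyError):
        loop_polarity(("A", "B", "C"), g)  # C->A edge missing
    with pytest.raises(ValueError):
        loop_polarity(("A",), g)


# ---------------------------------------------------------------------------
# the packaged reference reconstruction
# ---------------------------------------------------------------------------
def test_reference_graph_structure(ref_graph):
    rep = structure_counts(ref_graph)
    assert rep.n_nodes == 17
    assert rep.n_cause == 10
    assert rep.n_effect == 7
    assert rep.n_loops == 8


def test_reference_named_loops(ref_graph):
    loops = {lp.label: lp for lp in enumerate_feedback_loops(ref_graph)}
    assert loops["B1"].polarity == BALANCING
    assert loops["R1"].polarity == REINFORCING
    # the named loops carry their narrative membership
    assert "poor_emergency_response" in loops["B1"].node_cycle
    assert "recruitment_pressure" in loops["B1"].node_cycle
    assert set(loops["R1"].node_cycle) == {
        "no_financial_manager",
        "liquidity_problems",
        "poor_cost_analysis",
    }


def test_structure_report_counts_consistent(ref_graph):
    rep = structure_counts(ref_graph)
    assert rep.n_cause + rep.n_effect == rep.n_nodes
    assert len(rep.loops) == rep.n_loops
    assert "n_loops" in rep.to_json()
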