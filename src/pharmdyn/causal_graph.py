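"""Signed causal-loop diagram of drug supply-chain sustainability challenges.

The domain graph encodes 17 challenges observed in hospital inpatient
pharmacies (insufficient specialized staff, poor emergency responsiveness,
unnecessary resident prescribing, weak financial analysis, medication
expiration, ...) as a signed digraph.  Each node is typed ``cause`` or
``effect`` and each directed edge carries a polarity (+1: same-direction
influence, -1: opposite).  A feedback loop is a simple directed cycle; it is
*reinforcing* when it has an even number of negative edges and *balancing*
when the count is odd.

The packaged reference graph is a documented reconstruction, not a
transcription: the published diagram names the challenges and two loops (the
balancing emergency-response/procurement/finance/recruitment loop ``B1`` and
the reinforcing financial-manager/liquidity/cost-analysis loop ``R1``) but
not the full signed edge list.  See ``data/reference_nodes.csv`` and
``data/reference_edges.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ChallengeNode",
    "SignedEdge",
    "CausalGraph",
    "FeedbackLoop",
    "StructureReport",
    "GraphFormatError",
    "load_causal_graph",
    "reference_graph",
    "enumerate_feedback_loops",
    "loop_polarity",
    "structure_counts",
]

ROLES = ("cause", "effect")
REINFORCING = "reinforcing"
BALANCING = "balancing"


class GraphFormatError(ValueError):
    """Malformed or inconsistent node/edge tables."""


@dataclass(frozen=True)
class ChallengeNode:
    id: str
    label: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GraphFormatError(
                f"node {self.id!r}: role must be one of {ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    polarity: int

    def __post_init__(self) -> None:
        if self.polarity not in (1, -1):
            raise GraphFormatError(
                f"edge {self.source}->{self.target}: polarity must be +1 or -1"
            )
        if self.source == self.target:
            raise GraphFormatError(f"self-edge on {self.source!r} not allowed")


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle; first node is not repeated at the end."""

    node_cycle: tuple[str, ...]
    polarity: str
    label: str | None = None

    def __len__(self) -> int:
        return len(self.node_cycle)


@dataclass
class CausalGraph:
    nodes: list[ChallengeNode]
    edges: list[SignedEdge]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise GraphFormatError(f"duplicate node ids: {sorted(dupes)}")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    raise GraphFormatError(
                        f"edge {e.source}->{e.target} references unknown node "
                        f"{endpoint!r}"
                    )
            if (e.source, e.target) in seen:
                raise GraphFormatError(
                    f"duplicate edge {e.source}->{e.target}"
                )
            seen.add((e.source, e.target))

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def edge_polarity(self, source: str, target: str) -> int:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.polarity
        raise KeyError(f"no edge {source}->{target}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, label=n.label, role=n.role)
        for e in self.edges:
            g.add_edge(e.source, e.target, polarity=e.polarity)
        return g


@dataclass
class StructureReport:
    n_nodes: int
    n_cause: int
    n_effect: int
    n_loops: int
    loops: list[FeedbackLoop] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_nodes": self.n_nodes,
                "n_cause": self.n_cause,
                "n_effect": self.n_effect,
                "n_loops": self.n_loops,
                "loops": [
                    {
                        "label": lp.label,
                        "polarity": lp.polarity,
                        "nodes": list(lp.node_cycle),
                    }
                    for lp in self.loops
                ],
            },
            indent=2,
        )


def _read_table(table, required: Sequence[str], what: str) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    df = pd.DataFrame(table)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GraphFormatError(f"{what} table lacks columns {missing}")
    return df


def load_causal_graph(node_table, edge_table) -> CausalGraph:
    """Build a validated :class:`CausalGraph` from tabular inputs.

    ``node_table``: columns ``id,label,role``; ``edge_table``: columns
    ``source,target,polarity``.  Either argument may be a CSV path or
    anything :class:`pandas.DataFrame` accepts.  Malformed rows raise
    :class:`GraphFormatError` naming the offending row.
    """
    ndf = _read_table(node_table, ("id", "label", "role"), "node")
    edf = _read_table(edge_table, ("source", "target", "polarity"), "edge")
    nodes = []
    for i, row in enumerate(ndf.itertuples(index=False)):
        try:
            nodes.append(
                ChallengeNode(id=str(row.id), label=str(row.label), role=str(row.role))
            )
        except GraphFormatError as exc:
            raise GraphFormatError(f"node row {i}: {exc}") from exc
    edges = []
    for i, row in enumerate(edf.itertuples(index=False)):
        try:
            pol = int(row.polarity)
        except (TypeError, ValueError) as exc:
            raise GraphFormatError(
                f"edge row {i}: polarity {row.polarity!r} is not an integer"
            ) from exc
        try:
            edges.append(SignedEdge(source=str(row.source), target=str(row.target), polarity=pol))
        except GraphFormatError as exc:
            raise GraphFormatError(f"edge row {i}: {exc}") from exc
    return CausalGraph(nodes=nodes, edges=edges)


def _data_path(name: str):
    return resources.files("pharmdyn") / "data" / name


def reference_graph() -> CausalGraph:
    """The packaged 17-challenge reference reconstruction."""
    with resources.as_file(_data_path("reference_nodes.csv")) as np_, resources.as_file(
        _data_path("reference_edges.csv")
    ) as ep_:
        return load_causal_graph(np_, ep_)


def _canonical(cycle: Sequence[str]) -> tuple[str, ...]:
    """Rotate a cycle so its lexicographically smallest node comes first."""
    i = min(range(len(cycle)), key=lambda k: cycle[k])
    return tuple(cycle[i:]) + tuple(cycle[:i])


def loop_polarity(loop_nodes: Sequence[str], graph: CausalGraph) -> str:
    """Classify a cycle as reinforcing (even negatives) or balancing (odd).

    ``loop_nodes`` must form a simple directed cycle in ``graph`` (first node
    not repeated); anything else raises ``ValueError``/``KeyError``.
    """
    if len(loop_nodes) < 2 or len(set(loop_nodes)) != len(loop_nodes):
        raise ValueError(f"{list(loop_nodes)} is not a simple cycle")
    negatives = 0
    for i, src in enumerate(loop_nodes):
        tgt = loop_nodes[(i + 1) % len(loop_nodes)]
        if graph.edge_polarity(src, tgt) < 0:
            negatives += 1
    return REINFORCING if negatives % 2 == 0 else BALANCING


#: loops of the reference reconstruction that carry published names.  B1 is
#: the emergency-response/procurement/finance/recruitment balancing loop, R1
#: the financial-manager/liquidity/cost-analysis reinforcing loop.
_PINNED_LABELS = {
    (
        "incorrect_prioritization",
        "weak_consumption_analysis",
        "liquidity_problems",
        "reduced_profitability",
        "recruitment_pressure",
        "poor_emergency_response",
    ): "B1",
    ("liquidity_problems", "poor_cost_analysis", "no_financial_manager"): "R1",
}


def enumerate_feedback_loops(
    graph: CausalGraph, labels: bool = True
) -> list[FeedbackLoop]:
    """Every simple directed cycle, once, in deterministic order.

    Cycles equal up to rotation are reported once, rotated so the smallest
    node id leads; a cycle and its reverse are distinct loops.  Ordering is
    lexicographic by leading node id, then cycle length, then node sequence.
    Unpinned loops are labelled ``B<i>``/``R<i>`` by polarity class in that
    order; the reference B1/R1 keep their published names.
    """
    g = graph.to_networkx()
    cycles = [_canonical(c) for c in nx.simple_cycles(g)]
    cycles.sort(key=lambda c: (c[0], len(c), c))
    pinned = {_canonical(k): v for k, v in _PINNED_LABELS.items()}
    loops = []
    counters = {BALANCING: 0, REINFORCING: 0}
    # first pass: polarity; second: label assignment skipping pinned numbers
    pols = [loop_polarity(c, graph) for c in cycles]
    taken = {pinned[c] for c in cycles if c in pinned} if labels else set()
    for c, pol in zip(cycles, pols):
        lab = None
        if labels:
            if c in pinned:
                lab = pinned[c]
            else:
                prefix = "B" if pol == BALANCING else "R"
                while True:
                    counters[pol] += 1
                    lab = f"{prefix}{counters[pol]}"
                    if lab not in taken:
                        break
                taken.add(lab)
        loops.append(FeedbackLoop(node_cycle=c, polarity=pol, label=lab))
    return loops


def structure_counts(graph: CausalGraph) -> StructureReport:
    """Node/role/loop counts plus the enumerated loops."""
    loops = enumerate_feedback_loops(graph)
    n_cause = sum(1 for n in graph.nodes if n.role == "cause")
    n_effect = sum(1 for n in graph.nodes if n.role == "effect")
    return StructureReport(
        n_nodes=len(graph.nodes),
        n_cause=n_cause,
        n_effect=n_effect,
        n_loops=len(loops),
        loops=loops,
    )
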