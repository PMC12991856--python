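"""Causal graphs for piecewise SEM: DAG structure, d-separation basis sets,
and the default forest structure -> carbon -> biodiversity conceptual model.

A :class:`CausalGraph` is a DAG over named plot-level variables plus a set of
correlated-error pairs (undirected, error covariances that are allowed and
therefore generate no testable independence claim) and per-node transforms
(identity or natural log) applied before scaling.

The basis set follows the union-conditioning convention: for every
non-adjacent ordered pair (x earlier in topological order, y later) the claim
is  y _||_ x | parents(x) U parents(y).  Because x precedes y topologically,
the conditioning set contains only non-descendants of y, so every claim is a
valid d-separation statement of the DAG (the local Markov property plus weak
union).  Pairs in ``correlated_errors`` are excluded; pairs where both
variables are exogenous are excluded by default — exogenous variables are
treated as freely covarying, as usual in SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "CausalGraph",
    "IndependenceClaim",
    "basis_set",
    "default_graph",
    "default_generating_coefficients",
    "parse_graph",
    "serialize_graph",
]


@dataclass(frozen=True)
class IndependenceClaim:
    """A testable claim: ``y`` is independent of ``x`` given ``conditioning``."""

    x: str
    y: str
    conditioning: tuple[str, ...]

    def label(self) -> str:
        cond = ", ".join(self.conditioning) if self.conditioning else "-"
        return f"{self.y} _||_ {self.x} | {cond}"


@dataclass
class CausalGraph:
    nodes: list[str]
    edges: list[tuple[str, str]]
    correlated_errors: set[frozenset[str]] = field(default_factory=set)
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.nodes)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        self.correlated_errors = {frozenset(p) for p in self.correlated_errors}
        for pair in self.correlated_errors:
            if len(pair) != 2 or not pair <= known:
                raise ValueError(f"bad correlated-error pair {set(pair)}")
            a, b = tuple(pair)
            if (a, b) in self.edges or (b, a) in self.edges:
                raise ValueError(
                    f"correlated-error pair {set(pair)} also has a directed edge"
                )
        for node, t in self.transforms.items():
            if node not in known:
                raise ValueError(f"transform for unknown node {node!r}")
            if t not in ("identity", "log"):
                raise ValueError(f"unknown transform {t!r}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a directed cycle")

    # -- structure ---------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(a for a, b in self.edges if b == node)

    def children(self, node: str) -> list[str]:
        return sorted(b for a, b in self.edges if a == node)

    @property
    def exogenous(self) -> list[str]:
        with_parents = {b for _, b in self.edges}
        return [n for n in self.nodes if n not in with_parents]

    @property
    def endogenous(self) -> list[str]:
        with_parents = {b for _, b in self.edges}
        return [n for n in self.nodes if n in with_parents]

    def topological_order(self) -> list[str]:
        """Deterministic topological order (ties broken by node-list position)."""
        rank = {n: i for i, n in enumerate(self.nodes)}
        return list(
            nx.lexicographical_topological_sort(self.to_networkx(), key=rank.get)
        )

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges


def basis_set(
    graph: CausalGraph, include_exogenous_pairs: bool = False
) -> list[IndependenceClaim]:
    """Independence claims implied by the DAG (d-separation basis set).

    One claim per non-adjacent ordered pair, the topologically earlier
    variable as predictor and the later as response, conditioning on the
    union of both variables' parents.  Pairs declared in
    ``graph.correlated_errors`` are excluded, as are pairs of two exogenous
    variables unless ``include_exogenous_pairs`` is set.
    """
    order = graph.topological_order()
    exog = set(graph.exogenous)
    edge_set = set(graph.edges)
    claims = []
    for i, x in enumerate(order):
        for y in order[i + 1 :]:
            if (x, y) in edge_set or (y, x) in edge_set:
                continue
            if frozenset((x, y)) in graph.correlated_errors:
                continue
            if not include_exogenous_pairs and x in exog and y in exog:
                continue
            cond = tuple(sorted(set(graph.parents(x)) | set(graph.parents(y))))
            claims.append(IndependenceClaim(x=x, y=y, conditioning=cond))
    return claims


# ---------------------------------------------------------------------------
# Default conceptual model
# ---------------------------------------------------------------------------

EXOGENOUS_NODES = ["stand_age", "tree_richness", "mean_temp", "annual_precip"]
STRUCTURE_NODES = ["mean_dbh", "dw_type_richness"]
CARBON_NODES = ["c_living", "c_dead"]
TAXON_NODES = ["rich_plants", "rich_fungi", "rich_beetles", "rich_birds"]


def default_graph() -> CausalGraph:
    """The default conceptual model linking forest structure, carbon and
    multi-taxon richness.

    Every exogenous driver (stand age, tree species richness, mean annual
    temperature, annual precipitation) may influence every endogenous node;
    the structural variables (mean dbh, deadwood type richness) may influence
    both carbon pools and all four taxa; both carbon pools may influence all
    taxa; and vascular-plant richness may influence saproxylic beetles.
    Temperature and precipitation share a correlated error.  Carbon stocks
    are log-transformed before scaling.

    The implied d-separation basis set has exactly 7 claims (df = 14): the
    two within-layer structure pairs (mean dbh ~ deadwood type richness,
    living ~ dead carbon) and the five taxon pairs other than
    plants -> beetles.
    """
    nodes = EXOGENOUS_NODES + STRUCTURE_NODES + CARBON_NODES + TAXON_NODES
    endo = STRUCTURE_NODES + CARBON_NODES + TAXON_NODES
    edges: list[tuple[str, str]] = []
    for x in EXOGENOUS_NODES:
        edges += [(x, y) for y in endo]
    for x in STRUCTURE_NODES:
        edges += [(x, y) for y in CARBON_NODES + TAXON_NODES]
    for x in CARBON_NODES:
        edges += [(x, y) for y in TAXON_NODES]
    edges.append(("rich_plants", "rich_beetles"))
    return CausalGraph(
        nodes=nodes,
        edges=edges,
        correlated_errors={frozenset(("mean_temp", "annual_precip"))},
        transforms={"c_living": "log", "c_dead": "log"},
    )


def default_generating_coefficients(magnitude: float = 0.3) -> dict[tuple[str, str], float]:
    """Generating path coefficients for the synthetic forest.

    Nonzero (+/- ``magnitude``) on the ecologically established paths, zero
    on the remaining conceptual edges: stand age
    increases mean dbh, deadwood carbon and bird richness; tree richness
    increases deadwood type richness and decreases mean dbh; mean dbh
    increases living carbon and bird richness; deadwood type richness
    increases deadwood carbon, bird and beetle richness; living carbon
    increases beetle richness but decreases bird and plant richness; dead
    carbon increases fungus richness; plants increase beetles; temperature
    decreases deadwood type richness; precipitation increases plant richness
    and living carbon and decreases fungus richness.
    """
    m = magnitude
    signed = {
        ("stand_age", "mean_dbh"): +m,
        ("stand_age", "c_dead"): +m,
        ("stand_age", "rich_birds"): +m,
        ("tree_richness", "dw_type_richness"): +m,
        ("tree_richness", "mean_dbh"): -m,
        ("mean_dbh", "c_living"): +m,
        ("mean_dbh", "rich_birds"): +m,
        ("dw_type_richness", "c_dead"): +m,
        ("dw_type_richness", "rich_birds"): +m,
        ("dw_type_richness", "rich_beetles"): +m,
        ("c_living", "rich_beetles"): +m,
        ("c_living", "rich_birds"): -m,
        ("c_living", "rich_plants"): -m,
        ("c_dead", "rich_fungi"): +m,
        ("rich_plants", "rich_beetles"): +m,
        ("mean_temp", "dw_type_richness"): -m,
        ("annual_precip", "rich_plants"): +m,
        ("annual_precip", "c_living"): +m,
        ("annual_precip", "rich_fungi"): -m,
    }
    coeffs = {edge: 0.0 for edge in default_graph().edges}
    coeffs.update(signed)
    return coeffs


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

def parse_graph(text: str) -> CausalGraph:
    """Parse a graph specification.

    Line syntax: ``parent -> child`` for a directed edge, ``a ~~ b`` for a
    correlated-error pair, ``log: node`` for a log transform; ``#`` starts a
    comment.  Nodes are collected from the lines.
    """
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    cerrs: set[frozenset[str]] = set()
    transforms: dict[str, str] = {}

    def add_node(n: str):
        if n not in nodes:
            nodes.append(n)

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("log:"):
            transforms[line[4:].strip()] = "log"
        elif "->" in line:
            a, b = (s.strip() for s in line.split("->", 1))
            add_node(a)
            add_node(b)
            edges.append((a, b))
        elif "~~" in line:
            a, b = (s.strip() for s in line.split("~~", 1))
            add_node(a)
            add_node(b)
            cerrs.add(frozenset((a, b)))
        elif line.startswith("node:"):
            add_node(line[5:].strip())
        else:
            raise ValueError(f"cannot parse graph line: {raw!r}")
    return CausalGraph(nodes=nodes, edges=edges, correlated_errors=cerrs, transforms=transforms)


def serialize_graph(graph: CausalGraph) -> str:
    lines = [f"node: {n}" for n in graph.nodes]
    lines += [f"{a} -> {b}" for a, b in graph.edges]
    lines += [f"{a} ~~ {b}" for a, b in (sorted(p) for p in graph.correlated_errors)]
    lines += [f"log: {n}" for n, t in graph.transforms.items() if t == "log"]
    return "\n".join(lines) + "\n"
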