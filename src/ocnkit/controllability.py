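"""Structural control configurations of a directed regulatory network.

A structural control configuration (SCC — not a strongly connected
component) is a spanning skeleton of the network built from a maximum
matching in the bipartite representation of the digraph: every node is
split into an out-copy and an in-copy, and each directed edge u->v becomes
a bipartite edge between the out-copy of u and the in-copy of v.  The
matched edges partition the node set into node-disjoint elementary paths
and elementary cycles; nodes whose in-copy is unmatched are the driver
nodes (one per elementary path).  Additional links are the remaining
network edges that run from a non-terminal path node into a cycle,
conveying control from the paths to the cycles.

Because the matching number of a bipartite graph is unique, the number of
driver nodes is seed-independent even though the edge composition of the
matching varies.  Matchings are diversified by permuting, under a seed, the
order in which nodes and edges are inserted into the bipartite graph
before running the Hopcroft–Karp algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Matching:
    """A set of directed edges, no two sharing a source or a target."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        sources = [u for u, _ in self.edges]
        targets = [v for _, v in self.edges]
        if len(set(sources)) != len(sources) or len(set(targets)) != len(targets):
            raise ValueError("matching edges must have distinct sources and targets")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SCCDecomposition:
    """One structural control configuration of a network.

    ``paths`` and ``cycles`` jointly partition the node set.  ``skeleton``
    (matched edges plus additional links) is the edge set along which
    direct control propagates.
    """

    matching: Matching
    paths: list[list[str]]
    cycles: list[list[str]]
    additional_links: frozenset[tuple[str, str]]
    driver_nodes: frozenset[str]

    @property
    def skeleton_edges(self) -> set[tuple[str, str]]:
        edges = set(self.matching.edges)
        edges |= set(self.additional_links)
        return edges


def maximum_matching(net: nx.DiGraph, seed: int | None = None) -> Matching:
    """Maximum matching of the bipartite representation of the digraph.

    The matching size (hence the driver-node count) is identical across
    seeds; the edge composition may differ.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    edges = sorted(net.edges)
    if seed is not None:
        nodes = [nodes[i] for i in rng.permutation(len(nodes))]
        edges = [edges[i] for i in rng.permutation(len(edges))]
    bip = nx.Graph()
    out_nodes = [("out", u) for u in nodes]
    bip.add_nodes_from(out_nodes, bipartite=0)
    bip.add_nodes_from((("in", v) for v in nodes), bipartite=1)
    bip.add_edges_from((("out", u), ("in", v)) for u, v in edges)
    match = nx.bipartite.hopcroft_karp_matching(bip, top_nodes=out_nodes)
    matched = frozenset(
        (key[1], val[1]) for key, val in match.items() if key[0] == "out"
    )
    return Matching(edges=matched)


def decompose_scc(net: nx.DiGraph, matching: Matching) -> SCCDecomposition:
    """Decompose a matched network into paths, cycles and additional links."""
    for u, v in matching.edges:
        if not net.has_edge(u, v):
            raise ValueError(f"matched edge {u}->{v} is not a network edge")
    nxt = {u: v for u, v in matching.edges}
    has_in = {v for _, v in matching.edges}

    paths: list[list[str]] = []
    seen: set[str] = set()
    for start in sorted(net.nodes):
        if start in has_in or start in seen:
            continue
        path = [start]
        seen.add(start)
        node = start
        while node in nxt:
            node = nxt[node]
            path.append(node)
            seen.add(node)
        paths.append(path)

    cycles: list[list[str]] = []
    for start in sorted(net.nodes):
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        node = nxt[start]
        while node != start:
            cycle.append(node)
            seen.add(node)
            node = nxt[node]
        cycles.append(cycle)

    cycle_nodes = {n for cyc in cycles for n in cyc}
    # tails eligible for additional links: path nodes except each path's
    # terminal node
    eligible_tails = {n for path in paths for n in path[:-1]}
    matched = set(matching.edges)
    additional = frozenset(
        (u, v)
        for u, v in net.edges
        if (u, v) not in matched and u in eligible_tails and v in cycle_nodes
    )
    drivers = frozenset(path[0] for path in paths)
    return SCCDecomposition(
        matching=matching,
        paths=paths,
        cycles=cycles,
        additional_links=additional,
        driver_nodes=drivers,
    )


def sample_sccs(
    net: nx.DiGraph, n_sccs: int = 1000, seed: int | None = None
) -> list[SCCDecomposition]:
    """Sample ``n_sccs`` structural control configurations.

    Each comes from an independently randomized maximum matching;
    duplicates are allowed (their count is logged).  Deterministic given
    ``seed``.
    """
    if n_sccs < 1:
        raise ValueError("n_sccs must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_sccs)
    sccs = []
    for s in seeds:
        matching = maximum_matching(net, seed=int(s))
        sccs.append(decompose_scc(net, matching))
    n_unique = len({scc.matching.edges for scc in sccs})
    if n_unique < n_sccs:
        logger.info("sampled %d SCCs, %d unique matchings", n_sccs, n_unique)
    return sccs


def direct_control_region(gene: str, scc: SCCDecomposition, net: nx.DiGraph) -> set[str]:
    """Genes reachable from ``gene`` along SCC skeleton edges, plus itself.

    Reachability is computed over matched edges and additional links only,
    never over raw network edges.
    """
    if gene not in net:
        raise KeyError(f"unknown gene {gene!r}")
    adj: dict[str, list[str]] = {}
    for u, v in scc.skeleton_edges:
        adj.setdefault(u, []).append(v)
    region = {gene}
    stack = [gene]
    while stack:
        node = stack.pop()
        for succ in adj.get(node, ()):
            if succ not in region:
                region.add(succ)
                stack.append(succ)
    return region
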