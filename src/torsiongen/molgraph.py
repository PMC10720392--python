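"""Covalent-bond graph metadata for torsion sampling.

The pipeline: build the undirected bond graph, take a deterministic DFS
spanning tree (breaking each cycle at one bond), prune leaf nodes in a single
pass (terminal bonds carry no dihedral), and for each surviving tree edge
record the smaller connected component obtained by deleting it -- the atom set
that a rotation about that bond moves.

Leaf pruning is deliberately a *single* pass over the original tree, not an
iterated 2-core reduction: iterating would delete genuine terminal-group
torsions (e.g. the methyl rotation of all-atom ethane, whose carbons are each
left with one heavy neighbor after the hydrogens go).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ConnectivityError, UsageError, ValidationError
from .molio import MolecularSystem

__all__ = [
    "MoleculeGraph",
    "SpanningTree",
    "DihedralSpec",
    "DihedralTopology",
    "build_graph",
    "spanning_tree_dfs",
    "dihedral_edges",
    "rotating_component",
    "prepare_rotamer_metadata",
]


@dataclass
class MoleculeGraph:
    """Symmetric adjacency of the covalent-bond graph."""

    n_nodes: int
    adjacency: dict[int, list[int]]


@dataclass
class SpanningTree:
    """DFS spanning tree; broken_cycle_edges are the non-tree bonds."""

    n_nodes: int
    tree_edges: set[tuple[int, int]]
    broken_cycle_edges: set[tuple[int, int]]
    root: int = 0

    def tree_adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for u, v in self.tree_edges:
            adj[u].append(v)
            adj[v].append(u)
        return {k: sorted(v) for k, v in adj.items()}


@dataclass(frozen=True)
class DihedralSpec:
    """One rotatable bond.

    ``edge`` is the (u, v) bond with u < v; ``rotating_set`` is the smaller
    component produced by deleting it from the spanning tree.  ``quadruple``
    is the measurement quadruple (a, r, s, b): r is the edge endpoint inside
    the rotating set, s the static endpoint, a the smallest-index tree
    neighbor of r besides s, b likewise for s.  Orienting the quadruple by
    the rotating side fixes the sign convention so that applying +theta
    increases the measured dihedral by +theta.
    """

    edge: tuple[int, int]
    rotating_set: frozenset[int]
    quadruple: tuple[int, int, int, int]


@dataclass
class DihedralTopology:
    """Ordered list of rotatable-bond specs; order is sorted by edge."""

    specs: list[DihedralSpec] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.specs)


def build_graph(system: MolecularSystem) -> MoleculeGraph:
    """Undirected bond graph with sorted neighbor lists; must be connected."""
    n = system.n_atoms
    if n < 2 or not system.bonds:
        raise ValidationError("need at least 2 atoms and 1 bond")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(system.bonds)
    if not nx.is_connected(g):
        parts = sorted(len(c) for c in nx.connected_components(g))
        raise ConnectivityError(
            f"bond graph has {len(parts)} components (sizes {parts}); "
            "atoms must form a single connected structure"
        )
    adjacency = {i: sorted(g.neighbors(i)) for i in range(n)}
    return MoleculeGraph(n_nodes=n, adjacency=adjacency)


def spanning_tree_dfs(graph: MoleculeGraph, root: int = 0) -> SpanningTree:
    """Deterministic DFS spanning tree: from `root`, neighbors in ascending order."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for u, nbrs in graph.adjacency.items():
        for v in nbrs:
            g.add_edge(u, v)
    tree = set()
    for u, v in nx.dfs_edges(g, source=root, sort_neighbors=sorted):
        tree.add((min(u, v), max(u, v)))
    all_edges = {(min(u, v), max(u, v)) for u, v in g.edges}
    broken = all_edges - tree
    assert len(tree) == graph.n_nodes - 1
    return SpanningTree(
        n_nodes=graph.n_nodes, tree_edges=tree, broken_cycle_edges=broken, root=root
    )


def dihedral_edges(tree: SpanningTree) -> list[tuple[int, int]]:
    """Tree edges that carry a dihedral: drop degree-1 nodes (single pass)."""
    degree = {i: 0 for i in range(tree.n_nodes)}
    for u, v in tree.tree_edges:
        degree[u] += 1
        degree[v] += 1
    surviving = [
        (u, v) for u, v in tree.tree_edges if degree[u] > 1 and degree[v] > 1
    ]
    return sorted(surviving)


def rotating_component(tree: SpanningTree, edge: tuple[int, int]) -> set[int]:
    """Smaller of the two tree components after deleting `edge`.

    Ties go to the component containing the smaller-indexed endpoint.
    """
    e = (min(edge), max(edge))
    if e not in tree.tree_edges:
        raise UsageError(f"edge {edge} is not a spanning-tree edge")
    adj = tree.tree_adjacency()
    u, v = e

    def component(start: int, blocked: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((u, v), (v, u)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    comp_u = component(u, v)
    comp_v = component(v, u)
    if len(comp_u) < len(comp_v):
        return comp_u
    if len(comp_v) < len(comp_u):
        return comp_v
    return comp_u if u < v else comp_v  # u < v always; tie -> side of min(u, v)


def prepare_rotamer_metadata(system: MolecularSystem) -> DihedralTopology:
    """Full preparation pass: graph -> DFS tree -> pruned edges -> specs."""
    graph = build_graph(system)
    tree = spanning_tree_dfs(graph)
    adj = tree.tree_adjacency()
    specs = []
    for u, v in dihedral_edges(tree):
        rot = rotating_component(tree, (u, v))
        r, s = (u, v) if u in rot else (v, u)
        a_candidates = [x for x in adj[r] if x != s]
        b_candidates = [x for x in adj[s] if x != r]
        if not a_candidates or not b_candidates:
            continue  # cannot happen after pruning, kept defensive
        spec = DihedralSpec(
            edge=(u, v),
            rotating_set=frozenset(rot),
            quadruple=(min(a_candidates), r, s, min(b_candidates)),
        )
        specs.append(spec)
    return DihedralTopology(specs=specs)


def metadata_to_dict(topology: DihedralTopology) -> dict:
    """JSON-ready representation of the dihedral metadata."""
    return {
        "M": topology.M,
        "dihedrals": [
            {
                "edge": list(s.edge),
                "rotating_set": sorted(s.rotating_set),
                "quadruple": list(s.quadruple),
            }
            for s in topology.specs
        ],
    }


def metadata_from_dict(doc: dict) -> DihedralTopology:
    specs = [
        DihedralSpec(
            edge=tuple(d["edge"]),
            rotating_set=frozenset(d["rotating_set"]),
            quadruple=tuple(d["quadruple"]),
        )
        for d in doc["dihedrals"]
    ]
    return DihedralTopology(specs=specs)
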