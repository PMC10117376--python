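"""Interactome graph construction, summaries, and dense-cluster detection.

The graph is built from a confidence-scored edge list (combined score in
[0, 1] plus evidence channels) restricted to high-confidence edges backed
by experimental or curated-database evidence.  Dense clusters are found
with a from-scratch implementation of the molecular-complex-detection
(MCODE) algorithm: vertices are weighted by the highest k-core of their
closed neighborhood times that core's density, complexes are grown from
high-weight seeds by a vertex-weight-percentage rule, and post-processed
with a k-core filter and a haircut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "DEFAULT_ALLOWED_CHANNELS",
    "MCODEParams",
    "MCODECluster",
    "NetworkSummary",
    "build_graph",
    "component_summary",
    "mcode_vertex_weight",
    "mcode_complexes",
]

DEFAULT_MIN_SCORE = 0.700
DEFAULT_ALLOWED_CHANNELS = frozenset({"experimental", "database"})


def _parse_channels(value) -> frozenset[str]:
    if isinstance(value, str):
        parts = value.replace(";", ",").split(",")
        return frozenset(p.strip() for p in parts if p.strip())
    return frozenset(value)


def build_graph(
    node_list: Iterable[str] | None,
    edges: pd.DataFrame,
    min_score: float = DEFAULT_MIN_SCORE,
    allowed_channels: Iterable[str] = DEFAULT_ALLOWED_CHANNELS,
) -> nx.Graph:
    """Build a simple undirected graph from a scored edge table.

    Parameters
    ----------
    node_list : iterable of str or None
        Nodes to retain even when isolated.  Edges touching proteins not
        in this list are dropped (with a warning count).  ``None`` means
        "use every endpoint in the edge table".
    edges : DataFrame
        Columns ``protein_a``, ``protein_b``, ``combined_score`` and
        ``channels`` (comma- or semicolon-separated evidence labels).
    min_score : float
        Minimum combined confidence score, inclusive.
    allowed_channels : iterable of str
        An edge is kept only if it is supported by at least one of these
        evidence channels.

    Self-loops and duplicate edges are dropped (counts recorded in
    ``graph.graph``).
    """
    allowed = frozenset(allowed_channels)
    graph = nx.Graph()
    if node_list is not None:
        graph.add_nodes_from(sorted(set(node_list)))
    known = set(graph.nodes) if node_list is not None else None

    n_unknown = n_self = n_dup = 0
    for row in edges.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        try:
            score = float(row.combined_score)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed combined_score {row.combined_score!r}") from exc
        if a == b:
            n_self += 1
            continue
        if known is not None and (a not in known or b not in known):
            n_unknown += 1
            continue
        if score < min_score:
            continue
        channels = _parse_channels(row.channels)
        if not channels & allowed:
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b, combined_score=score, channels=channels)
    if n_unknown:
        warnings.warn(f"dropped {n_unknown} edges with unknown endpoints", stacklevel=2)
    graph.graph.update(
        n_unknown_endpoint_edges=n_unknown,
        n_self_loops_dropped=n_self,
        n_duplicate_edges_dropped=n_dup,
    )
    return graph


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    component_sizes: tuple[int, ...]
    components: tuple[frozenset[str], ...]
    n_isolated: int
    hubs: tuple[tuple[str, int], ...]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "component_sizes": list(self.component_sizes),
            "n_isolated": self.n_isolated,
            "hubs": [list(h) for h in self.hubs],
        }


def component_summary(graph: nx.Graph, top_k: int = 3) -> NetworkSummary:
    """Connected components, mean degree, and the top-``top_k`` hub list.

    Components are sorted by size descending, then by lexicographically
    smallest member; hubs by degree descending then node id.
    """
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    mean_degree = 2.0 * n_edges / n_nodes if n_nodes else 0.0
    hubs = sorted(graph.degree, key=lambda item: (-item[1], item[0]))[:top_k]
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_degree=mean_degree,
        component_sizes=tuple(len(c) for c in comps),
        components=tuple(comps),
        n_isolated=sum(1 for c in comps if len(c) == 1),
        hubs=tuple((n, d) for n, d in hubs),
    )


@dataclass(frozen=True)
class MCODEParams:
    """Tuning knobs of the complex-detection algorithm (plugin defaults)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # vertex weight percentage (VWP)
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2

    def validate(self) -> None:
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1)")
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be nonnegative")


@dataclass(frozen=True)
class MCODECluster:
    nodes: frozenset[str]
    density: float
    score: float  # density * size

    @property
    def size(self) -> int:
        return len(self.nodes)


def _highest_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest k-core of ``graph`` as (k, induced subgraph)."""
    if graph.number_of_nodes() == 0:
        return 0, graph
    core_numbers = nx.core_number(graph)
    k = max(core_numbers.values())
    members = [n for n, c in core_numbers.items() if c >= k]
    return k, graph.subgraph(members)


def mcode_vertex_weight(graph: nx.Graph, node, degree_cutoff: int = 2) -> float:
    """Vertex weight: highest k-core number of the closed neighborhood
    times the density of that core.

    Nodes with degree below ``degree_cutoff`` (including isolated nodes)
    receive weight 0.
    """
    if node not in graph:
        raise KeyError(f"unknown node {node!r}")
    if graph.degree(node) < degree_cutoff:
        return 0.0
    closed = graph.subgraph([node, *graph.neighbors(node)])
    k, core = _highest_core(closed)
    return float(k) * nx.density(core)


def mcode_complexes(graph: nx.Graph, params: MCODEParams = MCODEParams()) -> list[MCODECluster]:
    """Detect densely interconnected complexes.

    Seeds are taken from unvisited vertices in descending weight order
    (ties broken by node id).  A complex grows outward from its seed,
    admitting unassigned neighbors whose weight is at least
    ``(1 - node_score_cutoff) * seed_weight``, to at most ``max_depth``
    hops.  Complexes lacking a ``k_core``-core are discarded; haircut
    removes members singly connected within the complex; optional fluff
    adds boundary vertices whose neighborhood density exceeds the fluff
    cutoff.  Each node belongs to at most one complex.  Output is sorted
    by score (density x size) descending, then by member set, so results
    are independent of input node order.
    """
    params.validate()
    weights = {
        v: mcode_vertex_weight(graph, v, params.degree_cutoff) for v in graph.nodes
    }
    seed_order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw_clusters: list[set] = []

    for seed in seed_order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        cluster = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            next_frontier = []
            for v in sorted(frontier, key=str):
                for nb in sorted(graph.neighbors(v), key=str):
                    if nb in cluster or nb in assigned:
                        continue
                    if weights[nb] >= threshold:
                        cluster.add(nb)
                        next_frontier.append(nb)
            frontier = next_frontier
            depth += 1
        assigned |= cluster
        raw_clusters.append(cluster)

    results: list[MCODECluster] = []
    for cluster in raw_clusters:
        sub = graph.subgraph(cluster)
        k, _ = _highest_core(sub)
        if k < params.k_core:
            continue
        members = set(cluster)
        if params.haircut:
            members = {v for v in members if sub.degree(v) >= 2}
        if params.fluff:
            extra = set()
            for v in sorted(members, key=str):
                for nb in graph.neighbors(v):
                    if nb in members or nb in extra or nb in assigned:
                        continue
                    nbhood = graph.subgraph([nb, *graph.neighbors(nb)])
                    if nx.density(nbhood) > params.fluff_density_cutoff:
                        extra.add(nb)
            members |= extra
        if not members:
            continue
        final = graph.subgraph(members)
        density = nx.density(final) if final.number_of_nodes() > 1 else 0.0
        results.append(
            MCODECluster(frozenset(members), density, density * final.number_of_nodes())
        )

    results.sort(key=lambda c: (-c.score, sorted(map(str, c.nodes))))
    return results
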