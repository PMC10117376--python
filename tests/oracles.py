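"""Independent oracles used by the unit and acceptance tests.

Everything here is deliberately implemented without calling the package
code paths it checks: brute-force traversal, exhaustive enumeration, and
permutation simulation.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_components(edges, nodes):
    """Connected components by naive label propagation (no networkx)."""
    labels = {n: n for n in nodes}

    def find(n):
        while labels[n] != n:
            labels[n] = labels[labels[n]]
            n = labels[n]
        return n

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            labels[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda c: (-len(c), min(map(str, c))))


def brute_force_highest_core(graph: nx.Graph):
    """Highest k-core by exhaustive subset search (tiny graphs only)."""
    best_k, best_nodes = 0, frozenset()
    nodes = list(graph.nodes)
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if sub.number_of_nodes() == 0:
                continue
            k = min(dict(sub.degree).values())
            if k > best_k or (k == best_k and len(subset) > len(best_nodes)):
                best_k, best_nodes = k, frozenset(subset)
    return best_k, best_nodes


def density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def cluster_superset_violations(graph, clusters, params, weight_fn):
    """Check that no reachable strict superset of a reported cluster is
    denser than the cluster itself (exhaustive; graphs of <= 10 nodes).

    "Reachable" means: connected vertex sets containing the cluster,
    drawn from vertices of the cluster's component whose weight meets
    the expansion threshold of the cluster's heaviest member, excluding
    vertices already assigned to other clusters.
    """
    weights = {v: weight_fn(graph, v, params.degree_cutoff) for v in graph.nodes}
    assigned: dict = {}
    for idx, cluster in enumerate(clusters):
        for v in cluster.nodes:
            assigned[v] = idx
    violations = []
    for idx, cluster in enumerate(clusters):
        members = set(cluster.nodes)
        comp = next(c for c in nx.connected_components(graph) if members <= c)
        seed_weight = max(weights[v] for v in members)
        threshold = (1.0 - params.node_score_cutoff) * seed_weight
        eligible = {
            v for v in comp
            if (weights[v] >= threshold and assigned.get(v, idx) == idx) or v in members
        }
        extras = sorted(eligible - members, key=str)
        base_density = density(graph.subgraph(members))
        for r in range(1, len(extras) + 1):
            for added in itertools.combinations(extras, r):
                candidate = members | set(added)
                sub = graph.subgraph(candidate)
                if not nx.is_connected(sub):
                    continue
                if density(sub) > base_density + 1e-9:
                    violations.append((idx, frozenset(candidate)))
    return violations


def tukey_q_stats(parts: list[np.ndarray]):
    """Studentized-range statistics for each pair of groups."""
    k = len(parts)
    n_total = sum(len(p) for p in parts)
    msw = sum(((p - p.mean()) ** 2).sum() for p in parts) / (n_total - k)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(msw / 2.0 * (1.0 / len(parts[i]) + 1.0 / len(parts[j])))
            out[(i, j)] = abs(parts[i].mean() - parts[j].mean()) / se
    return out


def permutation_tukey(groups: dict, n_perm: int, rng: np.random.Generator) -> dict:
    """Family-wise adjusted pairwise p-values by label permutation.

    For each pair, p = P(max over pairs of the permuted q statistic >=
    the observed q for that pair); this is the resampling analogue of
    Tukey's studentized-range adjustment.
    """
    labels = sorted(groups)
    sizes = [len(groups[lab]) for lab in labels]
    data = np.concatenate([np.asarray(groups[lab], dtype=float) for lab in labels])
    splits = np.cumsum(sizes)[:-1]
    observed = tukey_q_stats(list(np.split(data, splits)))
    exceed = {pair: 0 for pair in observed}
    for _ in range(n_perm):
        permuted = rng.permutation(data)
        max_q = max(tukey_q_stats(list(np.split(permuted, splits))).values())
        for pair, q in observed.items():
            if max_q >= q:
                exceed[pair] += 1
    return {
        (labels[i], labels[j]): count / n_perm
        for (i, j), count in exceed.items()
    }
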