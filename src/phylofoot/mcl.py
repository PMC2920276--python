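"""Markov clustering (MCL) of weighted undirected graphs.

Flow simulation on the column-stochastic transition matrix of the graph:
expansion (matrix power) spreads flow along paths, inflation (elementwise
power followed by column renormalization) strengthens strong flows and
starves weak ones, and small entries are pruned. At convergence the
non-zero structure decomposes the graph into attractor systems, which are
read out as clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["MCLResult", "mcl", "mcl_matrix"]


@dataclass
class MCLResult:
    clusters: list[set]
    converged: bool
    iterations: int

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


def mcl_matrix(
    w: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    self_loops: float = 1.0,
) -> tuple[np.ndarray, bool, int]:
    """Run the flow iteration on a dense weight matrix; returns the limit
    matrix, a convergence flag and the iteration count."""
    n = w.shape[0]
    m = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(m, self_loops)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m = m / col
        if m.shape == prev.shape and np.abs(m - prev).max() < 1e-6:
            converged = True
            break
    return m, converged, it


def _read_clusters(m: np.ndarray, nodes: list) -> list[set]:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:
        attractors = [int(m[:, j].argmax()) for j in range(n)]
    # attractor systems: attractor rows whose supports overlap form one cluster
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    support = {i: set(np.flatnonzero(m[i] > 0)) | {i} for i in attractors}
    for ii, a in enumerate(attractors):
        for b in attractors[ii + 1:]:
            if support[a] & support[b]:
                sys_graph.add_edge(a, b)
    systems = sorted(
        (sorted(comp) for comp in nx.connected_components(sys_graph)),
        key=lambda c: c[0],
    )
    raw = [set().union(*(support[a] for a in comp)) for comp in systems]
    # resolve overlaps: a node joins the system giving it the most flow
    assignment: dict[int, int] = {}
    for j in range(n):
        owners = [k for k, nodes_k in enumerate(raw) if j in nodes_k]
        if not owners:
            assignment[j] = -1
            continue
        flows = [sum(m[a, j] for a in systems[k]) for k in owners]
        best = max(range(len(owners)), key=lambda t: (flows[t], -owners[t]))
        assignment[j] = owners[best]
    clusters: dict[int, set] = {}
    singletons = []
    for j, k in assignment.items():
        if k == -1:
            singletons.append({nodes[j]})
        else:
            clusters.setdefault(k, set()).add(nodes[j])
    out = [cl for _, cl in sorted(clusters.items())] + singletons
    return sorted(out, key=lambda s: sorted(map(str, s))[0])


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
) -> MCLResult:
    """Cluster a weighted undirected graph with MCL.

    Every node lands in exactly one cluster; disconnected components are
    never merged. Non-convergence returns the current clustering with
    ``converged=False``.
    """
    nodes = sorted(graph.nodes, key=str)
    if not nodes:
        raise ValueError("empty graph")
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = data.get("weight", 1.0)
    m, converged, it = mcl_matrix(w, inflation, expansion, prune, max_iter)
    clusters = _read_clusters(m, nodes)
    return MCLResult(clusters=clusters, converged=converged, iterations=it)
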