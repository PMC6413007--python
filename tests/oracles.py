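"""Independent brute-force oracles used to verify the descriptor machinery.

Every function here deliberately avoids the code paths of the package under
test: distances come from networkx BFS, detours from exhaustive DFS over all
simple paths, subgraph counts from itertools over raw edge subsets, and the
remaining formulas are written as plain double loops.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def nx_graph(g):
    h = nx.Graph()
    h.add_nodes_from(range(g.n_atoms))
    h.add_edges_from((i, j) for i, j, _ in g.bonds)
    return h


def bfs_distance_matrix(g) -> np.ndarray:
    h = nx_graph(g)
    n = g.n_atoms
    d = np.zeros((n, n), dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(h):
        for dst, length in lengths.items():
            d[src, dst] = length
    return d


def exhaustive_detour_matrix(g) -> np.ndarray:
    """Longest simple path between every pair by full DFS (small graphs only)."""
    h = nx_graph(g)
    n = g.n_atoms
    delta = np.zeros((n, n), dtype=int)
    adj = {v: list(h.neighbors(v)) for v in h.nodes}

    for s in range(n):
        best = [0] * n
        stack = [(s, {s}, 0)]
        while stack:
            u, visited, length = stack.pop()
            if length > best[u]:
                best[u] = length
            for w in adj[u]:
                if w not in visited:
                    stack.append((w, visited | {w}, length + 1))
        for t in range(n):
            if t != s:
                delta[s, t] = best[t]
    return delta


def connected_edge_subsets(g, m: int) -> list[frozenset]:
    """All connected m-edge subgraphs by raw enumeration of edge subsets."""
    edges = [(i, j) for i, j, _ in g.bonds]
    out = []
    for subset in combinations(edges, m):
        h = nx.Graph(list(subset))
        if nx.is_connected(h):
            out.append(frozenset(subset))
    return out


def classify_subset(subset) -> str:
    deg: dict[int, int] = {}
    for i, j in subset:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    if max(deg.values()) <= 2:
        return "path"
    return "path_cluster" if 2 in deg.values() else "cluster"


def chi_oracle(g, order: int, kind: str, valence: bool) -> float:
    deltas = g.valence_degrees() if valence else g.degrees()
    if order == 0:
        return sum(1.0 / np.sqrt(d) for d in deltas) if kind == "path" else 0.0
    total = 0.0
    for subset in connected_edge_subsets(g, order):
        if classify_subset(subset) != kind:
            continue
        verts = {v for e in subset for v in e}
        prod = 1.0
        for v in verts:
            prod *= 1.0 / np.sqrt(deltas[v])
        total += prod
    return total


def charge_index_oracle(g, k: int) -> float:
    """G_k by explicit loops over the defining matrix product."""
    n = g.n_atoms
    d = bfs_distance_matrix(g)
    a = g.adjacency()
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] != k:
                continue
            m_ij = sum(
                a[i, l] * (1.0 / d[l, j] ** 2 if d[l, j] > 0 else 0.0) for l in range(n)
            )
            m_ji = sum(
                a[j, l] * (1.0 / d[l, i] ** 2 if d[l, i] > 0 else 0.0) for l in range(n)
            )
            total += abs(m_ij - m_ji)
    return total


def maxdn_oracle(g) -> float:
    n = g.n_atoms
    d = bfs_distance_matrix(g)
    i_state = []
    for a in g.atoms:
        i_state.append(((2.0 / a.element.L) ** 2 * a.delta_v + 1.0) / a.delta)
    worst = 0.0
    for i in range(n):
        di = sum(
            (i_state[i] - i_state[j]) / (d[i, j] + 1.0) ** 2 for j in range(n) if j != i
        )
        if di < 0 and -di > worst:
            worst = -di
    return worst


def hyper_wiener_oracle(g) -> float:
    d = bfs_distance_matrix(g)
    n = g.n_atoms
    return 0.5 * sum(
        d[i, j] + d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    )


def loo_refit_q2_oracle(X, y) -> float:
    """Q^2 by literally refitting with each case deleted (numpy lstsq)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        xd = np.column_stack([np.ones(n - 1), X[mask]])
        beta, *_ = np.linalg.lstsq(xd, y[mask], rcond=None)
        pred = beta[0] + X[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    return 1.0 - press / ((y - y.mean()) ** 2).sum()


def permuted_graph(g, perm):
    """Rebuild a MolGraph with atoms reordered by ``perm`` (independent helper)."""
    from topoqsar.graph import MolGraph

    inv = {old: new for new, old in enumerate(perm)}
    atoms = [g.atoms[old] for old in perm]
    bonds = sorted(
        (min(inv[i], inv[j]), max(inv[i], inv[j]), order) for i, j, order in g.bonds
    )
    return MolGraph(atoms=atoms, bonds=bonds, id=g.id + "_perm")
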