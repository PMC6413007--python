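"""Hydrogen-suppressed molecular graphs and the graph primitives behind every
topological descriptor: shortest-path (distance) and longest-simple-path
(detour) matrices, and connected edge-subgraph enumeration in the Kier–Hall
path / cluster / path-cluster typology.

SMILES parsing and aromaticity perception are delegated to RDKit; this module
owns the graph model itself (vertex degrees delta and valence degrees
delta_v, which RDKit does not expose in the Kier–Hall form needed here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger

from .elements import ELEMENTS, ElementInfo, valence_degree

RDLogger.DisableLog("rdApp.error")

log = logging.getLogger(__name__)

#: largest biconnected component for which detour distances are attempted
DETOUR_COMPONENT_LIMIT = 30

BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a connected graph."""


class DetourIntractableError(RuntimeError):
    """Raised when a biconnected component exceeds the detour search limit."""


@dataclass
class AtomNode:
    """One heavy atom: element, hydrogen count and the two Kier–Hall degrees."""

    element: ElementInfo
    h_count: int
    delta: int
    delta_v: float


@dataclass
class MolGraph:
    """Hydrogen-suppressed molecular graph with stable atom indexing."""

    atoms: list[AtomNode]
    bonds: list[tuple[int, int, object]]  # (i, j, order) with i < j
    id: str = ""
    _nx: nx.Graph | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_rings(self) -> int:
        """Cyclomatic number |E| - |V| + 1 (graph is connected)."""
        return self.n_bonds - self.n_atoms + 1

    def to_networkx(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_atoms))
            g.add_edges_from((i, j) for i, j, _ in self.bonds)
            self._nx = g
        return self._nx

    def adjacency(self) -> np.ndarray:
        """Unit adjacency matrix (bond orders are not encoded)."""
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        return np.array([a.delta for a in self.atoms], dtype=float)

    def valence_degrees(self) -> np.ndarray:
        return np.array([a.delta_v for a in self.atoms], dtype=float)


def from_rdkit(mol: Chem.Mol, mol_id: str = "") -> MolGraph:
    """Build a MolGraph from a sanitized RDKit molecule.

    Explicit hydrogens are folded into ``h_count``; charged or isotopic atoms
    are accepted with the neutral-element valence-electron count (a warning is
    logged, matching the all-neutral chemistry this package targets).
    """
    mol = Chem.RemoveHs(mol)
    atoms: list[AtomNode] = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in ELEMENTS:
            raise SmilesParseError(f"unsupported element {sym!r} in molecule {mol_id!r}")
        if a.GetFormalCharge() != 0 or a.GetIsotope() != 0:
            log.warning(
                "atom %s in %r is charged/isotopic; neutral-element Zv used for delta_v",
                sym, mol_id,
            )
        h = a.GetTotalNumHs()
        delta = sum(1 for nb in a.GetNeighbors() if nb.GetAtomicNum() > 1)
        atoms.append(
            AtomNode(
                element=ELEMENTS[sym],
                h_count=h,
                delta=delta,
                delta_v=valence_degree(sym, h),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise SmilesParseError(
                f"unsupported bond type {b.GetBondType()} in molecule {mol_id!r}"
            )
        bonds.append((min(i, j), max(i, j), order))
    g = MolGraph(atoms=atoms, bonds=sorted(bonds, key=lambda t: t[:2]), id=mol_id)
    if g.n_atoms > 1 and not nx.is_connected(g.to_networkx()):
        raise SmilesParseError(f"molecule {mol_id!r} is disconnected")
    return g


def parse_smiles(smiles: str, mol_id: str = "") -> MolGraph:
    """Parse SMILES into a hydrogen-suppressed connected MolGraph.

    Multi-fragment (dot-disconnected) input is rejected: every descriptor in
    this package assumes a connected graph.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    smiles = smiles.strip()
    if "." in smiles:
        raise SmilesParseError(f"disconnected (multi-fragment) SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return from_rdkit(mol, mol_id=mol_id or smiles)


def topological_distances(g: MolGraph) -> np.ndarray:
    """All-pairs shortest topological distances (every bond counts 1)."""
    n = g.n_atoms
    d = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(d, 0)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in g.bonds:
        adj[i].append(j)
        adj[j].append(i)
    for s in range(n):
        row = d[s]
        frontier = [s]
        dist = 0
        while frontier:
            dist += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if row[v] < 0:
                        row[v] = dist
                        nxt.append(v)
            frontier = nxt
    return d


def _longest_paths_from(adj: list[list[int]], start: int, allowed: frozenset[int]) -> dict[int, int]:
    """Longest simple path lengths from ``start`` to every reachable vertex,
    restricted to ``allowed``, by exhaustive DFS with backtracking."""
    best: dict[int, int] = {}
    visited = {start}
    path_len = 0

    def dfs(u: int) -> None:
        nonlocal path_len
        if path_len > best.get(u, -1):
            best[u] = path_len
        for v in adj[u]:
            if v in allowed and v not in visited:
                visited.add(v)
                path_len += 1
                dfs(v)
                path_len -= 1
                visited.remove(v)

    dfs(start)
    del best[start]
    return best


def detour_distances(g: MolGraph, component_limit: int = DETOUR_COMPONENT_LIMIT) -> np.ndarray:
    """All-pairs longest simple path (detour) distances.

    Detour distance is additive across cut vertices, so the exhaustive search
    runs only inside each biconnected component; results are then combined
    along the unique block path of the block–cut tree.  A component larger
    than ``component_limit`` raises :class:`DetourIntractableError` rather
    than hanging.
    """
    n = g.n_atoms
    nxg = g.to_networkx()
    delta = np.zeros((n, n), dtype=int)
    if n < 2:
        return delta

    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in g.bonds:
        adj[i].append(j)
        adj[j].append(i)

    blocks = [frozenset(b) for b in nx.biconnected_components(nxg)]
    for b in blocks:
        if len(b) > component_limit:
            raise DetourIntractableError(
                f"biconnected component with {len(b)} atoms exceeds limit {component_limit}"
            )

    # within-block all-pairs detour
    block_detour: list[dict[tuple[int, int], int]] = []
    for b in blocks:
        table: dict[tuple[int, int], int] = {}
        for u in b:
            far = _longest_paths_from(adj, u, b)
            for v, length in far.items():
                table[(u, v)] = length
        block_detour.append(table)

    # block--cut tree: nodes are ('B', k) and ('C', v) for articulation v
    cuts = set(nx.articulation_points(nxg))
    tree = nx.Graph()
    vertex_home: dict[int, object] = {}  # non-cut vertex -> its block node
    for k, b in enumerate(blocks):
        bn = ("B", k)
        tree.add_node(bn)
        for v in b:
            if v in cuts:
                tree.add_edge(bn, ("C", v))
            else:
                vertex_home[v] = bn
    for v in cuts:
        vertex_home[v] = ("C", v)

    if len(blocks) == 1:
        table = block_detour[0]
        for (u, v), length in table.items():
            delta[u, v] = length
        return delta

    block_index = {("B", k): k for k in range(len(blocks))}
    # single BFS tree over the block-cut tree rooted anywhere gives unique paths
    parent = {
        child: par for par, child in nx.bfs_edges(tree, source=next(iter(tree.nodes)))
    }

    def tree_path(a, b):
        # path between two nodes of a tree via common ancestor
        seen = {}
        x = a
        i = 0
        while True:
            seen[x] = i
            if x not in parent:
                break
            x = parent[x]
            i += 1
        path_b = []
        x = b
        while x not in seen:
            path_b.append(x)
            x = parent[x]
        meet = x
        path_a = []
        y = a
        while y != meet:
            path_a.append(y)
            y = parent[y]
        return path_a + [meet] + path_b[::-1]

    for u, v in combinations(range(n), 2):
        nodes = tree_path(vertex_home[u], vertex_home[v])
        total = 0
        current = u
        for node, nxt in zip(nodes, nodes[1:]):
            if node[0] == "B":
                # leave this block at the articulation vertex nxt
                exit_v = nxt[1]
                if current != exit_v:
                    total += block_detour[block_index[node]][(current, exit_v)]
                current = exit_v
        last = nodes[-1]
        if last[0] == "B" and current != v:
            total += block_detour[block_index[last]][(current, v)]
        delta[u, v] = delta[v, u] = total
    return delta


# ---------------------------------------------------------------------------
# connected edge-subgraph enumeration (Kier–Hall orders 0..4)
# ---------------------------------------------------------------------------

KINDS = ("path", "cluster", "path_cluster")


def classify_edge_subgraph(edges: list[tuple[int, int]]) -> str:
    """Kier–Hall type from the subgraph degree sequence.

    path: every subgraph vertex has degree <= 2; cluster: some vertex of
    degree >= 3 and none of degree 2; path_cluster: some vertex >= 3 and some
    of degree 2.  The three kinds partition all connected edge-subgraphs.
    """
    deg: dict[int, int] = {}
    for i, j in edges:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    mx = max(deg.values())
    if mx <= 2:
        return "path"
    if 2 in deg.values():
        return "path_cluster"
    return "cluster"


def connected_edge_subgraphs(g: MolGraph, order: int):
    """Yield every connected subgraph with exactly ``order`` edges, once.

    Enumeration is the ESU (exclusion) scheme on the line graph: a set of
    edges is connected in g iff it is a connected vertex set of the line
    graph.  Yields lists of (i, j) vertex pairs (i < j).
    """
    if order < 1:
        return []
    edges = [(i, j) for i, j, _ in g.bonds]
    m = len(edges)
    # line-graph adjacency over edge indices
    incident: dict[int, list[int]] = {}
    for idx, (i, j) in enumerate(edges):
        incident.setdefault(i, []).append(idx)
        incident.setdefault(j, []).append(idx)
    lg_adj: list[set[int]] = [set() for _ in range(m)]
    for ids in incident.values():
        for a, b in combinations(ids, 2):
            lg_adj[a].add(b)
            lg_adj[b].add(a)

    results: list[list[tuple[int, int]]] = []

    # Wernicke's ESU on the line graph: `closed` is sub ∪ N(sub) restricted to
    # indices > root, which guarantees each connected set is emitted once.
    def extend(sub: list[int], ext: list[int], closed: set[int], root: int) -> None:
        if len(sub) == order:
            results.append([edges[e] for e in sorted(sub)])
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            new = [u for u in lg_adj[w] if u > root and u not in closed]
            extend(sub + [w], ext + new, closed | set(new), root)

    for root in range(m):
        ext0 = [u for u in lg_adj[root] if u > root]
        extend([root], ext0, {root} | set(ext0), root)
    return results


def enumerate_subgraphs(g: MolGraph, order: int, kind: str):
    """Connected ``order``-edge subgraphs of the requested Kier–Hall kind.

    Returns a list of (vertex_tuple, edge_list).  Order 0 returns single
    vertices (kind must be "path").  Cluster below order 3 and path_cluster
    below order 4 are empty by construction.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    if not 0 <= order <= 4:
        raise ValueError("order must be in 0..4")
    if order == 0:
        if kind != "path":
            return []
        return [((v,), []) for v in range(g.n_atoms)]
    out = []
    for sub_edges in connected_edge_subgraphs(g, order) or []:
        if classify_edge_subgraph(sub_edges) == kind:
            verts = tuple(sorted({v for e in sub_edges for v in e}))
            out.append((verts, sub_edges))
    return out
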