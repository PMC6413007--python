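"""Core topological descriptor families computed from the hydrogen-suppressed
molecular graph: Kier–Hall connectivity indices (simple and valence, orders
0–4, path / cluster / path-cluster), their combined quotient/difference forms,
Galvez topological charge indices, the Wiener index, and constitutional
counts.

All formulas operate on the abstract graph only; bond orders never enter
(aromatic and Kekulé renderings of the same molecule give identical values,
asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import MolGraph, enumerate_subgraphs, topological_distances

#: sentinel for a descriptor whose value is undefined for a molecule
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ChiKey:
    """Identifies one connectivity index: order m, subgraph kind, valence flag."""

    order: int
    kind: str = "path"
    valence: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.order <= 4:
            raise ValueError("chi order must be in 0..4")
        if self.kind == "cluster" and self.order < 3:
            pass  # legal key; the index is identically zero
        if self.kind == "path_cluster" and self.order < 4:
            pass


def chi(g: MolGraph, key: ChiKey, _subgraphs=None) -> float:
    """Kier–Hall connectivity index ^m chi_t.

    Sum over connected m-edge subgraphs of the requested kind of the
    reciprocal square root of the product of vertex degrees (simple delta or
    valence delta_v) of the subgraph's vertices.  Order 0 sums over atoms.
    """
    deltas = g.valence_degrees() if key.valence else g.degrees()
    if np.any(deltas <= 0):
        return UNDEFINED
    inv_sqrt = 1.0 / np.sqrt(deltas)
    subs = _subgraphs if _subgraphs is not None else enumerate_subgraphs(g, key.order, key.kind)
    total = 0.0
    for verts, _ in subs:
        prod = 1.0
        for v in verts:
            prod *= inv_sqrt[v]
        total += prod
    return total


def chi_combined(g: MolGraph, order: int, kind: str, conventions=None, _subgraphs=None):
    """Combined connectivity indices (C, D) of one order/kind.

    D is the difference and C the quotient of the simple and valence chi; the
    orientation of each is a recorded convention (see
    :mod:`topoqsar.conventions`).  C is undefined (NaN) when the denominator
    vanishes.
    """
    from .conventions import DEFAULT

    conv = conventions or DEFAULT
    subs = _subgraphs if _subgraphs is not None else enumerate_subgraphs(g, order, kind)
    x = chi(g, ChiKey(order, kind, valence=False), _subgraphs=subs)
    xv = chi(g, ChiKey(order, kind, valence=True), _subgraphs=subs)
    if conv.cd_difference == "simple_minus_valence":
        d = x - xv
    else:
        d = xv - x
    num, den = (x, xv) if conv.cd_quotient == "simple_over_valence" else (xv, x)
    c = num / den if den != 0.0 else UNDEFINED
    return c, d


def charge_indices(g: MolGraph, max_order: int = 10, _dist=None):
    """Galvez topological charge indices G_1..G_max and J_1..J_max.

    With A the unit adjacency matrix and Q the reciprocal-square-distance
    matrix (zero diagonal), the charge-transfer term between atoms i and j is
    the antisymmetric part of M = A·Q; G_k sums its absolute value over pairs
    at topological distance k, and J_k = G_k / (n - 1).
    """
    n = g.n_atoms
    if n < 2:
        raise ValueError("charge indices require at least two atoms")
    d = _dist if _dist is not None else topological_distances(g)
    a = g.adjacency()
    with np.errstate(divide="ignore"):
        q = np.where(d > 0, 1.0 / np.maximum(d, 1) ** 2, 0.0)
    m = a @ q
    c = np.abs(m - m.T)
    gk = np.zeros(max_order)
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    cv = c[iu]
    for k in range(1, max_order + 1):
        gk[k - 1] = cv[dv == k].sum()
    jk = gk / (n - 1)
    return gk, jk


def wiener(g: MolGraph, _dist=None) -> float:
    """Wiener index: sum of all pairwise shortest topological distances."""
    d = _dist if _dist is not None else topological_distances(g)
    return float(np.triu(d, k=1).sum())


def constitutional(g: MolGraph) -> dict[str, float]:
    """Constitutional counts: atoms, bonds, rings, degree counts V1..V4 and
    per-element heavy-atom counts."""
    out: dict[str, float] = {
        "n_atoms": float(g.n_atoms),
        "n_bonds": float(g.n_bonds),
        "n_rings": float(g.n_rings),
    }
    degs = [a.delta for a in g.atoms]
    for k in range(1, 5):
        out[f"V{k}"] = float(sum(1 for d in degs if d == k))
    counts: dict[str, int] = {}
    for a in g.atoms:
        counts[a.element.symbol] = counts.get(a.element.symbol, 0) + 1
    for sym in sorted(counts):
        out[f"n_{sym}"] = float(counts[sym])
    return out


def hyper_wiener_from_distances(d: np.ndarray) -> float:
    """Half-sum of d + d^2 over pairs (equals the hyper-detour index on trees)."""
    iu = np.triu_indices(d.shape[0], k=1)
    dv = d[iu].astype(float)
    return 0.5 * float((dv + dv**2).sum())
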