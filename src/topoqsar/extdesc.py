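"""Extended descriptors from the Dragon-style families: hyper-detour index
(ww), maximal electrotopological negative variation (MAXDN), Burden-matrix
eigenvalue descriptors (BELm), and the adjacency principal-eigenvector sum
(VEA1).

The Burden off-diagonal recipe is a recorded convention (see
:mod:`topoqsar.conventions`): the exact variant used by proprietary software
is undocumented, so both a faithful rendering of Burden's original scheme and
a plain variant without the terminal-bond increment are provided.
"""

from __future__ import annotations

import numpy as np

from .elements import CARBON_MASS
from .graph import MolGraph, detour_distances, topological_distances
from .topo import UNDEFINED


def hyper_detour(g: MolGraph, _detour=None) -> float:
    """Hyper-detour index ww = 1/2 * sum over pairs of (Delta + Delta^2),
    with Delta the longest-simple-path (detour) distance."""
    delta = _detour if _detour is not None else detour_distances(g)
    iu = np.triu_indices(g.n_atoms, k=1)
    dv = delta[iu].astype(float)
    return 0.5 * float((dv + dv**2).sum())


def intrinsic_states(g: MolGraph) -> np.ndarray:
    """Kier–Hall intrinsic states I_i = ((2/L_i)^2 * delta_v_i + 1) / delta_i."""
    out = np.empty(g.n_atoms)
    for i, a in enumerate(g.atoms):
        if a.delta == 0:
            raise ValueError("intrinsic state undefined for an isolated atom")
        out[i] = ((2.0 / a.element.L) ** 2 * a.delta_v + 1.0) / a.delta
    return out


def estate_perturbations(g: MolGraph, _dist=None) -> np.ndarray:
    """Field perturbations dI_i = sum_j (I_i - I_j) / (d_ij + 1)^2.

    Pairwise antisymmetric, hence sums to zero over the molecule.
    """
    i_state = intrinsic_states(g)
    d = _dist if _dist is not None else topological_distances(g)
    diff = i_state[:, None] - i_state[None, :]
    w = 1.0 / (d.astype(float) + 1.0) ** 2
    np.fill_diagonal(w, 0.0)
    return (diff * w).sum(axis=1)


def maxdn(g: MolGraph, _dist=None) -> float:
    """Maximal electrotopological negative variation: the largest -dI_i over
    atoms with negative perturbation, or 0 when no atom has dI < 0."""
    di = estate_perturbations(g, _dist=_dist)
    neg = -di[di < 0]
    return float(neg.max()) if neg.size else 0.0


_NUMERIC_ORDER = {"aromatic": 1.5, 1: 1.0, 2: 2.0, 3: 3.0}


def burden_matrix(g: MolGraph, variant: str = "original") -> np.ndarray:
    """Mass-weighted Burden connectivity matrix.

    Diagonal: atomic mass relative to carbon.  Bonded off-diagonal: 0.1 x
    conventional bond order (aromatic = 1.5), plus 0.01 when either endpoint
    is terminal (variant "original" only).  Non-bonded entries: 0.001.
    """
    if variant not in ("original", "plain"):
        raise ValueError("burden variant must be 'original' or 'plain'")
    n = g.n_atoms
    b = np.full((n, n), 0.001)
    for idx, a in enumerate(g.atoms):
        b[idx, idx] = a.element.mass / CARBON_MASS
    degs = g.degrees()
    for i, j, order in g.bonds:
        val = 0.1 * _NUMERIC_ORDER[order]
        if variant == "original" and (degs[i] == 1 or degs[j] == 1):
            val += 0.01
        b[i, j] = b[j, i] = val
    return b


def belm(g: MolGraph, rank: int, variant: str = "original") -> float:
    """The rank-th smallest eigenvalue of the mass-weighted Burden matrix
    (BELm5 = rank 5).  Undefined (NaN) when the molecule has fewer atoms than
    the requested rank."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if g.n_atoms < rank:
        return UNDEFINED
    eig = np.linalg.eigvalsh(burden_matrix(g, variant=variant))
    return float(np.sort(eig)[rank - 1])


def vea1(g: MolGraph) -> float:
    """Sum of components of the adjacency principal eigenvector (unit norm,
    signs fixed non-negative; Perron–Frobenius guarantees this for a
    connected graph)."""
    a = g.adjacency()
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    if vec.sum() < 0:
        vec = -vec
    # numerical noise can leave tiny negative components
    return float(np.abs(vec).sum())
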