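"""Descriptor orchestration: named descriptor registry, per-molecule lazy
caching of the expensive graph primitives (distance matrix, detour matrix,
subgraph enumerations), and assembly of full descriptor vectors.

Descriptor names
----------------
``chi{m}{t}`` / ``chiv{m}{t}``
    simple / valence connectivity index of order m and kind t
    (t = "p", "c", "pc"), e.g. ``chi1p``, ``chiv4pc``.
``Cchi{m}{t}`` / ``Dchi{m}{t}``
    combined quotient / difference of the two, under the active convention.
``G1``..``G10``, ``J1``..``J10``
    Galvez charge indices (``GGI10`` is an alias for ``G10``).
``W``, ``n_atoms``, ``n_bonds``, ``n_rings``, ``V1``..``V4``, ``n_<El>``
    Wiener index and constitutional counts.
``ww``, ``MAXDN``, ``BELm5``, ``VEA1``
    extended (Dragon-family) descriptors.
"""

from __future__ import annotations

import re

from . import extdesc, topo
from .conventions import DEFAULT, Conventions
from .graph import MolGraph, detour_distances, enumerate_subgraphs, topological_distances

KIND_CODE = {"p": "path", "c": "cluster", "pc": "path_cluster"}

#: the (order, kind) pairs with a possibly non-zero chi value
CHI_KEYS: list[tuple[int, str]] = [
    (0, "p"), (1, "p"), (2, "p"), (3, "p"), (4, "p"),
    (3, "c"), (4, "c"),
    (4, "pc"),
]

_CHI_RE = re.compile(r"^(chi|chiv|Cchi|Dchi)([0-4])(p|c|pc)$")
_G_RE = re.compile(r"^(G|J)([1-9][0-9]?)$")


class DescriptorCalculator:
    """Computes named descriptors for one molecule, caching shared primitives."""

    def __init__(self, g: MolGraph, conventions: Conventions | None = None):
        self.g = g
        self.conventions = conventions or DEFAULT
        self._dist = None
        self._detour = None
        self._subgraphs: dict[tuple[int, str], list] = {}
        self._charge = None
        self._const = None

    # -- cached primitives -------------------------------------------------
    @property
    def dist(self):
        if self._dist is None:
            self._dist = topological_distances(self.g)
        return self._dist

    @property
    def detour(self):
        if self._detour is None:
            self._detour = detour_distances(self.g)
        return self._detour

    def subgraphs(self, order: int, kind: str):
        key = (order, kind)
        if key not in self._subgraphs:
            self._subgraphs[key] = enumerate_subgraphs(self.g, order, kind)
        return self._subgraphs[key]

    def _charge_indices(self):
        if self._charge is None:
            self._charge = topo.charge_indices(self.g, max_order=10, _dist=self.dist)
        return self._charge

    def _constitutional(self):
        if self._const is None:
            self._const = topo.constitutional(self.g)
        return self._const

    # -- public API --------------------------------------------------------
    def chi(self, order: int, kind_code: str, valence: bool) -> float:
        kind = KIND_CODE[kind_code]
        return topo.chi(
            self.g,
            topo.ChiKey(order, kind, valence=valence),
            _subgraphs=self.subgraphs(order, kind),
        )

    def get(self, name: str) -> float:
        m = _CHI_RE.match(name)
        if m:
            prefix, order_s, kc = m.groups()
            order = int(order_s)
            if prefix == "chi":
                return self.chi(order, kc, valence=False)
            if prefix == "chiv":
                return self.chi(order, kc, valence=True)
            c, d = topo.chi_combined(
                self.g, order, KIND_CODE[kc], conventions=self.conventions,
                _subgraphs=self.subgraphs(order, KIND_CODE[kc]),
            )
            return c if prefix == "Cchi" else d
        m = _G_RE.match(name)
        if m:
            which, k_s = m.groups()
            k = int(k_s)
            gk, jk = self._charge_indices()
            if k > len(gk):
                return 0.0
            return float(gk[k - 1] if which == "G" else jk[k - 1])
        if name == "GGI10":
            return self.get("G10")
        if name == "W":
            return topo.wiener(self.g, _dist=self.dist)
        if name == "ww":
            return extdesc.hyper_detour(self.g, _detour=self.detour)
        if name == "MAXDN":
            return extdesc.maxdn(self.g, _dist=self.dist)
        if name == "VEA1":
            return extdesc.vea1(self.g)
        if name == "BELm5":
            return extdesc.belm(self.g, 5, variant=self.conventions.burden)
        m = re.match(r"^BELm([1-9][0-9]?)$", name)
        if m:
            return extdesc.belm(self.g, int(m.group(1)), variant=self.conventions.burden)
        const = self._constitutional()
        if name in const:
            return const[name]
        if re.match(r"^n_[A-Z][a-z]?$", name):
            return 0.0  # element absent from this molecule
        raise KeyError(f"unknown descriptor {name!r}")

    def compute(self, names) -> dict[str, float]:
        return {n: self.get(n) for n in names}


#: fixed column order of the core (topological + constitutional) table
CORE_DESCRIPTORS: list[str] = (
    ["n_atoms", "n_bonds", "n_rings", "V1", "V2", "V3", "V4", "W"]
    + [f"chi{m}{k}" for m, k in CHI_KEYS]
    + [f"chiv{m}{k}" for m, k in CHI_KEYS]
    + [f"Cchi{m}{k}" for m, k in CHI_KEYS]
    + [f"Dchi{m}{k}" for m, k in CHI_KEYS]
    + [f"G{k}" for k in range(1, 11)]
    + [f"J{k}" for k in range(1, 11)]
)

#: extended family (slower: requires the detour matrix)
EXTENDED_DESCRIPTORS: list[str] = ["ww", "MAXDN", "BELm5", "VEA1"]


def compute_descriptors(
    g: MolGraph,
    names=None,
    conventions: Conventions | None = None,
) -> dict[str, float]:
    """Compute a descriptor vector for one molecule.

    ``names=None`` computes the core table; pass an explicit list (e.g.
    ``CORE_DESCRIPTORS + EXTENDED_DESCRIPTORS``) for more.
    """
    calc = DescriptorCalculator(g, conventions=conventions)
    return calc.compute(names if names is not None else CORE_DESCRIPTORS)
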