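"""Deterministic fixture molecules and random test graphs.

The fixture set is the substrate for the oracle-based descriptor tests:
linear and branched alkanes, cycloalkanes, small heteroatom probes, the
packaged library fragment list, and seeded random connected graphs (built
directly as carbon skeletons with a degree cap of 4 so they remain valid
hydrogen-suppressed molecular graphs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import ELEMENTS
from .graph import AtomNode, MolGraph, parse_smiles
from .library import load_library_spec, packaged_library_path

ALKANES = {f"C{n}": "C" * n for n in range(2, 11)}
BRANCHED = {
    "isobutane": "CC(C)C",
    "neopentane": "CC(C)(C)C",
    "isopentane": "CCC(C)C",
    "3-methylpentane": "CCC(C)CC",
    "2,3-dimethylbutane": "CC(C)C(C)C",
    "2,2,3-trimethylbutane": "CC(C)(C)C(C)C",
}
CYCLOALKANES = {f"cyclo_C{n}": "C1" + "C" * (n - 1) + "1" for n in range(3, 9)}
HETERO = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "pyridine": "c1ccncc1",
    "thiophene": "c1ccsc1",
    "phenol": "Oc1ccccc1",
    "toluene": "Cc1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "methylcyclobutane": "CC1CCC1",
}


@dataclass
class FixtureSet:
    named: dict[str, MolGraph] = field(default_factory=dict)
    fragments: dict[str, MolGraph] = field(default_factory=dict)
    random_graphs: list[MolGraph] = field(default_factory=list)

    def small(self, max_atoms: int = 12) -> dict[str, MolGraph]:
        return {k: g for k, g in self.named.items() if g.n_atoms <= max_atoms}


def random_molgraph(rng: np.random.Generator, n: int, extra_edges: int = 1) -> MolGraph:
    """Random connected carbon skeleton: a random tree plus up to
    ``extra_edges`` chords, degrees capped at 4."""
    edges: set[tuple[int, int]] = set()
    deg = [0] * n
    for v in range(1, n):
        candidates = [u for u in range(v) if deg[u] < 4]
        u = int(rng.choice(candidates))
        edges.add((u, v))
        deg[u] += 1
        deg[v] += 1
    for _ in range(extra_edges):
        pool = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if (u, v) not in edges and deg[u] < 4 and deg[v] < 4
        ]
        if not pool:
            break
        u, v = pool[int(rng.integers(len(pool)))]
        edges.add((u, v))
        deg[u] += 1
        deg[v] += 1
    atoms = [
        AtomNode(element=ELEMENTS["C"], h_count=4 - deg[v], delta=deg[v], delta_v=float(4 - (4 - deg[v])))
        for v in range(n)
    ]
    bonds = [(u, v, 1) for u, v in sorted(edges)]
    return MolGraph(atoms=atoms, bonds=bonds, id=f"rand{n}")


def make_fixtures(seed: int = 0, n_random: int = 10) -> FixtureSet:
    """Build the full fixture set, deterministic in ``seed``."""
    fs = FixtureSet()
    for name, smi in {**ALKANES, **BRANCHED, **CYCLOALKANES, **HETERO}.items():
        fs.named[name] = parse_smiles(smi, mol_id=name)
    spec = load_library_spec(packaged_library_path())
    for aid, subs in spec.lists.items():
        for s in subs:
            # fragment with the marker resolved to its anchor atom, as a
            # standalone molecule (marker -> CH3-terminated carbon)
            resolved = s.smiles.replace("[R]", "C" if s.anchor_element == "C" else f"[{s.anchor_element}H]")
            try:
                fs.fragments[f"{aid}/{s.code}"] = parse_smiles(resolved, mol_id=f"{aid}{s.code}")
            except Exception:  # noqa: BLE001 - fragments are probes, not assertions
                pass
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        n = int(rng.integers(4, 11))
        fs.random_graphs.append(random_molgraph(rng, n, extra_edges=int(rng.integers(0, 3))))
    return fs
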