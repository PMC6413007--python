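"""Combinatorial construction of molecule libraries from a base scaffold with
indexed anchor points and per-position substituent lists.

Anchor syntax
-------------
The scaffold carries indexed markers ``[R1]`` ... ``[Rk]``; substituent
fragments carry a single plain ``[R]``.  Under the default semantics the
marker in a substituent *is* the attachment atom (a carbon unless the
fragment declares another ``anchor_element``): benzyl is written
``[R]C1=CC=CC=C1`` with the marker as the benzylic CH2.  The alternative
placeholder semantics (marker removed, its neighbours bonded directly) is
available through :class:`~topoqsar.conventions.Conventions`.

Assembly is graph editing on RDKit molecules; emitted SMILES are canonical,
which renumbers ring closures with the lowest free digit (two-digit ``%nn``
escape above 9) so no digit is reused while open.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdkit import Chem

from .conventions import DEFAULT, Conventions
from .graph import MolGraph, from_rdkit

log = logging.getLogger(__name__)

MARKER_RE = re.compile(r"\[R([0-9]*)\]")


class AssemblyError(ValueError):
    """Raised when attaching a substituent produces an invalid molecule."""


@dataclass(frozen=True)
class SubstituentSpec:
    """One substituent: single-letter code, fragment SMILES with one [R]
    marker, free-text name, and the element placed at the anchor point."""

    code: str
    smiles: str
    name: str = ""
    anchor_element: str = "C"


@dataclass(frozen=True)
class ScaffoldSpec:
    """Base scaffold SMILES with k distinct indexed anchors [R1]..[Rk]."""

    smiles: str
    anchor_ids: tuple[str, ...]


@dataclass
class LibrarySpec:
    scaffold: ScaffoldSpec
    lists: dict[str, list[SubstituentSpec]]

    @property
    def size(self) -> int:
        n = 1
        for aid in self.scaffold.anchor_ids:
            n *= len(self.lists[aid])
        return n


@dataclass
class EnumeratedMolecule:
    """One assembled library member."""

    id_code: str
    smiles: str
    mol: Chem.Mol = field(repr=False)

    def graph(self) -> MolGraph:
        return from_rdkit(self.mol, mol_id=self.id_code)


@dataclass
class ValidationReport:
    smiles: str
    faults: list[str]

    @property
    def ok(self) -> bool:
        return not self.faults


def _to_mappable(smiles: str, index_required: bool) -> tuple[str, list[int]]:
    """Rewrite [R]/[Rk] markers as RDKit dummy atoms [*:k]; returns the
    rewritten SMILES and the marker indices found (0 for plain [R])."""
    found: list[int] = []

    def sub(m: re.Match) -> str:
        idx = int(m.group(1)) if m.group(1) else 0
        found.append(idx)
        return f"[*:{idx if idx else 99}]"

    return MARKER_RE.sub(sub, smiles), found


def validate_fragment(
    smiles: str,
    expect_marker: bool = True,
    conventions: Conventions | None = None,
) -> ValidationReport:
    """Check one substituent fragment; faults are data, not exceptions."""
    conv = conventions or DEFAULT
    faults: list[str] = []
    rewritten, markers = _to_mappable(smiles, index_required=False)
    if expect_marker and len(markers) == 0:
        faults.append("no attachment marker [R]")
    if len(markers) > 1:
        faults.append(f"{len(markers)} attachment markers (exactly one expected)")
    mol = Chem.MolFromSmiles(rewritten)
    if mol is None:
        faults.append(f"unparseable SMILES {smiles!r}")
        return ValidationReport(smiles, faults)
    if len(Chem.GetMolFrags(mol)) > 1:
        faults.append("fragment is disconnected")
    if markers and not conv.marker_is_atom:
        dummy = next(a for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if dummy.GetDegree() != 1:
            faults.append(
                "marker has %d neighbours; placeholder semantics need exactly 1"
                % dummy.GetDegree()
            )
    return ValidationReport(smiles, faults)


def validate_scaffold(spec: ScaffoldSpec) -> ValidationReport:
    rewritten, markers = _to_mappable(spec.smiles, index_required=True)
    faults: list[str] = []
    want = sorted(int(a[1:]) for a in spec.anchor_ids)
    if sorted(markers) != want:
        faults.append(f"anchor markers {sorted(markers)} != declared {want}")
    if Chem.MolFromSmiles(rewritten) is None:
        faults.append(f"unparseable scaffold SMILES {spec.smiles!r}")
    return ValidationReport(spec.smiles, faults)


def _parse_marked(smiles: str) -> Chem.Mol:
    rewritten, _ = _to_mappable(smiles, index_required=False)
    mol = Chem.MolFromSmiles(rewritten)
    if mol is None:
        raise AssemblyError(f"unparseable SMILES {smiles!r}")
    return mol


def attach(
    scaffold: ScaffoldSpec,
    assignment: dict[str, SubstituentSpec],
    conventions: Conventions | None = None,
    id_code: str | None = None,
) -> EnumeratedMolecule:
    """Assemble one molecule: substitute every anchor of the scaffold.

    Each scaffold anchor placeholder is replaced by its substituent's anchor
    atom (default semantics) or by a direct bond between the two marker
    neighbourhoods (placeholder semantics); attachment bonds are single.
    """
    conv = conventions or DEFAULT
    missing = [a for a in scaffold.anchor_ids if a not in assignment]
    if missing:
        raise AssemblyError(f"anchors {missing} not assigned")
    code = id_code or "".join(assignment[a].code for a in scaffold.anchor_ids)

    combined = _parse_marked(scaffold.smiles)
    frag_anchor_map: dict[int, int] = {}  # anchor index k -> map number used
    for aid in scaffold.anchor_ids:
        k = int(aid[1:])
        frag = _parse_marked(assignment[aid].smiles)
        # remap the fragment's plain marker (map 99) to 100+k to find it later
        for a in frag.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(100 + k)
        frag_anchor_map[k] = 100 + k
        combined = Chem.CombineMols(combined, frag)

    rw = Chem.RWMol(combined)

    def find(map_num: int) -> Chem.Atom:
        for a in rw.GetAtoms():
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == map_num:
                return a
        raise AssemblyError(f"marker with map {map_num} not found")

    for aid in scaffold.anchor_ids:
        k = int(aid[1:])
        sub = assignment[aid]
        scaf_dummy = find(k)
        frag_dummy = find(frag_anchor_map[k])
        scaf_neighbors = [n.GetIdx() for n in scaf_dummy.GetNeighbors()]
        if conv.marker_is_atom:
            # the fragment marker becomes a real atom bonded into the scaffold
            frag_dummy.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(sub.anchor_element))
            frag_dummy.SetAtomMapNum(0)
            frag_dummy.SetNoImplicit(False)
            target = frag_dummy.GetIdx()
        else:
            frag_neighbors = [n.GetIdx() for n in frag_dummy.GetNeighbors()]
            if len(frag_neighbors) != 1:
                raise AssemblyError(
                    f"anchor {aid}: fragment marker has {len(frag_neighbors)} "
                    "neighbours under placeholder semantics"
                )
            target = frag_neighbors[0]
        for n_idx in scaf_neighbors:
            rw.AddBond(n_idx, target, Chem.BondType.SINGLE)
        rw.RemoveAtom(scaf_dummy.GetIdx())
        if not conv.marker_is_atom:
            frag_dummy = find(frag_anchor_map[k])  # indices shifted
            rw.RemoveAtom(frag_dummy.GetIdx())

    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001 - RDKit raises several types
        raise AssemblyError(f"molecule {code}: invalid after assembly ({exc})") from exc
    if len(Chem.GetMolFrags(mol)) > 1:
        raise AssemblyError(f"molecule {code}: assembly left a disconnected graph")
    smiles = Chem.MolToSmiles(mol)
    return EnumeratedMolecule(id_code=code, smiles=smiles, mol=mol)


def enumerate_library(
    spec: LibrarySpec, conventions: Conventions | None = None
) -> list[EnumeratedMolecule]:
    """Cartesian product over the anchor substituent lists.

    Order is documented: first anchor varies slowest (anchor order major,
    list order minor); id codes concatenate the substituent letters in
    anchor order.
    """
    rep = validate_scaffold(spec.scaffold)
    if not rep.ok:
        raise AssemblyError(f"invalid scaffold: {rep.faults}")
    anchors = spec.scaffold.anchor_ids
    out: list[EnumeratedMolecule] = []
    for combo in itertools.product(*(spec.lists[a] for a in anchors)):
        assignment = dict(zip(anchors, combo))
        out.append(attach(spec.scaffold, assignment, conventions=conventions))
    return out


def write_smi(mols, path) -> None:
    """Write one 'SMILES whitespace id' line per molecule (UTF-8)."""
    mols = list(mols)
    if not mols:
        log.warning("writing empty .smi file to %s", path)
    with open(path, "w", encoding="utf-8") as fh:
        for m in mols:
            fh.write(f"{m.smiles} {m.id_code}\n")


def load_library_spec(path, apply_repairs: bool = False) -> LibrarySpec:
    """Read a library spec config (YAML): scaffold SMILES + anchor list +
    per-anchor substituent rows; optional 'repairs' section overriding
    individual fragments (keyed 'ANCHOR/CODE')."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    scaffold = ScaffoldSpec(
        smiles=data["scaffold"]["smiles"],
        anchor_ids=tuple(data["scaffold"]["anchors"]),
    )
    repairs = data.get("repairs", {}) if apply_repairs else {}
    lists: dict[str, list[SubstituentSpec]] = {}
    for aid in scaffold.anchor_ids:
        rows = []
        for row in data["substituents"][aid]:
            key = f"{aid}/{row['code']}"
            if key in repairs:
                row = {**row, **repairs[key]}
            rows.append(
                SubstituentSpec(
                    code=str(row["code"]),
                    smiles=row["smiles"],
                    name=row.get("name", ""),
                    anchor_element=row.get("anchor_element", "C"),
                )
            )
        if not rows:
            raise ValueError(f"anchor {aid} has an empty substituent list")
        lists[aid] = rows
    return LibrarySpec(scaffold=scaffold, lists=lists)


def packaged_library_path() -> Path:
    """Path of the packaged FPR dioxopiperazine library config."""
    return Path(__file__).parent / "data" / "fpr_library.yaml"
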