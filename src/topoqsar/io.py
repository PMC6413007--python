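"""File I/O: molecule readers (.smi, .mol, .sdf via RDKit), the .smi writer,
and the two-sheet descriptor table writer (spreadsheet or CSV twin files).

The .smi dialect is whitespace-separated "SMILES name" with '#' comments and
no header.  The descriptor table mirrors classic QSAR tooling: sheet one has
one row per processed molecule in a fixed column order, sheet two carries run
metadata (input, convention toggles, timestamp) plus the unprocessed
molecules with their fault reasons.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .conventions import DEFAULT, Conventions
from .graph import MolGraph, from_rdkit

FORMATS = ("smi", "mol", "sdf")


@dataclass
class MoleculeSet:
    molecules: list[MolGraph] = field(default_factory=list)
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (where, reason)


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        if fmt not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_molecules(path, fmt: str | None = None) -> MoleculeSet:
    """Read molecules from .smi / .mol / .sdf; per-record failures are
    collected in the rejects list (with line or record position), not raised."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    out = MoleculeSet()
    if fmt == "smi":
        for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"line{ln}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                out.rejects.append((f"line {ln}", f"invalid SMILES {smiles!r}"))
                continue
            try:
                out.molecules.append(from_rdkit(mol, mol_id=name))
            except Exception as exc:  # noqa: BLE001
                out.rejects.append((f"line {ln}", str(exc)))
    elif fmt == "mol":
        mol = Chem.MolFromMolFile(str(path))
        if mol is None:
            out.rejects.append((path.name, "invalid Molfile"))
        else:
            name = (mol.GetProp("_Name") or path.stem) if mol.HasProp("_Name") else path.stem
            out.molecules.append(from_rdkit(mol, mol_id=name or path.stem))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                out.rejects.append((f"record {i + 1}", "invalid SD record"))
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record{i + 1}"
            try:
                out.molecules.append(from_rdkit(mol, mol_id=name))
            except Exception as exc:  # noqa: BLE001
                out.rejects.append((f"record {i + 1}", str(exc)))
    return out


def write_descriptor_table(
    ids,
    vectors,
    rejects,
    path,
    fmt: str = "csv",
    conventions: Conventions | None = None,
    source: str = "",
    descriptor_order: list[str] | None = None,
) -> list[Path]:
    """Write the two-sheet descriptor table.

    ``fmt="xlsx"`` writes one spreadsheet with sheets "descriptors" and
    "metadata"; ``fmt="csv"`` (the format of record for tests) writes two
    files, ``<path>`` and ``<path stem>_metadata.csv``.  Column order is
    fixed: id first, then descriptors in ``descriptor_order`` (default: the
    sorted union of all keys).  Returns the written paths.
    """
    conv = conventions or DEFAULT
    path = Path(path)
    vectors = list(vectors)
    ids = list(ids)
    if len(ids) != len(vectors):
        raise ValueError("ids and vectors length mismatch")
    if descriptor_order is None:
        seen: dict[str, None] = {}
        for v in vectors:
            for k in v:
                seen.setdefault(k)
        descriptor_order = list(seen)
    rows = [{"id": i, **{k: v.get(k) for k in descriptor_order}} for i, v in zip(ids, vectors)]
    df = pd.DataFrame(rows, columns=["id"] + descriptor_order)

    meta_rows = [("input", source), ("written", datetime.datetime.now().isoformat(timespec="seconds"))]
    meta_rows += [(f"convention:{k}", v) for k, v in conv.describe().items()]
    meta_rows += [("n_processed", str(len(ids))), ("n_unprocessed", str(len(rejects)))]
    meta_rows += [(f"unprocessed:{where}", reason) for where, reason in rejects]
    meta = pd.DataFrame(meta_rows, columns=["key", "value"])

    if fmt == "xlsx":
        with pd.ExcelWriter(path) as xl:
            df.to_excel(xl, sheet_name="descriptors", index=False)
            meta.to_excel(xl, sheet_name="metadata", index=False)
        return [path]
    if fmt == "csv":
        meta_path = path.with_name(path.stem + "_metadata.csv")
        df.to_csv(path, index=False)
        meta.to_csv(meta_path, index=False)
        return [path, meta_path]
    raise ValueError("fmt must be 'csv' or 'xlsx'")
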