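"""Combinatorial library construction: fragment validation, attachment under
both marker semantics, enumeration, and .smi output."""

import itertools

import pytest
from rdkit import Chem

from topoqsar.conventions import Conventions
from topoqsar.graph import parse_smiles
from topoqsar.library import (
    AssemblyError,
    LibrarySpec,
    ScaffoldSpec,
    SubstituentSpec,
    attach,
    enumerate_library,
    load_library_spec,
    packaged_library_path,
    validate_fragment,
    validate_scaffold,
    write_smi,
)

PLACEHOLDER = Conventions(marker_is_atom=False)


class TestValidateFragment:
    def test_benzyl_accepted(self):
        assert validate_fragment("[R]C1=CC=CC=C1").ok

    def test_ring_marker_accepted_as_atom(self):
        # the marker participates in the ring closure: valid when the marker
        # is itself an atom
        assert validate_fragment("[R]1=CC=CC=C1").ok

    def test_missing_marker_fault(self):
        rep = validate_fragment("CCC", expect_marker=True)
        assert not rep.ok and "no attachment marker" in rep.faults[0]

    def test_duplicate_marker_fault(self):
        rep = validate_fragment("[R]C[R]")
        assert any("markers" in f for f in rep.faults)

    def test_unparseable_fault(self):
        rep = validate_fragment("[R]C1CC")
        assert any("unparseable" in f for f in rep.faults)

    def test_multi_neighbour_marker_fault_under_placeholder_semantics(self):
        # isopropyl as printed: fine when the marker is an atom, ambiguous
        # when it is a removable placeholder
        assert validate_fragment("[R](C)(C)").ok
        rep = validate_fragment("[R](C)(C)", conventions=PLACEHOLDER)
        assert any("neighbours" in f for f in rep.faults)

    def test_scaffold_anchor_bookkeeping(self):
        assert validate_scaffold(ScaffoldSpec("[R1]C[R2]", ("R1", "R2"))).ok
        assert not validate_scaffold(ScaffoldSpec("[R1]C", ("R1", "R2"))).ok


class TestAttach:
    benzyl = SubstituentSpec("A", "[R]C1=CC=CC=C1", "benzyl")

    def test_marker_as_atom_contributes_methylene(self):
        m = attach(ScaffoldSpec("C1CC1[R1]", ("R1",)), {"R1": self.benzyl})
        assert m.smiles == Chem.CanonSmiles("C1CC1Cc1ccccc1")

    def test_placeholder_semantics_direct_bond(self):
        m = attach(
            ScaffoldSpec("C1CC1[R1]", ("R1",)), {"R1": self.benzyl}, conventions=PLACEHOLDER
        )
        assert m.smiles == Chem.CanonSmiles("C1CC1c1ccccc1")

    def test_two_anchor_propane(self):
        me = SubstituentSpec("M", "[R]", "methyl")
        m = attach(ScaffoldSpec("[R1]C[R2]", ("R1", "R2")), {"R1": me, "R2": me})
        assert m.smiles == Chem.CanonSmiles("CCC")

    def test_anchor_element_override(self):
        sphenyl = SubstituentSpec("E", "[R]C1=CC=CC=C1", "S-phenyl", anchor_element="S")
        m = attach(ScaffoldSpec("C[R1]", ("R1",)), {"R1": sphenyl})
        assert m.smiles == Chem.CanonSmiles("CSc1ccccc1")

    def test_missing_assignment_error(self):
        with pytest.raises(AssemblyError):
            attach(ScaffoldSpec("[R1]C[R2]", ("R1", "R2")), {"R1": self.benzyl})

    def test_atom_count_bookkeeping(self):
        # product heavy atoms = scaffold heavy atoms + sum of fragment heavy
        # atoms (markers count as atoms under the default semantics)
        spec = load_library_spec(packaged_library_path())
        scaffold_atoms = Chem.MolFromSmiles(
            spec.scaffold.smiles.replace("[R1]", "[*:1]").replace("[R2]", "[*:2]")
            .replace("[R3]", "[*:3]").replace("[R4]", "[*:4]")
        ).GetNumAtoms() - 4
        for combo in itertools.islice(
            itertools.product(*(spec.lists[a] for a in spec.scaffold.anchor_ids)), 0, 40, 7
        ):
            assignment = dict(zip(spec.scaffold.anchor_ids, combo))
            frag_atoms = sum(
                Chem.MolFromSmiles(s.smiles.replace("[R]", "[*:1]")).GetNumAtoms()
                for s in combo
            )
            m = attach(spec.scaffold, assignment)
            assert m.mol.GetNumAtoms() == scaffold_atoms + frag_atoms


class TestEnumerate:
    def _toy_spec(self):
        scaffold = ScaffoldSpec("[R1]C[R2]", ("R1", "R2"))
        lists = {
            "R1": [SubstituentSpec("A", "[R]"), SubstituentSpec("B", "[R]C")],
            "R2": [
                SubstituentSpec("A", "[R]"),
                SubstituentSpec("B", "[R]O"),
                SubstituentSpec("C", "[R]C1=CC=CC=C1"),
            ],
        }
        return LibrarySpec(scaffold=scaffold, lists=lists)

    def test_cartesian_product_count_and_order(self):
        mols = enumerate_library(self._toy_spec())
        assert len(mols) == 6
        # anchor order major, list order minor
        assert [m.id_code for m in mols] == ["AA", "AB", "AC", "BA", "BB", "BC"]

    def test_single_assignment_matches_attach(self):
        spec = self._toy_spec()
        spec.lists = {k: v[:1] for k, v in spec.lists.items()}
        mols = enumerate_library(spec)
        direct = attach(spec.scaffold, {"R1": spec.lists["R1"][0], "R2": spec.lists["R2"][0]})
        assert len(mols) == 1 and mols[0].smiles == direct.smiles

    def test_emitted_smiles_reparse_canonically(self):
        for m in enumerate_library(self._toy_spec()):
            assert Chem.CanonSmiles(m.smiles) == m.smiles
            parse_smiles(m.smiles)  # must be a valid connected molecule

    def test_packaged_spec_shape(self):
        spec = load_library_spec(packaged_library_path())
        sizes = [len(spec.lists[a]) for a in spec.scaffold.anchor_ids]
        assert sizes == [5, 8, 9, 17]
        assert spec.size == 6120

    def test_repair_table_overrides_fragment(self):
        plain = load_library_spec(packaged_library_path())
        repaired = load_library_spec(packaged_library_path(), apply_repairs=True)
        e_plain = next(s for s in plain.lists["R3"] if s.code == "E")
        e_rep = next(s for s in repaired.lists["R3"] if s.code == "E")
        assert e_plain.anchor_element == "C"
        assert e_rep.anchor_element == "S"


class TestWriteSmi:
    def test_round_trip(self, tmp_path):
        mols = enumerate_library(TestEnumerate()._toy_spec())
        path = tmp_path / "lib.smi"
        write_smi(mols, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 6
        smiles, code = lines[0].split()
        assert code == "AA" and Chem.MolFromSmiles(smiles) is not None
        ids = [ln.split()[1] for ln in lines]
        assert len(set(ids)) == len(ids)

    def test_empty_list_writes_empty_file(self, tmp_path):
        path = tmp_path / "empty.smi"
        write_smi([], path)
        assert path.read_text() == ""
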