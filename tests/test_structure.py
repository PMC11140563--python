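"""Structure model: PDB round-trips, parameter tables, domain maps."""
import numpy as np
import pytest

import abspatial as ab
from abspatial.structure import (
    ChargeTable, FORMAL_CHARGE, ONE_TO_THREE, PdbParseError, ParameterError,
    DomainError, RadiusTable,
)


# ---------------------------------------------------------------------------
# PDB parsing and writing
# ---------------------------------------------------------------------------

class TestPdbRoundTrip:
    def test_multi_model_snapshot_count(self, catalogue, tmp_path):
        st, _ = ab.make_toy_structure(catalogue["pair_5A_x3"],
                                      pdb_path=tmp_path / "t.pdb")
        parsed = ab.parse_pdb(tmp_path / "t.pdb")
        assert len(parsed.snapshots) == 3

    def test_single_model_single_snapshot(self, catalogue, tmp_path):
        ab.make_toy_structure(catalogue["quartet"], pdb_path=tmp_path / "q.pdb")
        parsed = ab.parse_pdb(tmp_path / "q.pdb")
        assert len(parsed.snapshots) == 1
        assert parsed.snapshots[0].n_atoms == 4

    def test_coordinates_serials_names_preserved(self, catalogue, tmp_path):
        st, _ = ab.make_toy_structure(catalogue["pair_5A_x3"],
                                      pdb_path=tmp_path / "t.pdb")
        parsed = ab.parse_pdb(tmp_path / "t.pdb")
        for orig, back in zip(st.snapshots, parsed.snapshots):
            a0 = orig.atoms
            a1 = back.atoms
            assert [a.serial for a in a0] == [a.serial for a in a1]
            assert [a.name for a in a0] == [a.name for a in a1]
            assert np.allclose(orig.coords(), back.coords(), atol=5e-4)

    def test_second_write_parse_cycle_is_stable(self, catalogue, tmp_path):
        st, _ = ab.make_toy_structure(catalogue["quartet"],
                                      pdb_path=tmp_path / "a.pdb")
        once = ab.parse_pdb(tmp_path / "a.pdb")
        ab.write_pdb(once, tmp_path / "b.pdb")
        twice = ab.parse_pdb(tmp_path / "b.pdb")
        assert np.allclose(once.snapshots[0].coords(), twice.snapshots[0].coords())

    def test_inconsistent_model_atom_sets_rejected(self, tmp_path):
        lines = [
            "MODEL        1",
            "ATOM      1  CB  LEU H  30       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CB  SER L  50       5.000   0.000   0.000  1.00  0.00           C",
            "ENDMDL",
            "MODEL        2",
            "ATOM      1  CB  LEU H  30       0.000   0.000   0.000  1.00  0.00           C",
            "ENDMDL",
            "END",
        ]
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PdbParseError, match="snapshot 1"):
            ab.parse_pdb(path)

    def test_malformed_atom_line_reports_line_number(self, tmp_path):
        path = tmp_path / "trunc.pdb"
        path.write_text(
            "ATOM      1  CB  LEU H  30       0.000   0.000\n"
        )
        with pytest.raises(PdbParseError, match="line 1"):
            ab.parse_pdb(path)

    def test_undeclared_chain_rejected(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(
            "ATOM      1  CB  LEU X  30       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(PdbParseError, match="chain 'X'"):
            ab.parse_pdb(path)


# ---------------------------------------------------------------------------
# Charge / radius assignment
# ---------------------------------------------------------------------------

def _one_residue_structure(resname: str) -> ab.FvStructure:
    """A structure holding one full residue (plus a remote partner chain)."""
    table = ChargeTable.bundled()
    atoms = sorted(table.expected_atoms(resname))
    res = ab.Residue(chain_id=ab.HEAVY, number=40, icode="",
                     aa=[k for k, v in ONE_TO_THREE.items() if v == resname][0])
    for i, name in enumerate(atoms):
        element = name[0] if name[0] in "CNOS" else "C"
        res.atoms.append(ab.Atom(serial=i + 1, name=name, element=element,
                                 coords=np.array([float(i), 0.0, 0.0]),
                                 is_side_chain=name not in ("N", "CA", "C", "O")))
    partner = ab.Residue(chain_id=ab.LIGHT, number=40, icode="", aa="G")
    for j, name in enumerate(sorted(table.expected_atoms("GLY"))):
        partner.atoms.append(ab.Atom(
            serial=90 + j, name=name, element=name[0],
            coords=np.array([50.0 + j, 0.0, 0.0]),
            is_side_chain=False))
    snap = ab.FvSnapshot(residues=[res, partner])
    return ab.FvStructure(name=resname, snapshots=[snap])


class TestChargeAssignment:
    @pytest.mark.parametrize("resname", sorted(FORMAL_CHARGE))
    def test_residue_charge_sums_equal_formal_charge(self, resname):
        st = ab.assign_parameters(_one_residue_structure(resname))
        res = st.snapshots[0].residues[0]
        total = sum(a.charge for a in res.atoms)
        assert total == pytest.approx(FORMAL_CHARGE[resname], abs=1e-6)

    def test_protonated_histidine_sums_to_plus_one(self):
        st = ab.assign_parameters(_one_residue_structure("HIS"))
        total = sum(a.charge for a in st.snapshots[0].residues[0].atoms)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_alanine_is_neutral(self):
        st = ab.assign_parameters(_one_residue_structure("ALA"))
        total = sum(a.charge for a in st.snapshots[0].residues[0].atoms)
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_snapshot_total_matches_sequence_formal_charge(self):
        for resname in ("LYS", "ASP", "HIS"):
            st = ab.assign_parameters(_one_residue_structure(resname))
            snap = st.snapshots[0]
            assert snap.charges().sum() == pytest.approx(
                ab.sequence_formal_charge(snap), abs=1e-6)

    def test_unknown_atom_strict_mode_errors_with_context(self):
        st = _one_residue_structure("ALA")
        st.snapshots[0].residues[0].atoms[0].name = "XX1"
        with pytest.raises(ParameterError, match="XX1"):
            ab.assign_parameters(st, mode="strict")

    def test_permissive_mode_skips_unknown_atoms(self):
        st = _one_residue_structure("ALA")
        st.snapshots[0].residues[0].atoms[0].name = "XX1"
        ab.assign_parameters(st, mode="permissive")
        assert st.snapshots[0].residues[0].atoms[0].charge == 0.0
        assert st.snapshots[0].residues[0].atoms[0].radius > 0

    def test_radii_follow_element_table(self):
        st = ab.assign_parameters(_one_residue_structure("CYS"))
        radii = RadiusTable.bundled()
        for atom in st.snapshots[0].residues[0].atoms:
            assert atom.radius == radii.radius(atom.element)


# ---------------------------------------------------------------------------
# Domain assignment
# ---------------------------------------------------------------------------

class TestDomainMap:
    def test_cdr_residue_gets_cdr_regions(self, toy_structures):
        st, _ = toy_structures["pair_5A"]
        dm = ab.assign_domains(st.snapshots[0])
        assert dm.regions_of((ab.HEAVY, 30, "")) == {"CDRH1", "CDR", "Hv", "Fv"}
        assert dm.regions_of((ab.LIGHT, 50, "")) == {"CDRL2", "CDR", "Lv", "Fv"}

    def test_framework_residue_only_chain_regions(self, toy_structures):
        st, _ = toy_structures["quartet"]
        dm = ab.assign_domains(st.snapshots[0])
        assert dm.regions_of((ab.HEAVY, 70, "")) == {"Hv", "Fv"}
        assert dm.regions_of((ab.LIGHT, 40, "")) == {"Lv", "Fv"}

    def test_partition_invariants(self, toy_structures):
        from conftest import random_cluster
        snap = random_cluster(16, seed=5)
        dm = ab.assign_domains(snap)
        for res in snap.residues:
            regions = dm.regions_of(res.key)
            chain_region = "Hv" if res.chain_id == ab.HEAVY else "Lv"
            assert {"Fv", chain_region} <= regions
            cdrs = regions & set(ab.CDR_REGIONS)
            # in CDR iff in exactly one CDRx
            assert ("CDR" in regions) == (len(cdrs) == 1)
            assert len(cdrs) <= 1

    def test_out_of_range_number_rejected(self):
        res = ab.Residue(chain_id=ab.HEAVY, number=150, icode="", aa="A")
        res.atoms.append(ab.Atom(serial=1, name="CB", element="C",
                                 coords=np.zeros(3), radius=1.7))
        snap = ab.FvSnapshot(residues=[res])
        with pytest.raises(DomainError, match="150"):
            ab.assign_domains(snap)

    def test_insertion_coded_residue_follows_numeric_parent(self):
        res = ab.Residue(chain_id=ab.HEAVY, number=100, icode="A", aa="A")
        res.atoms.append(ab.Atom(serial=1, name="CB", element="C",
                                 coords=np.zeros(3), radius=1.7))
        snap = ab.FvSnapshot(residues=[res])
        dm = ab.assign_domains(snap)
        assert "CDRH3" in dm.regions_of((ab.HEAVY, 100, "A"))
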