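import numpy as np
import pytest

from toplap.fixtures import make_peptide_pdb, peptide_pdb_text
from toplap.structure_io import (
    HEAVY,
    MutationSpec,
    classify_region,
    compute_rasa,
    label_site,
    parse_mutation,
    parse_pdb,
    read_rasa_table,
    select_cloud,
)


def write_pdb(tmp_path, lines, name="test.pdb"):
    path = tmp_path / name
    path.write_text("".join(lines))
    return path


def atom_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ",
              element=None):
    element = element if element is not None else name[0]
    padded = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {padded:<4}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


class TestParsePdb:
    def test_single_atom(self, tmp_path):
        path = write_pdb(tmp_path, [atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0)])
        atoms = parse_pdb(path)
        assert len(atoms) == 1
        assert atoms[0].element == "C"
        assert np.allclose(atoms[0].coordinates, 0.0)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = write_pdb(
            tmp_path,
            [
                atom_line(1, "CA", "ALA", "A", 1, 1, 0, 0, occ=0.6, altloc="A"),
                atom_line(2, "CA", "ALA", "A", 1, 2, 0, 0, occ=0.4, altloc="B"),
            ],
        )
        atoms = parse_pdb(path)
        assert len(atoms) == 1
        assert atoms[0].coordinates[0] == pytest.approx(1.0)

    def test_altloc_tie_keeps_first(self, tmp_path):
        path = write_pdb(
            tmp_path,
            [
                atom_line(1, "CA", "ALA", "A", 1, 1, 0, 0, occ=0.5, altloc="A"),
                atom_line(2, "CA", "ALA", "A", 1, 2, 0, 0, occ=0.5, altloc="B"),
            ],
        )
        atoms = parse_pdb(path)
        assert atoms[0].coordinates[0] == pytest.approx(1.0)

    def test_hetatm_and_hydrogens_excluded(self, tmp_path):
        lines = [
            atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0),
            atom_line(2, "H", "ALA", "A", 1, 0, 1, 0, element="H"),
            "HETATM    3  O   HOH A   2       0.000   0.000   9.000  1.00  0.00           O\n",
        ]
        atoms = parse_pdb(write_pdb(tmp_path, lines))
        assert len(atoms) == 1

    def test_first_model_only(self, tmp_path):
        lines = (
            ["MODEL        1\n", atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0), "ENDMDL\n"]
            + ["MODEL        2\n", atom_line(1, "CA", "ALA", "A", 1, 5, 0, 0), "ENDMDL\n"]
        )
        atoms = parse_pdb(write_pdb(tmp_path, lines))
        assert len(atoms) == 1
        assert atoms[0].coordinates[0] == 0.0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_pdb(tmp_path / "nope.pdb")

    def test_no_atom_records(self, tmp_path):
        with pytest.raises(ValueError):
            parse_pdb(write_pdb(tmp_path, ["REMARK nothing here\n"]))

    def test_element_fallback_from_atom_name(self, tmp_path):
        path = write_pdb(tmp_path, [atom_line(1, "OG", "SER", "A", 1, 0, 0, 0, element="")])
        atoms = parse_pdb(path)
        assert atoms[0].element == "O"

    def test_fixture_round_trip(self, tmp_path):
        wild, _, _ = peptide_pdb_text(6, 3, seed=4)
        n_written = wild.count("ATOM")
        path = tmp_path / "w.pdb"
        path.write_text(wild)
        atoms = parse_pdb(path)
        assert len(atoms) == n_written
        # coordinates survive to PDB precision (3 decimals)
        first = wild.splitlines()[0]
        assert atoms[0].coordinates[0] == pytest.approx(float(first[30:38]), abs=5e-4)


class TestMutationSpec:
    def test_parse_compact_form(self):
        spec = parse_mutation("A:I283W")
        assert spec == MutationSpec("A", 283, "I", "W")

    def test_round_trip_str(self):
        assert str(parse_mutation("B:N3D")) == "B:N3D"

    def test_same_aa_rejected(self):
        with pytest.raises(ValueError):
            MutationSpec("A", 1, "I", "I")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_mutation("not-a-mutation")


class TestLabelSite:
    def test_partition(self, tmp_path):
        _, _, spec = make_peptide_pdb(6, 3, seed=1, out_dir=tmp_path)
        atoms = parse_pdb(next(tmp_path.glob("*_wild.pdb")))
        cloud = label_site(atoms, spec)
        assert cloud.count("SITE") + cloud.count("ENV") == len(atoms)
        assert cloud.count("SITE") > 0

    def test_site_count_matches_residue(self, tmp_path):
        wild_path, _, spec = make_peptide_pdb(6, 3, seed=1, out_dir=tmp_path)
        atoms = parse_pdb(wild_path)
        expected = sum(1 for a in atoms if a.residue_id[1] == spec.residue_number)
        cloud = label_site(atoms, spec)
        assert cloud.count("SITE") == expected

    def test_two_residue_case(self, tmp_path):
        lines = [
            atom_line(1, "CA", "ILE", "A", 1, 0, 0, 0),
            atom_line(2, "CA", "GLY", "A", 2, 4, 0, 0),
        ]
        atoms = parse_pdb(write_pdb(tmp_path, lines))
        cloud = label_site(atoms, MutationSpec("A", 1, "I", "W"))
        assert cloud.location == ["SITE", "ENV"]

    def test_wrong_wild_aa_is_error(self, tmp_path):
        lines = [atom_line(1, "CA", "TRP", "A", 1, 0, 0, 0),
                 atom_line(2, "CA", "GLY", "A", 2, 4, 0, 0)]
        atoms = parse_pdb(write_pdb(tmp_path, lines))
        with pytest.raises(ValueError, match="expected ILE"):
            label_site(atoms, MutationSpec("A", 1, "I", "W"))

    def test_absent_residue_is_error(self, tmp_path):
        atoms = parse_pdb(write_pdb(tmp_path, [atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0)]))
        with pytest.raises(ValueError, match="no residue"):
            label_site(atoms, MutationSpec("A", 99, "A", "G"))


class TestSelectCloud:
    def build_cloud(self, tmp_path):
        lines = [
            atom_line(1, "CA", "ILE", "A", 1, 0, 0, 0),
            atom_line(2, "N", "ILE", "A", 1, 1, 0, 0),
            atom_line(3, "O", "GLY", "A", 2, 5, 0, 0),
            atom_line(4, "CA", "GLY", "A", 2, 20, 0, 0),
        ]
        atoms = parse_pdb(write_pdb(tmp_path, lines))
        return label_site(atoms, MutationSpec("A", 1, "I", "W"))

    def test_basic_selection(self, tmp_path):
        cloud = self.build_cloud(tmp_path)
        sub = select_cloud(cloud, "C", "O", neighborhood_radius=None)
        assert len(sub) == 2
        assert sub.elements == ["C", "O"]

    def test_empty_env_side(self, tmp_path):
        cloud = self.build_cloud(tmp_path)
        sub = select_cloud(cloud, "N", "N", neighborhood_radius=None)
        assert len(sub) == 1
        assert sub.location == ["SITE"]

    def test_radius_drops_far_atoms(self, tmp_path):
        cloud = self.build_cloud(tmp_path)
        sub = select_cloud(cloud, "C", "C", neighborhood_radius=12.0)
        assert all(a.residue_id[1] == 1 or a.name == "O" for a in sub.atoms)
        far = select_cloud(cloud, "C", "C", neighborhood_radius=None)
        assert len(far) == len(sub) + 1  # the 20 A carbon survives only unrestricted

    def test_heavy_includes_sulfur(self, tmp_path):
        lines = [
            atom_line(1, "CA", "CYS", "A", 1, 0, 0, 0),
            atom_line(2, "SG", "CYS", "A", 1, 1, 0, 0, element="S"),
            atom_line(3, "CA", "GLY", "A", 2, 4, 0, 0),
        ]
        atoms = parse_pdb(write_pdb(tmp_path, lines))
        cloud = label_site(atoms, MutationSpec("A", 1, "C", "S"))
        sub = select_cloud(cloud, HEAVY, HEAVY)
        assert len(sub) == 3
        single = select_cloud(cloud, "C", "C")
        assert len(single) == 2  # sulfur excluded from single-element pairs

    def test_idempotent(self, tmp_path):
        cloud = self.build_cloud(tmp_path)
        once = select_cloud(cloud, "C", "O", 12.0)
        twice = select_cloud(once, "C", "O", 12.0)
        assert [a.serial for a in once.atoms] == [a.serial for a in twice.atoms]

    def test_monotone_in_radius(self, tmp_path):
        cloud = self.build_cloud(tmp_path)
        sizes = [len(select_cloud(cloud, "C", "C", r)) for r in (1.0, 5.0, 12.0, 25.0)]
        assert sizes == sorted(sizes)


class TestClassifyRegion:
    def test_interior(self):
        assert classify_region(0.10) == "interior"

    def test_boundary_is_surface(self):
        assert classify_region(0.25) == "surface"

    def test_surface(self):
        assert classify_region(0.90) == "surface"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_region(1.5)


class TestRasa:
    def test_read_table(self, tmp_path):
        path = tmp_path / "rasa.tsv"
        path.write_text("A\t1\t0.12\nA\t2\t0.55\n")
        table = read_rasa_table(path)
        assert table[("A", 1)] == pytest.approx(0.12)
        assert classify_region(table[("A", 2)]) == "surface"

    def test_compute_rasa_fractions(self, tmp_path):
        wild_path, _, _ = make_peptide_pdb(8, 4, seed=2, out_dir=tmp_path)
        rasa = compute_rasa(wild_path)
        assert len(rasa) == 8
        assert all(0.0 <= v <= 1.0 for v in rasa.values())
        # terminal residues of an extended peptide are more exposed than the middle
        assert rasa[("A", 1)] > rasa[("A", 4)]
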