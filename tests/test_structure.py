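"""Structure container, PDB I/O, geometry operations."""

import numpy as np
import pytest

from mutsmith.structure import (
    Atom,
    MolecularStructure,
    MutationSpec,
    NumberingMap,
    Residue,
    hbond_geometry,
    interchain_clashes,
    place_polar_hydrogens,
    read_pdb,
    select_biological_dimer,
    tripeptide_segment,
    truncate_range,
    write_pdb,
)
from mutsmith.synthetic import toy_structure

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA ASER A   1      11.458  10.000  10.000  0.40  0.00           C
ATOM      3  CA BSER A   1      11.500  10.100  10.000  0.60  0.00           C
ATOM      4  C   SER A   1      12.000  11.400  10.000  1.00  0.00           C
END
"""


def single_atom(name, element, xyz, radius=1.7, charge=0.0):
    return Atom(name, element, np.asarray(xyz, float), radius, charge)


class TestPdbIO:
    def test_roundtrip_preserves_atoms(self, helix8, tmp_path):
        path = tmp_path / "helix.pdb"
        write_pdb(helix8, path)
        back = read_pdb(path)
        assert back.n_atoms == helix8.n_atoms
        assert np.allclose(back.coordinates(), helix8.coordinates(), atol=1e-3)
        names = [a.name for _, _, a in helix8.atoms()]
        assert [a.name for _, _, a in back.atoms()] == names

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        st = read_pdb(path)
        res = st.chains["A"][0]
        ca = res.atom("CA")
        assert np.allclose(ca.coords, [11.5, 10.1, 10.0], atol=1e-3)
        assert sum(1 for a in res.atoms if a.name == "CA") == 1

    def test_invariants(self):
        with pytest.raises(ValueError):
            Atom("X", "C", [np.nan, 0, 0], 1.7)
        with pytest.raises(ValueError):
            Atom("X", "C", [0, 0, 0], -1.0)


class TestDimerSelection:
    def test_distant_chains_no_clashes(self):
        a = Residue("GLY", 1, atoms=[single_atom("CA", "C", [0, 0, 0])])
        b = Residue("GLY", 1, atoms=[single_atom("CA", "C", [100, 0, 0])])
        st = MolecularStructure(chains={"C": [a], "D": [b]})
        _, report = select_biological_dimer(st, ("C", "D"))
        assert report == []

    def test_overlapping_pairs_reported_exactly(self):
        # two atom pairs overlapping by ~1 A, one clean pair
        c_res = Residue("GLY", 1, atoms=[
            single_atom("A1", "C", [0, 0, 0]),
            single_atom("A2", "C", [0, 5, 0]),
            single_atom("A3", "C", [0, 10, 0]),
        ])
        d_res = Residue("GLY", 1, atoms=[
            single_atom("B1", "C", [2.4, 0, 0]),
            single_atom("B2", "C", [2.4, 5, 0]),
            single_atom("B3", "C", [20, 10, 0]),
        ])
        st = MolecularStructure(chains={"C": [c_res], "D": [d_res]})
        clashes = interchain_clashes(st, "C", "D")
        named = {(a[2], b[2]) for a, b, _ in clashes}
        assert named == {("A1", "B1"), ("A2", "B2")}
        # oracle: full O(n^2) scan
        for a, b, dist in clashes:
            assert dist < 1.7 + 1.7 - 0.4

    def test_clashing_vs_clean_pair(self):
        clean = toy_structure("two_domain_dimer", cleft=12.0, n_residues=4)
        tight = toy_structure("two_domain_dimer", cleft=1.5, n_residues=4)
        assert interchain_clashes(clean, "C", "D") == []
        assert len(interchain_clashes(tight, "C", "D")) > 0

    def test_missing_chain(self, helix8):
        with pytest.raises(KeyError):
            select_biological_dimer(helix8, ("A", "Z"))


class TestNumbering:
    def test_published_offset(self):
        nm = NumberingMap(offset=15)
        assert nm.to_sequence(165) == 180
        assert nm.to_sequence(206) == 221
        assert nm.to_crystal(180) == 165

    def test_round_trip_identity(self):
        nm = NumberingMap(offset=15, valid_range=(1, 400))
        for site in (1, 165, 178, 366):
            assert nm.to_crystal(nm.to_sequence(site)) == site

    def test_range_enforced(self):
        nm = NumberingMap(offset=15, valid_range=(100, 200))
        with pytest.raises(ValueError):
            nm.to_sequence(50)


class TestTruncation:
    @staticmethod
    def chain(numbers):
        return [Residue("GLY", n, atoms=[single_atom("CA", "C", [n * 3.8, 0, 0])]) for n in numbers]

    def test_closed_range_removed(self):
        st = MolecularStructure(chains={"A": self.chain(range(1, 121))})
        out = truncate_range(st, (2, 109))
        numbers = [r.number for r in out.chains["A"]]
        assert numbers == [1] + list(range(110, 121))
        assert len(numbers) == 12

    def test_no_residues_in_range_unchanged(self):
        st = MolecularStructure(chains={"A": self.chain(range(200, 210))})
        out = truncate_range(st, (2, 109))
        assert [r.number for r in out.chains["A"]] == list(range(200, 210))

    def test_input_not_mutated(self):
        st = MolecularStructure(chains={"A": self.chain(range(1, 20))})
        truncate_range(st, (2, 10))
        assert len(st.chains["A"]) == 19


class TestTripeptide:
    def test_interior_three_residues(self, helix8):
        seg, at_terminus = tripeptide_segment(helix8, "A", 4)
        assert [r.number for r in seg.chains["A"]] == [3, 4, 5]
        assert not at_terminus

    def test_terminus_two_residues_flagged(self, helix8):
        seg, at_terminus = tripeptide_segment(helix8, "A", 1)
        assert [r.number for r in seg.chains["A"]] == [1, 2]
        assert at_terminus

    def test_coordinates_identical_to_parent(self, helix8):
        seg, _ = tripeptide_segment(helix8, "A", 4)
        for res in seg.chains["A"]:
            parent = helix8.residue("A", res.number)
            for a_seg, a_par in zip(res.atoms, parent.atoms):
                assert np.array_equal(a_seg.coords, a_par.coords)


class TestHydrogenBonds:
    @staticmethod
    def collinear_case():
        donor = Residue("THR", 178, atoms=[
            single_atom("OG1", "O", [0.0, 0.0, 0.0], 1.52, -0.4),
            single_atom("HG1", "H", [0.96, 0.0, 0.0], 1.10, 0.4),
        ])
        acceptor = Residue("ASP", 201, atoms=[
            single_atom("OD2", "O", [0.96 + 1.8, 0.0, 0.0], 1.52, -0.5),
        ])
        return MolecularStructure(chains={"C": [donor, acceptor]})

    def test_collinear_geometry(self):
        st = self.collinear_case()
        geo = hbond_geometry(st, ("C", 178, "OG1"), ("C", 178, "HG1"), ("C", 201, "OD2"))
        assert geo["distance"] == pytest.approx(1.8, abs=1e-9)
        assert geo["angle"] == pytest.approx(180.0, abs=1e-6)
        assert geo["bonded"]

    def test_distant_pair_not_bonded(self):
        st = self.collinear_case()
        st.residue("C", 201).atom("OD2").coords = np.array([10.0, 0.0, 0.0])
        geo = hbond_geometry(st, ("C", 178, "OG1"), ("C", 178, "HG1"), ("C", 201, "OD2"))
        assert geo["distance"] > 3.5 and not geo["bonded"]

    def test_hydroxyl_hydrogen_oriented_toward_acceptor(self):
        ser = Residue("SER", 10, atoms=[
            single_atom("CA", "C", [0.0, 0.0, 0.0]),
            single_atom("CB", "C", [1.53, 0.0, 0.0]),
            single_atom("OG", "O", [2.1, 1.3, 0.0], 1.52, -0.4),
        ])
        acceptor = Residue("ASP", 12, atoms=[single_atom("OD1", "O", [4.2, 2.3, 0.0], 1.52, -0.5)])
        st = MolecularStructure(chains={"A": [ser, acceptor]})
        with_h = place_polar_hydrogens(st)
        h = with_h.residue("A", 10).atom("HG")
        og = with_h.residue("A", 10).atom("OG").coords
        od1 = with_h.residue("A", 12).atom("OD1").coords
        assert np.linalg.norm(h.coords - og) == pytest.approx(0.96, abs=1e-6)
        # H must sit closer to the acceptor than the hydroxyl oxygen does
        assert np.linalg.norm(h.coords - od1) < np.linalg.norm(og - od1)


class TestMutationSpec:
    def test_parse(self):
        spec = MutationSpec.parse("C:165:S>D")
        assert (spec.chain, spec.site, spec.wt_aa, spec.mut_aa) == ("C", 165, "S", "D")
        assert spec.label == "S165D"

    def test_parse_errors(self):
        with pytest.raises(ValueError):
            MutationSpec.parse("C:165:SD")
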