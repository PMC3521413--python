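"""Structure parsing, accessibility, surface selection, labeling, curation."""

from __future__ import annotations

import numpy as np
import pytest

from betop.structure_io import (
    AsaTable, AtomRecord, ComplexRecord, StructureError, compute_asa, curate,
    label_epitope_residues, parse_structure, surface_atoms,
)

# minimal two-chain PDB: two alanines on chain A, one glycine on chain B,
# plus an altloc pair on atom 2 and a selenomethionine to be dropped
TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.500   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.400   0.100   0.000  0.60  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.300   1.600   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.300   2.600   0.000  1.00  0.00           C
HETATM    6  SE  MSE A   3       9.000   9.000   9.000  1.00  0.00          SE
ATOM      7  N   GLY B   1       0.000   0.000   5.000  1.00  0.00           N
ATOM      8  CA  GLY B   1       1.500   0.000   5.000  1.00  0.00           C
END
"""


def _atom(serial, xyz, aa="A", res=1, chain="A", radius=1.87, element="C"):
    return AtomRecord(serial=serial, atom_name="CA", element=element,
                      residue_key=(chain, res, ""), amino_acid=aa,
                      position=tuple(xyz), vdw_radius=radius)


class TestParseStructure:
    def test_roundtrip_two_chains(self):
        cx = parse_structure(TOY_PDB, ["A"], ["B"])
        assert {a.residue_key[0] for a in cx.atoms} == {"A", "B"}
        assert len(cx.antigen_atoms()) == 5  # MSE dropped, altloc deduped
        assert len(cx.antibody_atoms()) == 2

    def test_altloc_keeps_highest_occupancy(self):
        cx = parse_structure(TOY_PDB, ["A"], ["B"])
        ca1 = [a for a in cx.atoms if a.serial == 2]
        assert len(ca1) == 1
        assert ca1[0].position[0] == pytest.approx(1.4)  # occupancy 0.60 wins

    def test_missing_chain_errors(self):
        with pytest.raises(StructureError, match="Z"):
            parse_structure(TOY_PDB, ["Z"], ["B"])

    def test_no_atoms_errors(self):
        with pytest.raises(StructureError):
            parse_structure("REMARK empty\nEND\n", [], [])


class TestComputeAsa:
    def test_isolated_atom_full_sphere(self):
        # carbon r=1.87 + probe 1.4 -> 4*pi*(3.27)^2
        asa = compute_asa([_atom(1, (0, 0, 0))])
        assert asa.areas[1] == pytest.approx(4 * np.pi * 3.27**2, rel=1e-6)

    def test_occlusion_reduces_area(self):
        pair = [_atom(1, (0, 0, 0)), _atom(2, (1.0, 0, 0))]
        asa = compute_asa(pair)
        full = 4 * np.pi * 3.27**2
        assert asa.areas[1] < full and asa.areas[2] < full

    def test_caged_atom_is_buried(self):
        # icosahedral-ish cage of large atoms around a central one
        k = np.arange(60) + 0.5
        phi = np.arccos(1 - 2 * k / 60)
        th = np.pi * (1 + 5**0.5) * k
        shell = 2.2 * np.column_stack(
            (np.cos(th) * np.sin(phi), np.sin(th) * np.sin(phi), np.cos(phi)))
        atoms = [_atom(1, (0, 0, 0))] + [
            _atom(i + 2, p) for i, p in enumerate(shell)]
        asa = compute_asa(atoms)
        assert asa.areas[1] < 1.0

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=3, size=(15, 3))
        base = compute_asa([_atom(i + 1, c) for i, c in enumerate(coords)])
        moved = compute_asa([_atom(i + 1, c + np.array([5.0, -3.0, 2.0]))
                             for i, c in enumerate(coords)])
        for s in base.areas:
            assert moved.areas[s] == pytest.approx(base.areas[s], rel=1e-6)

    def test_rotation_invariance_within_discretization(self):
        # the sample-point lattice is fixed in space, so rotating the
        # molecule changes per-atom values only at the sampling resolution
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=3, size=(15, 3))
        base = compute_asa([_atom(i + 1, c) for i, c in enumerate(coords)])
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        rotated = compute_asa([_atom(i + 1, c @ q) for i, c in enumerate(coords)])
        for s in base.areas:
            assert rotated.areas[s] == pytest.approx(base.areas[s], abs=2.0)
        assert sum(rotated.areas.values()) == pytest.approx(
            sum(base.areas.values()), rel=0.01)

    def test_agrees_with_independent_implementation(self):
        """Cross-check against Bio.PDB's Shrake-Rupley on the same radii."""
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB import PDBParser
        import io

        cx = parse_structure(TOY_PDB, ["A"], ["B"])
        ours = compute_asa(cx.atoms)

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("t", io.StringIO(TOY_PDB))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85})
        sr.compute(structure, level="A")
        for atom in structure.get_atoms():
            serial = atom.get_serial_number()
            if serial in ours.areas and atom.element != "SE":
                assert ours.areas[serial] == pytest.approx(atom.sasa, abs=3.0)

    def test_empty_errors(self):
        with pytest.raises(StructureError):
            compute_asa([])


class TestSurfaceAtoms:
    @pytest.mark.parametrize("area,included", [(10.0, True), (9.99, False), (120.0, True)])
    def test_inclusive_threshold(self, area, included):
        table = AsaTable(areas={1: area})
        assert (1 in surface_atoms(table)) is included

    def test_empty_table(self):
        assert surface_atoms(AsaTable(areas={})) == set()

    def test_threshold_monotone(self):
        rng = np.random.default_rng(0)
        table = AsaTable(areas={i: float(v) for i, v in
                                enumerate(rng.uniform(0, 50, size=40))})
        lo, hi = surface_atoms(table, 5.0), surface_atoms(table, 20.0)
        assert hi <= lo
        assert surface_atoms(table, 0.0) == {
            s for s, v in table.areas.items() if v >= 0}


class TestEpitopeLabeling:
    def _two_sided(self, gap):
        ag = [_atom(1, (0, 0, 0), res=1), _atom(2, (50, 0, 0), res=2)]
        ab = [_atom(3, (0, 0, gap), chain="H", res=1)]
        return ComplexRecord(antigen_chains=["A"], antibody_chains=["H"],
                             atoms=ag + ab)

    def test_within_cutoff_labels(self):
        assert label_epitope_residues(self._two_sided(3.99)) == {("A", 1, "")}

    def test_beyond_cutoff_empty(self):
        assert label_epitope_residues(self._two_sided(4.01)) == set()

    def test_zero_distance_labels(self):
        assert label_epitope_residues(self._two_sided(0.0)) == {("A", 1, "")}

    def test_empty_antibody_errors(self):
        cx = ComplexRecord(antigen_chains=["A"], antibody_chains=[],
                           atoms=[_atom(1, (0, 0, 0))])
        with pytest.raises(StructureError):
            label_epitope_residues(cx)

    def test_invariant_to_chain_renaming(self):
        cx = self._two_sided(3.0)
        renamed = ComplexRecord(
            antigen_chains=["A"], antibody_chains=["L"],
            atoms=[a if a.residue_key[0] == "A" else
                   AtomRecord(a.serial, a.atom_name, a.element,
                              ("L",) + a.residue_key[1:], a.amino_acid,
                              a.position, a.vdw_radius)
                   for a in cx.atoms])
        assert {k[1:] for k in label_epitope_residues(cx)} == \
               {k[1:] for k in label_epitope_residues(renamed)}


def _seq_complex(seq: str, name: str, chain: str = "A",
                 resolution: float = 2.0) -> ComplexRecord:
    from betop._constants import ONE_TO_THREE  # noqa: F401  (validity check)
    atoms = [
        _atom(i + 1, (3.8 * i, 0, 0), aa=aa, res=i + 1, chain=chain)
        for i, aa in enumerate(seq)
    ]
    ab = [_atom(1000 + i, (3.8 * i, 0, 3.0), aa="G", res=i + 1, chain="Z")
          for i in range(max(30, len(seq)))]
    return ComplexRecord(antigen_chains=[chain], antibody_chains=["Z"],
                         atoms=atoms + ab, resolution=resolution, name=name)


class TestCurate:
    def test_short_chain_dropped(self):
        short = _seq_complex("ACDEFGHIKLMNPQRSTVWYACDEFGHIK", "short")  # 29
        ok = _seq_complex("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", "ok")      # 30
        kept = curate([short, ok])
        assert [c.name for c in kept] == ["ok"]

    def test_poor_resolution_dropped(self):
        bad = _seq_complex("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", "bad", resolution=3.0)
        assert curate([bad]) == []

    def test_high_identity_duplicate_removed(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aas, size=50))
        # mutate 5 of 50 positions -> 90% identity
        mutant = list(base)
        for i in range(5):
            mutant[i * 7] = "W" if mutant[i * 7] != "W" else "Y"
        kept = curate([_seq_complex(base, "first"),
                       _seq_complex("".join(mutant), "dup")])
        assert [c.name for c in kept] == ["first"]

    def test_low_identity_both_kept(self):
        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=60))
        b = "".join(rng.choice(aas, size=60))
        kept = curate([_seq_complex(a, "a"), _seq_complex(b, "b")])
        assert [c.name for c in kept] == ["a", "b"]
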