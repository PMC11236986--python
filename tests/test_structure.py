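import math

import numpy as np
import pytest

from tg2screen.structure import (
    CavityDefinition, StructureComplex, aromatic_interactions,
    cavity_occupancy, close_contacts, classify_ring_pair, contacts_by_residue,
    interaction_summary, kabsch, read_complex, remove_bridging_sulfur,
    residue_deviations, superpose, write_complex_pdb,
)
from tg2screen.synthetic import ComplexSpec, gen_complex

from conftest import make_atom, phe_ring_complex


def minimal_complex(protein_atoms, ligand_atoms):
    return StructureComplex(protein=list(protein_atoms),
                            ligand=list(ligand_atoms))


class TestReadComplex:
    def test_hetatm_ligand_extracted(self, tmp_path):
        cx, _ = gen_complex(ComplexSpec(seed=0))
        path = tmp_path / "cx.pdb"
        write_complex_pdb(cx, path)
        loaded = read_complex(path, "LIG")
        assert len(loaded.ligand) == len(cx.ligand)
        assert len(loaded.protein) == len(cx.protein)

    def test_missing_selector_lists_het_codes(self, tmp_path):
        cx, _ = gen_complex(ComplexSpec(seed=0))
        path = tmp_path / "cx.pdb"
        write_complex_pdb(cx, path)
        with pytest.raises(ValueError, match="LIG"):
            read_complex(path, "XYZ")

    def test_altloc_a_retained(self, tmp_path):
        pdb = tmp_path / "altloc.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.50 10.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000"
            "  0.50 10.00           C\n"
            "ATOM      3  CB  ALA A   1       0.000   1.500   0.000"
            "  1.00 10.00           C\n"
            "HETATM    4  C1  LIG L   1       0.000   0.000   3.000"
            "  1.00 10.00           C\n"
            "END\n")
        cx = read_complex(pdb, "LIG")
        assert len(cx.protein) == 2  # altloc B dropped
        ca = [a for a in cx.protein if a.name == "CA"][0]
        assert ca.xyz[0] == pytest.approx(0.0)

    def test_waters_dropped(self, tmp_path):
        pdb = tmp_path / "wat.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00 10.00           C\n"
            "HETATM    2  O   HOH A 100       5.000   0.000   0.000"
            "  1.00 10.00           O\n"
            "HETATM    3  C1  LIG L   1       0.000   0.000   3.000"
            "  1.00 10.00           C\n"
            "END\n")
        cx = read_complex(pdb, "LIG")
        assert len(cx.protein) == 1 and len(cx.ligand) == 1


class TestCloseContacts:
    def test_planted_polar_pair_is_hydrogen_bond(self):
        cx = minimal_complex(
            [make_atom("OG", "O", (0, 0, 0), res_name="SER")],
            [make_atom("N1", "N", (0, 0, 3.0), chain="L", res_name="LIG")])
        records = close_contacts(cx)
        assert len(records) == 1
        assert records[0].klass == "hydrogen_bond"
        assert records[0].distance == pytest.approx(3.0)

    def test_distant_pair_not_recorded(self):
        cx = minimal_complex(
            [make_atom("CB", "C", (0, 0, 0))],
            [make_atom("C1", "C", (0, 0, 5.0), chain="L", res_name="LIG")])
        assert close_contacts(cx) == []

    def test_polar_pair_beyond_hbond_range_is_close_contact(self):
        cx = minimal_complex(
            [make_atom("OG", "O", (0, 0, 0), res_name="SER")],
            [make_atom("O1", "O", (0, 0, 3.8), chain="L", res_name="LIG")])
        assert [r.klass for r in close_contacts(cx)] == ["close_contact"]

    def test_planted_counts_recovered(self):
        cx, truth = gen_complex(ComplexSpec(n_hbonds=4, n_apolar=2,
                                            stacks=(), seed=1))
        records = close_contacts(cx)
        hbonds = [r for r in records if r.klass == "hydrogen_bond"]
        assert len(hbonds) == 4
        assert len(records) - len(hbonds) == 2

    def test_empty_ligand_rejected(self):
        with pytest.raises(ValueError):
            close_contacts(minimal_complex(
                [make_atom("CA", "C", (0, 0, 0))], []))

    def test_per_residue_summary(self):
        cx, _ = gen_complex(ComplexSpec(n_hbonds=2, n_apolar=0, stacks=(),
                                        seed=2))
        summary = contacts_by_residue(close_contacts(cx))
        assert sum(v.get("hydrogen_bond", 0) for v in summary.values()) == 2


class TestAromaticInteractions:
    def test_coplanar_stack_is_parallel(self):
        cx = phe_ring_complex((0, 0, 3.5), (0, 0, 1))
        kinds = [a.klass for a in aromatic_interactions(cx)]
        assert kinds == ["parallel"]

    def test_offset_stack_is_parallel_displaced(self):
        cx = phe_ring_complex((2.0, 0, 3.5), (0, 0, 1))
        a = aromatic_interactions(cx)[0]
        assert a.klass == "parallel_displaced"
        assert a.offset == pytest.approx(2.0, abs=1e-6)

    def test_perpendicular_rings_are_t_shaped(self):
        cx = phe_ring_complex((0, 0, 5.0), (1, 0, 0))
        a = aromatic_interactions(cx)[0]
        assert a.klass == "t_shaped"
        assert a.angle == pytest.approx(90.0, abs=1e-6)

    def test_intermediate_angle_reported_unclassified(self):
        tilt = math.radians(45)
        cx = phe_ring_complex((0, 0, 4.0), (math.sin(tilt), 0, math.cos(tilt)))
        assert [a.klass for a in aromatic_interactions(cx)] == ["unclassified"]

    def test_beyond_range_gives_empty(self):
        cx = phe_ring_complex((0, 0, 7.0), (0, 0, 1))
        assert aromatic_interactions(cx) == []

    def test_no_rings_is_empty_not_error(self):
        cx = minimal_complex(
            [make_atom("CA", "C", (0, 0, 0))],
            [make_atom("C1", "C", (0, 0, 3.0), chain="L", res_name="LIG")])
        assert aromatic_interactions(cx) == []

    def test_classification_matches_planted_labels(self):
        """Planted geometries away from decision boundaries classify 100%."""
        classes = ("parallel", "parallel_displaced", "t_shaped")
        for seed in range(25):
            spec = ComplexSpec(n_hbonds=0, n_apolar=0,
                               stacks=(classes[seed % 3],
                                       classes[(seed + 1) % 3]),
                               seed=seed)
            cx, truth = gen_complex(spec)
            found = [a for a in aromatic_interactions(cx)
                     if a.klass != "unclassified"]
            assert len(found) == len(truth["stacks"])
            assert ([a.klass for a in found]
                    == [s["class"] for s in truth["stacks"]])

    def test_classifier_rules_directly(self):
        assert classify_ring_pair(3.5, 10.0, 0.5) == "parallel"
        assert classify_ring_pair(3.5, 10.0, 2.0) == "parallel_displaced"
        assert classify_ring_pair(5.0, 80.0, 0.0) == "t_shaped"
        assert classify_ring_pair(5.0, 45.0, 0.0) == "unclassified"
        assert classify_ring_pair(6.0, 0.0, 0.0) is None


class TestInteractionSummary:
    def test_zero_interaction_complex(self):
        cx, _ = gen_complex(ComplexSpec(n_hbonds=0, n_apolar=0, stacks=(),
                                        seed=0))
        assert interaction_summary(cx) == (0, 0)

    def test_planted_totals(self):
        cx, truth = gen_complex(ComplexSpec(n_hbonds=4, n_apolar=1,
                                            stacks=("parallel",), seed=9))
        n_contacts, n_aromatic = interaction_summary(cx)
        assert n_contacts == truth["census_close_contacts"]
        assert n_aromatic == truth["census_aromatic"]

    def test_doubling_cutoffs_never_decreases_counts(self):
        cx, _ = gen_complex(ComplexSpec(n_hbonds=2, n_apolar=2,
                                        stacks=("parallel",), seed=4))
        base = interaction_summary(cx)
        wide = interaction_summary(cx, hbond_max=7.0, contact_max=8.0,
                                   d_stack_max=11.0)
        assert wide[0] >= base[0] and wide[1] >= base[1]


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def transformed_copy(cx, rot, trans):
    protein = [make_atom(a.name, a.element, rot @ a.pos + trans,
                         chain=a.chain, res_id=a.res_id, res_name=a.res_name)
               for a in cx.protein]
    ligand = [make_atom(a.name, a.element, rot @ a.pos + trans,
                        chain=a.chain, res_id=a.res_id, res_name=a.res_name)
              for a in cx.ligand]
    return StructureComplex(protein=protein, ligand=ligand,
                            ligand_bonds=list(cx.ligand_bonds),
                            source=cx.source + "_moved")


class TestSuperpose:
    def test_self_superposition_is_zero(self):
        cx, _ = gen_complex(ComplexSpec(seed=1))
        assert superpose(cx, cx).rmsd == pytest.approx(0.0, abs=1e-10)

    def test_translated_copy_returns_to_zero(self):
        cx, _ = gen_complex(ComplexSpec(seed=1))
        moved = transformed_copy(cx, np.eye(3), np.array([5.0, -3.0, 12.0]))
        assert superpose(moved, cx).rmsd == pytest.approx(0.0, abs=1e-10)

    def test_known_rotation_recovered(self):
        cx, _ = gen_complex(ComplexSpec(seed=1))
        rng = np.random.default_rng(0)
        rot = random_rotation(rng)
        moved = transformed_copy(cx, rot, np.array([1.0, 2.0, 3.0]))
        sup = superpose(moved, cx)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        # the recovered rotation must invert the applied one
        assert np.allclose(sup.rotation @ rot, np.eye(3), atol=1e-6)

    def test_rmsd_invariant_under_rigid_motion(self):
        cx_a, _ = gen_complex(ComplexSpec(seed=2))
        cx_b, _ = gen_complex(ComplexSpec(seed=3))
        base = superpose(cx_a, cx_b).rmsd
        rng = np.random.default_rng(42)
        for _ in range(5):
            moved = transformed_copy(cx_a, random_rotation(rng),
                                     rng.normal(scale=20, size=3))
            assert superpose(moved, cx_b).rmsd == pytest.approx(base, abs=1e-8)

    def test_too_few_pairs(self):
        a = minimal_complex([make_atom("CA", "C", (0, 0, 0))],
                            [make_atom("C1", "C", (9, 9, 9), chain="L")])
        with pytest.raises(ValueError):
            superpose(a, a)

    def test_kabsch_input_validation(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def catalytic_site_protein():
    """CYS277 + GLN169 + a 'wide' anchor residue, far apart."""
    atoms = []
    for res_name, res_id, base in [
            ("CYS", 277, (0.0, 0.0, 0.0)), ("GLN", 169, (30.0, 0.0, 0.0)),
            ("ALA", 10, (60.0, 0.0, 0.0)), ("GLY", 50, (45.0, 20.0, 0.0))]:
        base = np.asarray(base)
        atoms.append(make_atom("CA", "C", base + (0, 0, -3.0),
                               res_id=res_id, res_name=res_name))
        side = {"CYS": ("SG", "S"), "GLN": ("NE2", "N"), "ALA": ("CB", "C"),
                "GLY": ("N", "N")}
        name, element = side[res_name]
        atoms.append(make_atom(name, element, base, res_id=res_id,
                               res_name=res_name))
    return atoms


CAVITIES = (CavityDefinition("catalytic", ("C277",)),
            CavityDefinition("surface", ("Q169",)),
            CavityDefinition("wide", ("A10",)))


class TestCavityOccupancy:
    def test_ligand_near_catalytic_cysteine(self):
        cx = minimal_complex(
            catalytic_site_protein(),
            [make_atom("C1", "C", (0, 0, 3.0), chain="L", res_name="LIG")])
        occ = cavity_occupancy(cx, CAVITIES)
        assert occ.occupied == ("catalytic",)
        assert not occ.meets_two_of_three

    def test_ligand_far_from_all(self):
        cx = minimal_complex(
            catalytic_site_protein(),
            [make_atom("C1", "C", (0, 50, 50), chain="L", res_name="LIG")])
        occ = cavity_occupancy(cx, CAVITIES)
        assert occ.occupied == () and not occ.meets_two_of_three

    def test_two_cavity_pose_meets_criterion(self):
        cx = minimal_complex(
            catalytic_site_protein(),
            [make_atom("C1", "C", (0, 0, 3.0), chain="L", res_name="LIG"),
             make_atom("C2", "C", (30, 0, 3.0), chain="L", res_name="LIG")])
        occ = cavity_occupancy(cx, CAVITIES)
        assert occ.occupied == ("catalytic", "surface")
        assert occ.meets_two_of_three

    def test_missing_cavity_residue_named_in_error(self):
        cx = minimal_complex(
            catalytic_site_protein(),
            [make_atom("C1", "C", (0, 0, 3.0), chain="L", res_name="LIG")])
        with pytest.raises(ValueError, match="W999"):
            cavity_occupancy(cx, (CavityDefinition("ghost", ("W999",)),))


class TestResidueDeviations:
    def test_identical_structures_are_zero(self):
        protein = catalytic_site_protein()
        lig = [make_atom("C1", "C", (5, 5, 5), chain="L", res_name="LIG")]
        a = minimal_complex(protein, lig)
        b = minimal_complex(protein, lig)
        df = residue_deviations([a, b], residues=("C277", "Q169"))
        assert np.allclose(df.to_numpy(dtype=float), 0.0, atol=1e-10)

    def test_displaced_residue_detected(self):
        protein = catalytic_site_protein()
        lig = [make_atom("C1", "C", (5, 5, 5), chain="L", res_name="LIG")]
        moved = []
        for a in protein:
            pos = np.array(a.xyz)
            if a.res_id == 277 and a.name == "SG":
                pos = pos + np.array([0.0, 2.0, 0.0])
            moved.append(make_atom(a.name, a.element, pos, res_id=a.res_id,
                                   res_name=a.res_name))
        df = residue_deviations([minimal_complex(protein, lig),
                                 minimal_complex(moved, lig)],
                                residues=("C277", "Q169", "A10"))
        col = df.iloc[:, 1]
        # SG moved 2 A; residue RMSD over CA+SG = sqrt(4/2)
        assert col["C277"] == pytest.approx(math.sqrt(2.0), abs=0.05)
        assert col["Q169"] == pytest.approx(0.0, abs=1e-6)

    def test_missing_residue_flagged_not_fatal(self):
        protein = catalytic_site_protein()
        lig = [make_atom("C1", "C", (5, 5, 5), chain="L", res_name="LIG")]
        partial = [a for a in protein if a.res_id != 169]
        df = residue_deviations([minimal_complex(protein, lig),
                                 minimal_complex(partial, lig)],
                                residues=("C277", "Q169"))
        assert np.isnan(df.iloc[:, 1]["Q169"])
        assert df.iloc[:, 1]["C277"] == pytest.approx(0.0, abs=1e-10)


class TestBridgingSulfur:
    def test_bridging_sulfur_removed(self):
        protein = catalytic_site_protein()
        lig = [make_atom("S1", "S", (0, 0, 2.0), chain="L", res_name="LIG"),
               make_atom("C1", "C", (0, 0, 3.5), chain="L", res_name="LIG")]
        cx = StructureComplex(protein=protein, ligand=lig,
                              ligand_bonds=[(0, 1)])
        cleaned = remove_bridging_sulfur(cx)
        assert [a.name for a in cleaned.ligand] == ["C1"]
        assert cleaned.ligand_bonds == []

    def test_distant_sulfur_kept(self):
        protein = catalytic_site_protein()
        lig = [make_atom("S1", "S", (0, 0, 9.0), chain="L", res_name="LIG")]
        cx = minimal_complex(protein, lig)
        assert len(remove_bridging_sulfur(cx).ligand) == 1
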