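import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, FilterCatalog, Lipinski

from tg2screen.chem import (
    DescriptorSet, Fingerprint, PatternLoadError, SmilesParseError,
    circular_fingerprint, descriptors, load_patterns, pains_match,
    parse_smiles, ro5_pass, ro5_violations, tanimoto,
)
from tg2screen.synthetic import LibrarySpec, gen_library


class TestParseSmiles:
    @pytest.mark.parametrize("smiles,n_heavy", [
        ("c1ccccc1", 6),     # benzene
        ("CCO", 3),          # ethanol
        ("C", 1),            # methane
    ])
    def test_heavy_atom_counts(self, smiles, n_heavy):
        assert parse_smiles(smiles).heavy_atoms == n_heavy

    @pytest.mark.parametrize("bad", ["C1CC", "", "   ", "not_smiles(("])
    def test_rejects_invalid(self, bad):
        with pytest.raises(SmilesParseError):
            parse_smiles(bad)

    def test_error_reports_offending_string(self):
        with pytest.raises(SmilesParseError, match="C1CC"):
            parse_smiles("C1CC")

    def test_canonical_roundtrip(self):
        for smiles in ["OCC", "c1ccccc1C(=O)N", "N#Cc1ccc(F)cc1"]:
            mol = parse_smiles(smiles)
            assert parse_smiles(mol.smiles).smiles == mol.smiles

    def test_salt_stripping_keeps_largest_fragment(self):
        mol = parse_smiles("CC(=O)[O-].[Na+]")
        assert mol.heavy_atoms == 4  # acetate only

    def test_stereo_preserved(self):
        mol = parse_smiles("C[C@H](N)C(=O)O")
        assert "@" in mol.smiles


class TestFingerprint:
    def test_atom_order_invariance_simple(self):
        a = circular_fingerprint(parse_smiles("OCC"))
        b = circular_fingerprint(parse_smiles("CCO"))
        assert a.bits == b.bits

    def test_atom_order_invariance_random_permutations(self):
        """Renumbering atoms of generated molecules never changes the bits."""
        mols, _, _ = gen_library(LibrarySpec(seed=11))
        rng = np.random.default_rng(0)
        for mol in mols[:50]:
            perm = rng.permutation(mol.mol.GetNumAtoms()).tolist()
            renumbered = Chem.RenumberAtoms(mol.mol, perm)
            assert (circular_fingerprint(renumbered).bits
                    == circular_fingerprint(mol).bits)

    def test_methane_has_at_least_one_bit(self):
        assert circular_fingerprint(parse_smiles("C")).popcount >= 1

    def test_determinism(self, benzene):
        assert (circular_fingerprint(benzene).bits
                == circular_fingerprint(benzene).bits)

    def test_benzene_vs_ethane_below_identity(self, benzene):
        """Distinct molecules are distinguishable; the substrate's own
        Tanimoto implementation is the oracle for the value."""
        from rdkit import DataStructs
        from rdkit.Chem import rdFingerprintGenerator
        ethane = parse_smiles("CC")
        mine = tanimoto(circular_fingerprint(benzene),
                        circular_fingerprint(ethane))
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        ref = DataStructs.TanimotoSimilarity(gen.GetFingerprint(benzene.mol),
                                             gen.GetFingerprint(ethane.mol))
        assert mine < 1.0
        assert mine == pytest.approx(ref)

    @pytest.mark.parametrize("radius,nbits", [(-1, 2048), (3, 0), (3, -5)])
    def test_parameter_errors(self, benzene, radius, nbits):
        with pytest.raises(ValueError):
            circular_fingerprint(benzene, radius=radius, nbits=nbits)


class TestTanimoto:
    def test_identity_of_nonzero(self):
        fp = Fingerprint.from_bits([1, 5, 9])
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(Fingerprint.from_bits([1, 2]),
                        Fingerprint.from_bits([3, 4])) == 0.0

    def test_hand_counted_overlap(self):
        # {1,2,3} vs {2,3,4}: 2 shared / 4 union
        assert tanimoto(Fingerprint.from_bits([1, 2, 3]),
                        Fingerprint.from_bits([2, 3, 4])) == 0.5

    def test_both_empty_defined_as_one(self):
        assert tanimoto(Fingerprint.from_bits([]), Fingerprint.from_bits([])) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(Fingerprint.from_bits([1], nbits=64),
                     Fingerprint.from_bits([1], nbits=128))

    @settings(deadline=None, max_examples=100)
    @given(st.sets(st.integers(0, 63)), st.sets(st.integers(0, 63)))
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = Fingerprint.from_bits(bits_a, nbits=64)
        b = Fingerprint.from_bits(bits_b, nbits=64)
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)


DESCRIPTOR_PANEL = [
    "CC", "CCCC", "CCO", "c1ccccc1", "CC(=O)O", "c1ccccc1C(=O)N",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "O=S(=O)(Nc1ccccc1)c1ccc(N2CCOCC2)cc1", "NCCc1ccc(O)c(O)c1",
    "CC(=O)Nc1ccc(O)cc1", "OC(=O)c1ccccc1OC(C)=O", "ClC(Cl)(Cl)C",
    "c1ccc2ncncc2c1", "CCN(CC)CC", "O=C(O)CCCCC(=O)O",
    "c1ccc(-c2ccccc2)cc1", "C1CCNCC1", "FC(F)(F)c1ccccc1", "CC#N",
]


class TestDescriptors:
    @pytest.mark.parametrize("smiles,rotb", [("CC", 0), ("CCCC", 1)])
    def test_rotatable_bonds_hand_counted(self, smiles, rotb):
        assert descriptors(parse_smiles(smiles)).rotb == rotb

    def test_amide_bond_not_rotatable(self):
        # N-methylacetamide: the only internal single bond is the amide C-N
        assert descriptors(parse_smiles("CC(=O)NC")).rotb == 0

    def test_ethanol_lipinski_counts(self, ethanol):
        d = descriptors(ethanol)
        assert (d.hbd, d.hba) == (1, 1)

    @pytest.mark.parametrize("smiles", DESCRIPTOR_PANEL)
    def test_oracle_equivalence(self, smiles):
        """Counts exactly match the substrate's reference descriptor
        implementations; clogp within 0.5."""
        mol = parse_smiles(smiles)
        d = descriptors(mol)
        assert d.mw == pytest.approx(Descriptors.MolWt(mol.mol))
        assert d.hbd == Lipinski.NumHDonors(mol.mol)
        assert d.hba == Lipinski.NOCount(mol.mol)
        assert d.heavy == mol.mol.GetNumHeavyAtoms()
        assert d.clogp == pytest.approx(Crippen.MolLogP(mol.mol), abs=0.5)
        assert d.mw > 0 and min(d.hbd, d.hba, d.rotb, d.heavy) >= 0

    def test_ro5(self):
        drug = descriptors(parse_smiles("CC(=O)Nc1ccc(O)cc1"))
        assert ro5_pass(drug) and not ro5_violations(drug)
        heavy = DescriptorSet(mw=700.0, clogp=6.2, hbd=6, hba=12, rotb=12,
                              heavy=50)
        assert set(ro5_violations(heavy)) == {"mw>500", "clogp>5", "hbd>5",
                                              "hba>10"}


@pytest.fixture(scope="module")
def patterns():
    return load_patterns()


class TestPains:

    def test_methane_clean(self, patterns):
        assert pains_match(parse_smiles("C"), patterns) == []

    def test_self_match(self, patterns):
        # a molecule that IS one of the packaged patterns matches its id
        rhodanine = parse_smiles("O=C1CSC(=S)N1")
        assert "rhodanine" in pains_match(rhodanine, patterns)

    def test_quinone_matched_with_substrate_oracle(self, patterns):
        mol = parse_smiles("CC1=CC(=O)C=CC1=O")  # methyl-p-quinone
        ids = pains_match(mol, patterns)
        assert "quinone_para" in ids
        query = Chem.MolFromSmarts("O=C1C=CC(=O)C=C1")
        assert mol.mol.HasSubstructMatch(query)

    def test_flagged_families_agree_with_reference_catalog(self, patterns):
        """Molecules our curated families flag are also flagged by the
        substrate's full published PAINS catalog."""
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        catalog = FilterCatalog.FilterCatalog(params)
        flagged = ["O=C1C=CC(=O)C=C1", "CC(=O)c1ccc(O)c(O)c1",
                   "O=C1CSC(=S)N1C", "c1ccc(N=Nc2ccccc2)cc1"]
        for smiles in flagged:
            mol = parse_smiles(smiles)
            assert pains_match(mol, patterns)
            assert catalog.HasMatch(mol.mol)

    def test_malformed_pattern_file_names_pattern(self, tmp_path):
        bad = tmp_path / "bad.smarts"
        bad.write_text("c1ccccc1\tok_pattern\nC1CC(((\tbroken_one\n")
        with pytest.raises(PatternLoadError, match="broken_one"):
            load_patterns(bad)
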