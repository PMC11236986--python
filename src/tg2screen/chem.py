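"""Molecular data model, fingerprints, similarity and descriptors.

SMILES/SDF parsing, canonicalisation and the per-atom chemistry are
delegated to RDKit; everything above that substrate (the data model, the
similarity arithmetic used by the triage pipeline, the drug-likeness
filters) lives here.

Defaults follow the screening protocol this package implements: Morgan
(ECFP-style) circular fingerprints of radius 3 folded to 2048 bits, and
Tanimoto similarity over the folded bitsets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 3
DEFAULT_NBITS = 2048


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitised."""


class PatternLoadError(ValueError):
    """Raised when a substructure-pattern file contains a malformed SMARTS."""


@dataclass
class Molecule:
    """An identified chemical structure.

    ``smiles`` is canonical (RDKit canonicalisation, stereo preserved);
    ``mol`` is the parsed RDKit graph; ``coords`` optionally carries 3D
    heavy-atom coordinates in Angstrom (one triple per heavy atom).
    """

    id: str
    smiles: str
    mol: Chem.Mol
    coords: np.ndarray | None = None

    @property
    def heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def __post_init__(self) -> None:
        if self.mol.GetNumHeavyAtoms() < 1:
            raise SmilesParseError(f"{self.id!r}: molecule has no heavy atoms")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.heavy_atoms, 3):
                raise ValueError(
                    f"{self.id!r}: expected {self.heavy_atoms}x3 coordinates, "
                    f"got {self.coords.shape}"
                )


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length hashed circular fingerprint.

    ``bits`` is the sorted tuple of on-bit indices; folding collisions are
    accepted as-is (standard hashed-fingerprint behaviour).
    """

    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS
    radius: int = DEFAULT_RADIUS

    @property
    def popcount(self) -> int:
        return len(self.bits)

    @classmethod
    def from_bits(cls, on_bits: Iterable[int], nbits: int = DEFAULT_NBITS,
                  radius: int = DEFAULT_RADIUS) -> "Fingerprint":
        bits = frozenset(int(b) for b in on_bits)
        if bits and (min(bits) < 0 or max(bits) >= nbits):
            raise ValueError("bit index out of range")
        return cls(bits=bits, nbits=nbits, radius=radius)


@dataclass(frozen=True)
class DescriptorSet:
    """Descriptors feeding the Ro5 drug-likeness filter and ligand efficiency.

    hbd/hba follow the Lipinski convention (donor = N/O bearing >= 1 H,
    acceptor = any N/O); rotb is the strict rotatable-bond count (acyclic
    single bonds between non-terminal heavy atoms, amide C-N excluded).
    """

    mw: float
    clogp: float
    hbd: int
    hba: int
    rotb: int
    heavy: int


def strip_salts(mol: Chem.Mol) -> Chem.Mol:
    """Keep only the largest covalent fragment (drops counterions)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def parse_smiles(smiles: str, mol_id: str | None = None,
                 keep_largest_fragment: bool = True) -> Molecule:
    """Parse a SMILES string into a canonicalised :class:`Molecule`.

    Salt/mixture inputs are reduced to the largest covalent fragment by
    default, since library SMILES frequently carry counterions.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    if keep_largest_fragment:
        mol = strip_salts(mol)
    canonical = Chem.MolToSmiles(mol)
    return Molecule(id=mol_id if mol_id is not None else canonical,
                    smiles=canonical, mol=mol)


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits)
    return _FP_GENERATORS[key]


def circular_fingerprint(mol: Molecule | Chem.Mol, radius: int = DEFAULT_RADIUS,
                         nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """Morgan/ECFP-style circular fingerprint folded to ``nbits`` bits.

    Deterministic and invariant under atom reordering of the input SMILES.
    """
    if nbits <= 0:
        raise ValueError(f"nbits must be positive, got {nbits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    bv = _generator(radius, nbits).GetFingerprint(rdmol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Defined as 1.0 when both fingerprints are empty.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} != {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def descriptors(mol: Molecule | Chem.Mol) -> DescriptorSet:
    """Compute the descriptor set used by the Ro5 filter and LE."""
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    return DescriptorSet(
        mw=Descriptors.MolWt(rdmol),
        clogp=Crippen.MolLogP(rdmol),
        hbd=Lipinski.NumHDonors(rdmol),
        hba=Lipinski.NOCount(rdmol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(
            rdmol, rdMolDescriptors.NumRotatableBondsOptions.Strict),
        heavy=rdmol.GetNumHeavyAtoms(),
    )


def ro5_violations(desc: DescriptorSet) -> list[str]:
    """Names of Lipinski rule-of-five rules the descriptor set violates."""
    out = []
    if desc.mw > 500:
        out.append("mw>500")
    if desc.clogp > 5:
        out.append("clogp>5")
    if desc.hbd > 5:
        out.append("hbd>5")
    if desc.hba > 10:
        out.append("hba>10")
    return out


def ro5_pass(desc: DescriptorSet, max_violations: int = 0) -> bool:
    return len(ro5_violations(desc)) <= max_violations


# ---------------------------------------------------------------------------
# PAINS / substructure pattern filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstructurePattern:
    id: str
    smarts: str
    query: Chem.Mol = field(compare=False, repr=False, default=None)


def load_patterns(path: str | Path | None = None) -> list[SubstructurePattern]:
    """Load substructure patterns from a SMARTS file (``smarts<TAB>id``).

    With no path, the packaged curated PAINS-family file is used. A
    malformed pattern aborts the load, naming the offending line.
    """
    if path is None:
        text = (resources.files("tg2screen") / "data" / "pains.smarts").read_text()
        source = "packaged pains.smarts"
    else:
        text = Path(path).read_text()
        source = str(path)
    patterns = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smarts = parts[0].strip()
        pid = parts[1].strip() if len(parts) > 1 else f"pattern_{lineno}"
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise PatternLoadError(
                f"{source}:{lineno}: malformed SMARTS for {pid!r}: {smarts!r}")
        patterns.append(SubstructurePattern(id=pid, smarts=smarts, query=query))
    return patterns


def pains_match(mol: Molecule | Chem.Mol,
                patterns: Sequence[SubstructurePattern]) -> list[str]:
    """IDs of all patterns matching the molecule; empty list = clean."""
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    return [p.id for p in patterns if rdmol.HasSubstructMatch(p.query)]


# ---------------------------------------------------------------------------
# Ingest
# ---------------------------------------------------------------------------

def read_smiles_table(path: str | Path, id_col: str = "id",
                      smiles_col: str = "smiles",
                      activity_col: str | None = "ic50_nM",
                      ) -> tuple[list[Molecule], dict[str, float], list[str]]:
    """Read molecules (and optional activities) from a CSV/TSV file.

    Returns (molecules, {id: activity} for rows that have one, rejected ids).
    Unparseable SMILES are collected, not silently dropped.
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    mols: list[Molecule] = []
    activities: dict[str, float] = {}
    rejected: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delim):
            mol_id = row[id_col].strip()
            try:
                mols.append(parse_smiles(row[smiles_col].strip(), mol_id=mol_id))
            except SmilesParseError:
                rejected.append(mol_id)
                continue
            if activity_col and row.get(activity_col, "").strip():
                activities[mol_id] = float(row[activity_col])
    return mols, activities, rejected


def read_sdf(path: str | Path, id_prop: str = "_Name") -> list[Molecule]:
    """Read molecules from an SDF file; 3D coordinates are retained."""
    mols = []
    for i, rdmol in enumerate(Chem.SDMolSupplier(str(path), removeHs=True)):
        if rdmol is None:
            continue
        name = rdmol.GetProp(id_prop) if rdmol.HasProp(id_prop) else ""
        mol_id = name or f"mol_{i}"
        coords = None
        if rdmol.GetNumConformers():
            coords = rdmol.GetConformer().GetPositions()
        mols.append(Molecule(id=mol_id, smiles=Chem.MolToSmiles(rdmol),
                             mol=rdmol, coords=coords))
    return mols


def write_smiles_table(path: str | Path, mols: Sequence[Molecule],
                       activities: dict[str, float] | None = None) -> None:
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["id", "smiles", "ic50_nM"])
        for m in mols:
            act = "" if not activities or m.id not in activities else activities[m.id]
            writer.writerow([m.id, m.smiles, act])
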