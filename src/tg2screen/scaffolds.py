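"""Bemis-Murcko scaffold decomposition and scaffold-frequency mining.

A Bemis-Murcko scaffold is the molecule's ring systems plus the linker
atoms connecting them, with all side chains pruned; substituents attached
to the framework through a double or triple bond (exocyclic carbonyls and
the like) are retained, which is the convention of the framework's original
definition. Acyclic molecules have no scaffold and are reported with an
explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from .chem import Molecule


@dataclass(frozen=True)
class ScaffoldResult:
    """Scaffold of one molecule: canonical SMILES, or acyclic flag."""

    smiles: str            # canonical scaffold SMILES; "" when acyclic
    is_acyclic: bool
    generic: bool = False  # True if atom types were erased (all-carbon frame)


@dataclass
class ScaffoldRow:
    scaffold_smiles: str
    member_ids: list[str]

    @property
    def frequency(self) -> int:
        return len(self.member_ids)


@dataclass
class ScaffoldTable:
    """Canonical scaffold -> members, sorted by frequency descending."""

    rows: list[ScaffoldRow]
    label: str = ""
    n_acyclic: int = 0
    min_count: int = 1

    @property
    def scaffold_smiles(self) -> list[str]:
        return [r.scaffold_smiles for r in self.rows]


def _framework_atoms(mol: Chem.Mol) -> set[int]:
    """Indices of ring + linker atoms: the fixed point of deleting terminal
    (degree-1) heavy atoms."""
    degree = {a.GetIdx(): a.GetDegree() for a in mol.GetAtoms()}
    alive = set(degree)
    changed = True
    while changed:
        changed = False
        for idx in list(alive):
            if degree[idx] <= 1:
                alive.discard(idx)
                atom = mol.GetAtomWithIdx(idx)
                for nb in atom.GetNeighbors():
                    j = nb.GetIdx()
                    if j in alive:
                        degree[j] -= 1
                changed = True
    return alive


def murcko_scaffold(mol: Molecule | Chem.Mol, generic: bool = False) -> ScaffoldResult:
    """Bemis-Murcko scaffold: rings + linkers, plus atoms multiple-bonded to
    that framework; idempotent; acyclic input yields the empty scaffold.

    With ``generic=True`` atom types and bond orders are erased after
    pruning (all-carbon single-bonded framework).
    """
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    core = _framework_atoms(rdmol)
    if not core:
        return ScaffoldResult(smiles="", is_acyclic=True, generic=generic)
    keep = set(core)
    for bond in rdmol.GetBonds():
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in core and j not in core:
                keep.add(j)
            elif j in core and i not in core:
                keep.add(i)

    em = Chem.RWMol(rdmol)
    removed = set(range(rdmol.GetNumAtoms())) - keep
    # an aromatic N losing a single-bonded substituent needs its H back,
    # otherwise the pruned ring cannot be kekulized
    for bond in rdmol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for kept, lost in ((i, j), (j, i)):
            if kept in keep and lost in removed:
                atom = em.GetAtomWithIdx(kept)
                if atom.GetIsAromatic() and atom.GetAtomicNum() == 7:
                    atom.SetNumExplicitHs(atom.GetNumExplicitHs() + 1)
    for idx in sorted(removed, reverse=True):
        em.RemoveAtom(idx)
    scaffold = em.GetMol()
    if generic:
        em = Chem.RWMol(scaffold)
        for atom in em.GetAtoms():
            atom.SetAtomicNum(6)
            atom.SetIsAromatic(False)
            atom.SetFormalCharge(0)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        for bond in em.GetBonds():
            bond.SetBondType(Chem.BondType.SINGLE)
            bond.SetIsAromatic(False)
        scaffold = em.GetMol()
    Chem.SanitizeMol(scaffold)
    return ScaffoldResult(smiles=Chem.MolToSmiles(scaffold), is_acyclic=False,
                          generic=generic)


def scaffold_frequency(mols: Sequence[Molecule], min_count: int = 1,
                       label: str = "", generic: bool = False) -> ScaffoldTable:
    """Group molecules by canonical scaffold and keep scaffolds occurring at
    least ``min_count`` times (inclusive threshold).

    Acyclic molecules are excluded from the table and counted separately.
    Rows are sorted by frequency descending, ties by first occurrence.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    groups: dict[str, list[str]] = {}
    n_acyclic = 0
    for m in mols:
        res = murcko_scaffold(m, generic=generic)
        if res.is_acyclic:
            n_acyclic += 1
            continue
        groups.setdefault(res.smiles, []).append(m.id)
    rows = [ScaffoldRow(scaffold_smiles=s, member_ids=ids)
            for s, ids in groups.items() if len(ids) >= min_count]
    rows.sort(key=lambda r: -r.frequency)
    return ScaffoldTable(rows=rows, label=label, n_acyclic=n_acyclic,
                         min_count=min_count)


def scaffold_overlap(a: ScaffoldTable, b: ScaffoldTable
                     ) -> list[tuple[str, int, int]]:
    """Scaffolds shared between two tables, with their row indices in each.

    Identity is exact canonical-SMILES equality (the tables are built from
    canonical scaffolds)."""
    index_b = {r.scaffold_smiles: j for j, r in enumerate(b.rows)}
    out = []
    for i, r in enumerate(a.rows):
        if r.scaffold_smiles in index_b:
            out.append((r.scaffold_smiles, i, index_b[r.scaffold_smiles]))
    return out
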