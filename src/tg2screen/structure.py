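"""Geometric profiling of protein-ligand complexes.

Covers the active-site analyses used to characterise the transglutaminase
(TG2) binding saddle: close contacts and hydrogen-bond-like polar contacts,
aromatic ring-stacking classification (parallel / parallel-displaced /
T-shaped), cavity occupancy against the three-cavity model of the active
site (catalytic pocket around C277, surface pocket around Q169, and the
wide pocket), rigid-body superposition, and cross-structure deviations of
the catalytic residues.

All geometric cutoffs are explicit parameters with conventional defaults;
every report embeds the cutoffs used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
STANDARD_AA = set(AA3.values())
POLAR_ELEMENTS = {"N", "O", "S"}
WATER_NAMES = {"HOH", "WAT", "DOD"}

# side-chain ring atom names for the aromatic residues
RESIDUE_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}

DEFAULT_KEY_RESIDUES = ("C277", "H335", "D358", "W241", "H305", "E363",
                        "N333", "W332", "Q169")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    chain: str
    res_id: int
    res_name: str
    xyz: tuple[float, float, float]

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_id, self.res_name)


@dataclass
class StructureComplex:
    """Protein atoms + ligand atoms with residue/chain bookkeeping."""

    protein: list[Atom]
    ligand: list[Atom]
    ligand_bonds: list[tuple[int, int]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.protein:
            key = (a.chain, a.res_id, a.name)
            if key in seen:
                raise ValueError(f"duplicate protein atom {key}")
            seen.add(key)
        for atoms in (self.protein, self.ligand):
            for a in atoms:
                if not all(math.isfinite(c) for c in a.xyz):
                    raise ValueError(f"non-finite coordinates on atom {a.name}")

    def protein_coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        return np.array([a.pos for a in (atoms or self.protein)])

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.ligand])

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.protein:
            out.setdefault(a.residue_key, []).append(a)
        return out


@dataclass(frozen=True)
class ContactRecord:
    protein_atom: Atom
    ligand_atom: Atom
    distance: float
    klass: str  # "hydrogen_bond" | "close_contact"


@dataclass(frozen=True)
class Ring:
    label: str                   # e.g. "A/PHE316" or "ligand_ring_0"
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]

    @property
    def c(self) -> np.ndarray:
        return np.asarray(self.centroid)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal)


@dataclass(frozen=True)
class AromaticInteraction:
    protein_ring: Ring
    ligand_ring: Ring
    distance: float       # centroid-centroid, Angstrom
    angle: float          # interplanar angle, degrees, in [0, 90]
    offset: float         # lateral displacement in the protein ring plane
    klass: str            # parallel | parallel_displaced | t_shaped | unclassified


@dataclass(frozen=True)
class CavityDefinition:
    label: str
    residues: tuple[str, ...]    # e.g. ("C277", "W241")
    capture_radius: float = 4.0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"cavity {self.label!r} has no defining residues")


DEFAULT_CAVITIES = (
    CavityDefinition("catalytic", ("C277", "W241", "W332", "H335")),
    CavityDefinition("surface", ("Q169",)),
)


def parse_residue_spec(spec: str) -> tuple[str, int]:
    """'C277' -> ('CYS', 277)."""
    letter, number = spec[0].upper(), spec[1:]
    if letter not in AA3 or not number.isdigit():
        raise ValueError(f"bad residue spec {spec!r} (expected e.g. 'C277')")
    return AA3[letter], int(number)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_complex(path: str | Path, ligand_selector: str) -> StructureComplex:
    """Read a PDB file and partition it into protein and one ligand.

    ``ligand_selector`` is a HET residue name (e.g. "LIG", "GTP") or a chain
    name. Waters are dropped; only altloc A (or blank) is kept.
    """
    st = gemmi.read_structure(str(path))
    model = st[0]
    protein: list[Atom] = []
    ligand: list[Atom] = []
    het_codes: set[str] = set()
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            is_ligand = (res.name == ligand_selector
                         or chain.name == ligand_selector)
            if res.name not in STANDARD_AA and not is_ligand:
                het_codes.add(res.name)
            for atom in res:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                rec = Atom(name=atom.name, element=atom.element.name.upper(),
                           chain=chain.name, res_id=res.seqid.num,
                           res_name=res.name,
                           xyz=(atom.pos.x, atom.pos.y, atom.pos.z))
                if is_ligand:
                    ligand.append(rec)
                elif res.name in STANDARD_AA:
                    protein.append(rec)
    if not ligand:
        raise ValueError(
            f"ligand selector {ligand_selector!r} matched nothing; "
            f"available het codes: {sorted(het_codes) or 'none'}")
    return StructureComplex(protein=protein, ligand=ligand, source=str(path))


def write_complex_pdb(cx: StructureComplex, path: str | Path) -> None:
    """Write a complex as a PDB file (protein as ATOM, ligand as HETATM)."""
    st = gemmi.Structure()
    st.name = cx.source or "complex"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add(atom: Atom, het: bool, serial: list[int]) -> None:
        ch = chains.setdefault(atom.chain, gemmi.Chain(atom.chain))
        res = None
        for r in ch:
            if r.seqid.num == atom.res_id and r.name == atom.res_name:
                res = r
                break
        if res is None:
            res = gemmi.Residue()
            res.name = atom.res_name
            res.seqid = gemmi.SeqId(atom.res_id, " ")
            res.het_flag = "H" if het else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        a = gemmi.Atom()
        a.name = atom.name
        a.element = gemmi.Element(atom.element)
        a.pos = gemmi.Position(*atom.xyz)
        a.serial = serial[0]
        serial[0] += 1
        res.add_atom(a)

    serial = [1]
    for atom in cx.protein:
        add(atom, het=False, serial=serial)
    for atom in cx.ligand:
        add(atom, het=True, serial=serial)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _heavy(atoms: Iterable[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element not in ("H", "D")]


def close_contacts(cx: StructureComplex, hbond_max: float = 3.5,
                   contact_max: float = 4.0) -> list[ContactRecord]:
    """Protein-ligand heavy-atom contacts.

    A pair of polar atoms (N/O/S on both sides) within ``hbond_max`` is
    recorded as a hydrogen bond (donor/acceptor geometry is not checked —
    hydrogens are usually absent); any other heavy-atom pair within
    ``contact_max`` is a close contact. One record per atom pair.
    """
    if not (0 < hbond_max <= contact_max):
        raise ValueError("require 0 < hbond_max <= contact_max")
    lig = _heavy(cx.ligand)
    prot = _heavy(cx.protein)
    if not lig:
        raise ValueError("complex has no ligand heavy atoms")
    if not prot:
        return []
    tree = cKDTree(np.array([a.pos for a in prot]))
    records: list[ContactRecord] = []
    for la in lig:
        for pi in tree.query_ball_point(la.pos, contact_max):
            pa = prot[pi]
            dist = float(np.linalg.norm(la.pos - pa.pos))
            if (pa.element in POLAR_ELEMENTS and la.element in POLAR_ELEMENTS
                    and dist <= hbond_max):
                klass = "hydrogen_bond"
            else:
                klass = "close_contact"
            records.append(ContactRecord(pa, la, dist, klass))
    records.sort(key=lambda r: r.distance)
    return records


def contacts_by_residue(records: Sequence[ContactRecord]
                        ) -> dict[tuple[str, int, str], dict[str, int]]:
    """Per-residue contact summary: residue -> {class: count}."""
    out: dict[tuple[str, int, str], dict[str, int]] = {}
    for r in records:
        counts = out.setdefault(r.protein_atom.residue_key, {})
        counts[r.klass] = counts.get(r.klass, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Aromatic interactions
# ---------------------------------------------------------------------------

def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane of ring atoms: (centroid, unit normal, max |dev|)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    dev = float(np.max(np.abs(centered @ normal)))
    return centroid, normal, dev


def infer_bonds(atoms: Sequence[Atom], tol: float = 0.45) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference for ligand atoms."""
    radii = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "P": 1.10,
             "F": 0.64, "CL": 0.99, "BR": 1.14, "I": 1.33}
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = radii.get(atoms[i].element, 0.77)
            rj = radii.get(atoms[j].element, 0.77)
            d = np.linalg.norm(atoms[i].pos - atoms[j].pos)
            if d <= ri + rj + tol:
                bonds.append((i, j))
    return bonds


def protein_rings(cx: StructureComplex) -> list[Ring]:
    """Side-chain aromatic rings (Phe/Tyr/Trp/His) present in the protein."""
    rings = []
    for key, atoms in cx.residues().items():
        chain, res_id, res_name = key
        templates = RESIDUE_RINGS.get(res_name)
        if not templates:
            continue
        by_name = {a.name: a for a in atoms}
        for t, names in enumerate(templates):
            if not all(n in by_name for n in names):
                continue
            coords = np.array([by_name[n].pos for n in names])
            centroid, normal, _ = ring_plane(coords)
            suffix = f".{t}" if len(templates) > 1 else ""
            rings.append(Ring(label=f"{chain}/{res_name}{res_id}{suffix}",
                              centroid=tuple(centroid), normal=tuple(normal)))
    return rings


def ligand_rings(cx: StructureComplex, planarity_max: float = 0.15) -> list[Ring]:
    """5-/6-membered (approximately planar) rings of the ligand.

    Uses the complex's explicit ligand bonds when present, otherwise
    distance-inferred bonds.
    """
    lig = _heavy(cx.ligand)
    if len(lig) < 5:
        return []
    bonds = cx.ligand_bonds or infer_bonds(lig)
    g = nx.Graph(bonds)
    rings = []
    for k, cycle in enumerate(nx.cycle_basis(g)):
        if len(cycle) not in (5, 6):
            continue
        coords = np.array([lig[i].pos for i in cycle])
        centroid, normal, dev = ring_plane(coords)
        if dev > planarity_max:
            continue
        rings.append(Ring(label=f"ligand_ring_{k}",
                          centroid=tuple(centroid), normal=tuple(normal)))
    return rings


def classify_ring_pair(distance: float, angle: float, offset: float,
                       d_stack_max: float = 5.5, angle_parallel_max: float = 30.0,
                       offset_parallel_max: float = 1.5,
                       angle_t_min: float = 60.0) -> str | None:
    """Geometry rules for a ring pair; None when beyond the stacking range."""
    if distance > d_stack_max:
        return None
    if angle <= angle_parallel_max:
        return "parallel" if offset <= offset_parallel_max else "parallel_displaced"
    if angle >= angle_t_min:
        return "t_shaped"
    return "unclassified"


def aromatic_interactions(cx: StructureComplex, d_stack_max: float = 5.5,
                          angle_parallel_max: float = 30.0,
                          offset_parallel_max: float = 1.5,
                          angle_t_min: float = 60.0) -> list[AromaticInteraction]:
    """Classify every protein-ring / ligand-ring pair within stacking range.

    The interplanar angle is folded into [0, 90] degrees; the lateral offset
    is the centroid separation projected into the protein ring plane.
    Intermediate angles are kept with class ``unclassified`` so they can be
    reported separately.
    """
    out = []
    for pr in protein_rings(cx):
        for lr in ligand_rings(cx):
            sep = lr.c - pr.c
            distance = float(np.linalg.norm(sep))
            if distance > d_stack_max:
                continue
            cosang = abs(float(np.dot(pr.n, lr.n)))
            angle = math.degrees(math.acos(min(1.0, cosang)))
            along = float(np.dot(sep, pr.n))
            offset = float(math.sqrt(max(0.0, distance ** 2 - along ** 2)))
            klass = classify_ring_pair(distance, angle, offset, d_stack_max,
                                       angle_parallel_max, offset_parallel_max,
                                       angle_t_min)
            out.append(AromaticInteraction(pr, lr, distance, angle, offset,
                                           klass))
    return out


def interaction_summary(cx: StructureComplex, hbond_max: float = 3.5,
                        contact_max: float = 4.0, d_stack_max: float = 5.5,
                        angle_parallel_max: float = 30.0,
                        offset_parallel_max: float = 1.5,
                        angle_t_min: float = 60.0) -> tuple[int, int]:
    """(number of close contacts incl. hydrogen bonds, number of classified
    aromatic interactions) for one complex."""
    contacts = close_contacts(cx, hbond_max, contact_max)
    aromatics = [a for a in aromatic_interactions(
        cx, d_stack_max, angle_parallel_max, offset_parallel_max, angle_t_min)
        if a.klass != "unclassified"]
    return len(contacts), len(aromatics)


# ---------------------------------------------------------------------------
# Superposition and residue deviations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray     # 3x3
    translation: np.ndarray  # 3
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid-body superposition of paired coordinate sets."""
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need >= 3 paired atoms with matching shapes")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd,
                         n_atoms=mobile.shape[0])


def _atom_map(cx: StructureComplex,
              selection: Callable[[Atom], bool] | None = None
              ) -> dict[tuple[str, int, str], Atom]:
    out = {}
    for a in cx.protein:
        if selection is None or selection(a):
            out[(a.chain, a.res_id, a.name)] = a
    return out


def superpose(mobile: StructureComplex, reference: StructureComplex,
              atom_selection: Callable[[Atom], bool] | None = None
              ) -> Superposition:
    """Superpose ``mobile`` onto ``reference``; atoms are paired by
    (chain, residue id, atom name), optionally restricted by a selection."""
    mmap = _atom_map(mobile, atom_selection)
    rmap = _atom_map(reference, atom_selection)
    shared = sorted(set(mmap) & set(rmap))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} paired atoms; need >= 3")
    mob = np.array([mmap[k].pos for k in shared])
    ref = np.array([rmap[k].pos for k in shared])
    return kabsch(mob, ref)


def residue_deviations(structures: Sequence[StructureComplex],
                       residues: Sequence[str] = DEFAULT_KEY_RESIDUES,
                       reference_index: int = 0) -> "pd.DataFrame":
    """Per-residue heavy-atom RMSD of each structure vs a reference.

    Structures are first superposed on their shared C-alpha atoms; each
    listed residue (one-letter + number, e.g. 'C277') is then compared by
    heavy atoms paired on atom name. Missing residues give NaN rather than
    failing, mirroring unresolved loops in experimental structures.
    """
    import pandas as pd

    if len(structures) < 2:
        raise ValueError("need >= 2 structures")
    ref = structures[reference_index]
    ref_res = ref.residues()
    rows = {}
    for si, st in enumerate(structures):
        col = {}
        if si == reference_index:
            for spec in residues:
                res_name, res_id = parse_residue_spec(spec)
                present = any(k[1] == res_id and k[2] == res_name for k in ref_res)
                col[spec] = 0.0 if present else float("nan")
        else:
            sup = superpose(st, ref, atom_selection=lambda a: a.name == "CA")
            st_res = st.residues()
            for spec in residues:
                res_name, res_id = parse_residue_spec(spec)

                def find(resmap):
                    for k, atoms in resmap.items():
                        if k[1] == res_id and k[2] == res_name:
                            return {a.name: a for a in _heavy(atoms)}
                    return None

                mv, rv = find(st_res), find(ref_res)
                if mv is None or rv is None:
                    col[spec] = float("nan")
                    continue
                names = sorted(set(mv) & set(rv))
                if not names:
                    col[spec] = float("nan")
                    continue
                moved = sup.apply(np.array([mv[n].pos for n in names]))
                refc = np.array([rv[n].pos for n in names])
                col[spec] = float(np.sqrt(np.mean(
                    np.sum((moved - refc) ** 2, axis=1))))
        rows[st.source or f"structure_{si}"] = col
    df = pd.DataFrame(rows)
    if df.notna().sum().sum() == 0:
        raise ValueError("no shared residues between the structures")
    return df


# ---------------------------------------------------------------------------
# Cavity occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyResult:
    occupied: tuple[str, ...]
    meets_two_of_three: bool
    capture_radius: float


def cavity_occupancy(cx: StructureComplex,
                     cavities: Sequence[CavityDefinition] = DEFAULT_CAVITIES,
                     capture: float = 4.0) -> OccupancyResult:
    """Which cavities the ligand occupies.

    A cavity is occupied when any ligand heavy atom lies within ``capture``
    Angstrom of any heavy atom of its defining residues. Also reports the
    binding criterion that a ligand should occupy at least two of the three
    active-site cavities.
    """
    lig = np.array([a.pos for a in _heavy(cx.ligand)])
    if lig.size == 0:
        raise ValueError("complex has no ligand heavy atoms")
    resmap = cx.residues()
    occupied = []
    for cav in cavities:
        atoms: list[Atom] = []
        missing = []
        for spec in cav.residues:
            res_name, res_id = parse_residue_spec(spec)
            found = [a for k, v in resmap.items()
                     for a in _heavy(v) if k[1] == res_id and k[2] == res_name]
            if not found:
                missing.append(spec)
            atoms.extend(found)
        if missing:
            raise ValueError(
                f"cavity {cav.label!r}: residues not in structure: {missing}")
        coords = np.array([a.pos for a in atoms])
        dmin = np.min(np.linalg.norm(
            lig[:, None, :] - coords[None, :, :], axis=-1))
        if dmin <= capture:
            occupied.append(cav.label)
    return OccupancyResult(occupied=tuple(occupied),
                           meets_two_of_three=len(occupied) >= 2,
                           capture_radius=capture)


def remove_bridging_sulfur(cx: StructureComplex, cys_res_id: int = 277,
                           max_dist: float = 2.3) -> StructureComplex:
    """Drop ligand sulfur atoms covalently bridging to the catalytic
    cysteine's SG (the leftover of covalent peptidomimetic inhibition)."""
    sg = [a for a in cx.protein
          if a.res_name == "CYS" and a.res_id == cys_res_id and a.name == "SG"]
    if not sg:
        return cx
    keep, removed_idx = [], set()
    for i, a in enumerate(cx.ligand):
        if a.element == "S" and any(
                np.linalg.norm(a.pos - s.pos) <= max_dist for s in sg):
            removed_idx.add(i)
        else:
            keep.append(a)
    if not removed_idx:
        return cx
    remap = {}
    j = 0
    for i in range(len(cx.ligand)):
        if i not in removed_idx:
            remap[i] = j
            j += 1
    bonds = [(remap[i], remap[j2]) for i, j2 in cx.ligand_bonds
             if i not in removed_idx and j2 not in removed_idx]
    return StructureComplex(protein=cx.protein, ligand=keep,
                            ligand_bonds=bonds, source=cx.source)
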