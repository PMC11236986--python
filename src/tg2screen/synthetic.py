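"""Download-free synthetic inputs with known ground truth.

Three generators emulate the statistical and geometric structure of the
real inputs the pipeline was designed for:

* :func:`gen_library` — a scaffold-structured SMILES library with
  log-normally distributed IC50 potencies, standing in for a curated
  extract of assayed inhibitors and a vendor search space;
* :func:`gen_complex` — a toy protein-ligand complex with hydrogen bonds,
  apolar contacts and aromatic stacks planted at exact geometries;
* :func:`gen_docking_table` — per-scaffold docking score tables with
  planted outliers.

Every generator is a pure function of its spec + seed and emits the planted
truth alongside the data, so each downstream stage can be scored without
any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .activity import ActivityRecord
from .chem import Molecule
from .scaffolds import murcko_scaffold
from .structure import Atom, StructureComplex

# Decoration fragments are a small curated set guaranteed to sanitise when
# attached to a ring or linker atom; sulfonamide and carboxamide are
# included because those groups dominate real TG2-targeted scaffolds.
DEFAULT_FRAGMENTS = ("F", "Cl", "Br", "C", "OC", "C(F)(F)F",
                     "S(N)(=O)=O", "C(N)=O", "C#N")

DEFAULT_SCAFFOLDS = (
    "O=S(=O)(Nc1ccc(-c2ccccc2)cc1)c1ccc2ccccc2c1",  # naphthalene sulfonamide biphenyl
    "O=C(Nc1ccc(N2CCOCC2)cc1)c1cc2ccccc2s1",        # benzothiophene amide / morpholine
    "c1ccc(CN2CCN(c3ncnc4ccccc34)CC2)cc1",          # quinazoline benzylpiperazine
    "O=C1CN=C(c2ccccc2)N1c1ccc2[nH]ccc2c1",         # aryl imidazolinone / indole
    "O=S(=O)(Nc1ccccn1)c1ccc(-n2cccc2)cc1",         # pyridyl sulfonamide / pyrrole
    "O=C(Nc1ccc2ncncc2c1)C1CCN(Cc2ccccc2)CC1",      # quinazoline amide piperidine
)


# ---------------------------------------------------------------------------
# Library generator
# ---------------------------------------------------------------------------

@dataclass
class LibrarySpec:
    """Conditions for a synthetic scaffold-structured library.

    IC50s are log-normal per scaffold: ``ic50_median_nm`` (scalar or one per
    scaffold) and geometric SD ``ic50_gsd``. Defaults emulate a potent
    inhibitor extract: median 150 nM with a geometric SD of 2.5, so most but
    not all compounds fall under the 500 nM activity cut.
    """

    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS[:3]
    compounds_per_scaffold: int = 25
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    n_sites: int = 2
    p_bare: float = 0.15
    ic50_median_nm: float | tuple[float, ...] = 150.0
    ic50_gsd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compounds_per_scaffold < 1:
            raise ValueError("compounds_per_scaffold must be >= 1")
        medians = self.medians()
        if any(m <= 0 for m in medians):
            raise ValueError("ic50 medians must be positive")

    def medians(self) -> tuple[float, ...]:
        if isinstance(self.ic50_median_nm, (int, float)):
            return (float(self.ic50_median_nm),) * len(self.scaffolds)
        if len(self.ic50_median_nm) != len(self.scaffolds):
            raise ValueError("one ic50 median per scaffold required")
        return tuple(float(m) for m in self.ic50_median_nm)


@dataclass
class LibraryTruth:
    """Planted ground truth: compound -> scaffold, plus the scaffold list."""

    compound_scaffold: dict[str, str]        # id -> canonical scaffold SMILES
    planted_scaffolds: list[str]             # canonical, one per spec scaffold


def _attach(core: Chem.Mol, fragment_smiles: str, site: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(fragment_smiles)
    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    combined.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _open_sites(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7)]


def gen_library(spec: LibrarySpec
                ) -> tuple[list[Molecule], list[ActivityRecord], LibraryTruth]:
    """Generate a decorated library around the spec's planted scaffolds.

    Each scaffold becomes a congeneric series: ``n_sites`` attachment
    positions are fixed once per scaffold and every member carries a random
    acyclic substituent at each of them (left bare with probability
    ``p_bare``), the way a medicinal-chemistry series enumerates R-groups
    around a core. Substituents are acyclic side chains, so every compound
    Murcko-reduces back to its planted scaffold. Deterministic under the
    spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    cores = []
    planted: list[str] = []
    for smi in spec.scaffolds:
        core = Chem.MolFromSmiles(smi)
        if core is None:
            raise ValueError(f"unparseable scaffold SMILES: {smi!r}")
        res = murcko_scaffold(core)
        if res.is_acyclic:
            raise ValueError(f"scaffold {smi!r} is acyclic: it has no "
                             "Bemis-Murcko framework to recover")
        cores.append(core)
        planted.append(res.smiles)

    medians = spec.medians()
    mols: list[Molecule] = []
    records: list[ActivityRecord] = []
    truth = LibraryTruth(compound_scaffold={}, planted_scaffolds=planted)
    for si, core in enumerate(cores):
        sites = _open_sites(core)
        if not sites:
            raise ValueError(f"scaffold {spec.scaffolds[si]!r} has no "
                             "substitutable positions")
        n_sites = min(spec.n_sites, len(sites))
        # descending order keeps site indices valid as fragments are appended
        series_sites = sorted(
            (int(s) for s in rng.choice(sites, size=n_sites, replace=False)),
            reverse=True)
        for ci in range(spec.compounds_per_scaffold):
            mol = core
            for site in series_sites:
                if rng.random() < spec.p_bare:
                    continue
                frag = spec.fragments[int(rng.integers(len(spec.fragments)))]
                attached = _attach(mol, frag, site)
                if attached is not None:
                    mol = attached
            cid = f"S{si}_C{ci:03d}"
            smiles = Chem.MolToSmiles(mol)
            mols.append(Molecule(id=cid, smiles=smiles,
                                 mol=Chem.MolFromSmiles(smiles)))
            ic50 = float(medians[si] * math.exp(
                rng.normal(0.0, math.log(spec.ic50_gsd))))
            records.append(ActivityRecord(compound_id=cid, ic50=ic50,
                                          source=f"synthetic seed={spec.seed}"))
            truth.compound_scaffold[cid] = planted[si]
    return mols, records, truth


# ---------------------------------------------------------------------------
# Complex generator
# ---------------------------------------------------------------------------

@dataclass
class ComplexSpec:
    """Planted interactions for a toy complex.

    Geometry parameters are sampled inside class-safe ranges that keep every
    planted interaction at least 5 degrees / 0.3 Angstrom away from the
    classifier decision boundaries (3.5/4.0 A contacts; 30/60 degrees and
    1.5 A offset, 5.5 A centroid distance for stacking).
    """

    n_hbonds: int = 2
    n_apolar: int = 1
    stacks: tuple[str, ...] = ("parallel",)
    seed: int = 0
    hbond_distance: tuple[float, float] = (2.7, 3.2)
    apolar_distance: tuple[float, float] = (3.2, 3.7)
    site_spacing: float = 25.0

    def __post_init__(self) -> None:
        valid = {"parallel", "parallel_displaced", "t_shaped"}
        bad = set(self.stacks) - valid
        if bad:
            raise ValueError(f"unknown stack classes: {sorted(bad)}")
        if self.hbond_distance[1] > 3.2 or self.apolar_distance[1] > 3.7:
            raise ValueError("planted contact distances must stay >= 0.3 A "
                             "below their classification cutoffs")


_RING_RADIUS = 1.39  # aromatic C-C ring circumradius, Angstrom


def _hexagon(centroid: np.ndarray, normal: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Six ring-atom positions in the plane through centroid with the given
    unit normal."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    phase = rng.uniform(0, 2 * math.pi)
    pts = []
    for k in range(6):
        ang = phase + k * math.pi / 3
        pts.append(centroid + _RING_RADIUS * (math.cos(ang) * u
                                              + math.sin(ang) * v))
    return np.array(pts)


def _stack_geometry(klass: str, rng: np.random.Generator
                    ) -> tuple[float, float, float]:
    """(centroid distance, interplanar angle deg, lateral offset) sampled
    safely inside the class region."""
    if klass == "parallel":
        angle = rng.uniform(0.0, 20.0)
        offset = rng.uniform(0.0, 1.1)
        height = rng.uniform(3.3, 4.3)
    elif klass == "parallel_displaced":
        angle = rng.uniform(0.0, 20.0)
        offset = rng.uniform(1.9, 2.6)
        height = rng.uniform(3.3, 4.0)
    else:  # t_shaped
        angle = rng.uniform(67.0, 90.0)
        offset = rng.uniform(0.0, 1.0)
        height = rng.uniform(4.3, 5.0)
    distance = math.hypot(height, offset)
    return distance, angle, offset


def gen_complex(spec: ComplexSpec) -> tuple[StructureComplex, dict]:
    """Build a synthetic protein fragment + ligand realising exactly the
    planted interactions; returns the complex and the planted truth.

    Sites are spaced ``site_spacing`` Angstrom apart so interactions cannot
    leak between sites. The truth records the planted counts, the per-stack
    class labels and geometry, and a full geometric census of heavy-atom
    contacts (planted polar pairs plus any incidental ring-carbon pairs
    within the 4.0 A contact cutoff).
    """
    rng = np.random.default_rng(spec.seed)
    protein: list[Atom] = []
    ligand: list[Atom] = []
    ligand_bonds: list[tuple[int, int]] = []
    truth: dict = {"n_hbonds": spec.n_hbonds, "n_apolar": spec.n_apolar,
                   "stacks": [], "seed": spec.seed}
    res_id = 0
    site = 0

    def origin() -> np.ndarray:
        nonlocal site
        o = np.array([site * spec.site_spacing, 0.0, 0.0])
        site += 1
        return o

    def add_residue(res_name: str, atoms: list[tuple[str, str, np.ndarray]]):
        nonlocal res_id
        res_id += 1
        for name, element, pos in atoms:
            protein.append(Atom(name=name, element=element, chain="A",
                                res_id=res_id, res_name=res_name,
                                xyz=tuple(float(c) for c in pos)))

    def add_ligand_atom(name: str, element: str, pos: np.ndarray) -> int:
        ligand.append(Atom(name=name, element=element, chain="L", res_id=1,
                           res_name="LIG", xyz=tuple(float(c) for c in pos)))
        return len(ligand) - 1

    for i in range(spec.n_hbonds):
        o = origin()
        d = rng.uniform(*spec.hbond_distance)
        add_residue("SER", [
            ("N", "N", o + (0.0, -1.2, -4.1)),
            ("CA", "C", o + (0.0, 0.0, -2.9)),
            ("CB", "C", o + (0.0, 0.0, -1.5)),
            ("OG", "O", o + (0.0, 0.0, 0.0)),
        ])
        add_ligand_atom(f"O{i + 1}", "O", o + (0.0, 0.0, d))

    for i in range(spec.n_apolar):
        o = origin()
        d = rng.uniform(*spec.apolar_distance)
        add_residue("ALA", [
            ("N", "N", o + (0.0, -1.2, -4.2)),
            ("CA", "C", o + (0.0, 0.0, -1.5)),
            ("CB", "C", o + (0.0, 0.0, 0.0)),
        ])
        add_ligand_atom(f"C{i + 1}", "C", o + (0.0, 0.0, d))

    phe_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    for k, klass in enumerate(spec.stacks):
        o = origin()
        distance, angle, offset = _stack_geometry(klass, rng)
        height = math.sqrt(distance ** 2 - offset ** 2)
        normal_p = np.array([0.0, 0.0, 1.0])
        ring_p = _hexagon(o, normal_p, rng)
        # hexagon positions are unordered vs the template names; any
        # assignment is geometrically equivalent for ring perception
        add_residue("PHE", [("CA", "C", o + (0.0, -4.5, -1.0))]
                    + [(n, "C", p) for n, p in zip(phe_names, ring_p)])
        a = math.radians(angle)
        normal_l = np.array([math.sin(a), 0.0, math.cos(a)])
        centroid_l = o + np.array([offset, 0.0, height])
        ring_l = _hexagon(centroid_l, normal_l, rng)
        idx = [add_ligand_atom(f"C{10 * (k + 1) + j}", "C", p)
               for j, p in enumerate(ring_l)]
        ligand_bonds += [(idx[j], idx[(j + 1) % 6]) for j in range(6)]
        truth["stacks"].append({"class": klass, "distance": distance,
                                "angle": angle, "offset": offset})

    if not ligand:
        # degenerate zero-interaction spec still needs a ligand atom,
        # placed far from every protein atom
        o = origin()
        add_ligand_atom("C99", "C", o + (0.0, 0.0, 50.0))
        add_residue("ALA", [("CA", "C", o), ("CB", "C", o + (0.0, 0.0, 1.5))])

    cx = StructureComplex(protein=protein, ligand=ligand,
                          ligand_bonds=ligand_bonds,
                          source=f"synthetic_complex_seed{spec.seed}")

    # independent geometric census (plain pairwise distances)
    pc = np.array([a.pos for a in protein])
    lc = np.array([a.pos for a in ligand])
    dmat = np.linalg.norm(pc[:, None, :] - lc[None, :, :], axis=-1)
    polar_p = np.array([a.element in ("N", "O", "S") for a in protein])
    polar_l = np.array([a.element in ("N", "O", "S") for a in ligand])
    both_polar = polar_p[:, None] & polar_l[None, :]
    n_hb = int(np.sum((dmat <= 3.5) & both_polar))
    n_cc = int(np.sum(dmat <= 4.0)) - int(np.sum((dmat <= 3.5) & both_polar))
    truth["census_hbonds"] = n_hb
    truth["census_close_contacts"] = n_hb + n_cc
    truth["census_aromatic"] = len(spec.stacks)
    return cx, truth


# ---------------------------------------------------------------------------
# Docking score table generator
# ---------------------------------------------------------------------------

def gen_docking_table(n_groups: int = 12, per_group: int = 5,
                      base_dg: Sequence[float] | None = None,
                      noise_sd: float = 0.15,
                      n_outliers: int = 1,
                      outlier_shift: float = -3.0,
                      outlier_kind: str = "dg",
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-scaffold docking score table with planted outliers.

    Inlier scores sit on evenly spaced symmetric offsets around each group
    mean (scaled by ``noise_sd``, shuffled, plus a small jitter), which
    bounds the group spread so Tukey whiskers can never flag an inlier;
    planted outliers are displaced by ``outlier_shift`` kcal/mol (kind
    "dg") or given an anomalously small heavy-atom count (kind "le").
    Deterministic under seed.
    """
    if per_group < 2:
        raise ValueError("per_group must be >= 2")
    if outlier_kind not in ("dg", "le"):
        raise ValueError("outlier_kind must be 'dg' or 'le'")
    rng = np.random.default_rng(seed)
    if base_dg is None:
        base_dg = np.linspace(-9.0, -6.5, n_groups)
    if len(base_dg) != n_groups:
        raise ValueError("one base dG per group required")
    outlier_groups = rng.choice(n_groups, size=min(n_outliers, n_groups),
                                replace=False)
    rows = []
    truth = {"outliers": [], "outlier_kind": outlier_kind, "seed": seed}
    for g in range(n_groups):
        heavy = int(rng.integers(20, 31))
        n_out = int(np.sum(outlier_groups == g))
        n_in = per_group - n_out
        offsets = (np.linspace(-1.0, 1.0, n_in) if n_in > 1
                   else np.zeros(1)) * noise_sd
        rng.shuffle(offsets)
        jitter = rng.uniform(-0.05, 0.05, size=per_group) * noise_sd
        member = 0
        for j in range(per_group):
            cid = f"G{g:02d}_M{j}"
            is_outlier = j == per_group - 1 and n_out > 0
            if is_outlier and outlier_kind == "dg":
                score = base_dg[g] + outlier_shift + jitter[j]
                h = heavy
            elif is_outlier:
                score = base_dg[g] + jitter[j]
                h = max(4, heavy // 3)
            else:
                score = base_dg[g] + offsets[member] + jitter[j]
                h = heavy
                member += 1
            rows.append({"id": cid, "score": float(score),
                         "scaffold": f"scaffold_{g:02d}", "heavy_atoms": h})
            if is_outlier:
                truth["outliers"].append(cid)
    return pd.DataFrame(rows), truth
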