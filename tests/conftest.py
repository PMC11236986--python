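"""Shared fixtures and small independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from tg2screen.chem import Fingerprint, parse_smiles, tanimoto
from tg2screen.structure import Atom, StructureComplex


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1", mol_id="benzene")


@pytest.fixture(scope="session")
def ethanol():
    return parse_smiles("CCO", mol_id="ethanol")


def random_fingerprints(rng: np.random.Generator, n: int,
                        nbits: int = 64) -> list[Fingerprint]:
    """Small random bitsets for clustering oracles."""
    fps = []
    for _ in range(n):
        popcount = int(rng.integers(4, 20))
        bits = rng.choice(nbits, size=popcount, replace=False)
        fps.append(Fingerprint.from_bits(bits, nbits=nbits))
    return fps


def butina_bruteforce(fps, cutoff):
    """Independent brute-force sphere-exclusion reference.

    Rescans every remaining pair each round instead of maintaining
    neighbour lists: at each step the surviving item with the most
    surviving neighbours (distance <= cutoff, ties by input order) seeds a
    cluster and absorbs those neighbours.
    """
    unassigned = set(range(len(fps)))
    formed = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned
                        if j != i and 1.0 - tanimoto(fps[i], fps[j]) <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [best] + [j for j in sorted(unassigned)
                            if j != best
                            and 1.0 - tanimoto(fps[best], fps[j]) <= cutoff]
        formed.append((best, members))
        unassigned -= set(members)
    order = sorted(range(len(formed)), key=lambda k: (-len(formed[k][1]), k))
    return ([formed[k][1] for k in order], [formed[k][0] for k in order])


def rand_index(labels_a, labels_b) -> float:
    """Pairwise co-membership agreement between two labelings."""
    n = len(labels_a)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            agree += ((labels_a[i] == labels_a[j])
                      == (labels_b[i] == labels_b[j]))
    return agree / total


def make_atom(name, element, xyz, chain="A", res_id=1, res_name="ALA"):
    return Atom(name=name, element=element, chain=chain, res_id=res_id,
                res_name=res_name, xyz=tuple(float(c) for c in xyz))


def phe_ring_complex(ligand_centroid, ligand_normal, res_id=10,
                     extra_protein=(), extra_ligand=()):
    """A hand-built complex: one PHE ring in the z=0 plane (centroid at the
    origin) plus a six-carbon ligand ring at the given centroid/normal."""
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    r = 1.39
    protein = [make_atom(n, "C",
                         (r * np.cos(k * np.pi / 3), r * np.sin(k * np.pi / 3), 0.0),
                         res_id=res_id, res_name="PHE")
               for k, n in enumerate(names)]
    protein += list(extra_protein)
    normal = np.asarray(ligand_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    c = np.asarray(ligand_centroid, dtype=float)
    ligand = [make_atom(f"C{k + 1}", "C",
                        c + r * (np.cos(k * np.pi / 3) * u
                                 + np.sin(k * np.pi / 3) * v),
                        chain="L", res_name="LIG")
              for k in range(6)]
    ligand += list(extra_ligand)
    bonds = [(k, (k + 1) % 6) for k in range(6)]
    return StructureComplex(protein=protein, ligand=ligand,
                            ligand_bonds=bonds, source="constructed")
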