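"""Ingest of externally produced docking results and their statistics.

Docking itself is out of scope; this module reads scored poses (SDF with a
score property tag, or plain TSV score tables), compares poses with
reference coordinates, checks scores against experiment-derived binding
free energies, and aggregates per-scaffold boxplot statistics and outliers.
Scores are treated as binding free energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .activity import EnergyRecord, flag_group_outliers, ligand_efficiency

DEFAULT_SCORE_TAG = "minimizedAffinity"


@dataclass
class DockingResult:
    ligand_id: str
    coords: np.ndarray                # heavy-atom coordinates, Angstrom
    atom_names: list[str]
    score: float                      # kcal/mol
    rank: int = 1
    flexible_residues: tuple[str, ...] = ()
    scaffold: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite([self.score])):
            raise ValueError(f"{self.ligand_id!r}: non-finite score")
        if self.rank < 1:
            raise ValueError(f"{self.ligand_id!r}: rank must be >= 1")


def read_results(path: str | Path, score_tag: str = DEFAULT_SCORE_TAG,
                 flexible_residues: Sequence[str] = ("Q169",),
                 ) -> list[DockingResult]:
    """Read poses from an SDF file and rank them by score ascending.

    Ties keep file order. A pose without the score tag aborts with the tags
    that are available.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    poses = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        if not mol.HasProp(score_tag):
            available = sorted(mol.GetPropNames())
            raise ValueError(
                f"pose {i} lacks score tag {score_tag!r}; available: {available}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"pose_{i}"
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        names = [f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in mol.GetAtoms()]
        scaffold = mol.GetProp("scaffold") if mol.HasProp("scaffold") else None
        poses.append((float(mol.GetProp(score_tag)), i, name, coords, names,
                      scaffold))
    poses.sort(key=lambda p: (p[0], p[1]))
    return [DockingResult(ligand_id=name, coords=coords, atom_names=names,
                          score=score, rank=rank,
                          flexible_residues=tuple(flexible_residues),
                          scaffold=scaffold)
            for rank, (score, _, name, coords, names, scaffold)
            in enumerate(poses, start=1)]


def aggregate_scores(results: Sequence[DockingResult], top_k: int = 1
                     ) -> dict[str, float]:
    """One score per ligand from its ranked poses.

    ``top_k=1`` (default) takes the best-ranked pose; larger values average
    the top-k scores.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    by_ligand: dict[str, list[float]] = {}
    for r in sorted(results, key=lambda r: r.rank):
        by_ligand.setdefault(r.ligand_id, []).append(r.score)
    return {lid: float(np.mean(scores[:top_k]))
            for lid, scores in by_ligand.items()}


def read_score_table(path: str | Path) -> pd.DataFrame:
    """TSV/CSV score table with columns id, score, and optional scaffold /
    heavy_atoms."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score table lacks columns: {sorted(missing)}")
    return df


def pose_rmsd(pose: DockingResult, reference_coords: np.ndarray,
              reference_names: Sequence[str] | None = None) -> float:
    """Direct (non-superposed) heavy-atom RMSD against reference coordinates.

    The docked pose and the reference share the receptor frame, so no
    fitting is applied. Atoms are paired by name when reference names are
    given, otherwise by order; a count mismatch is an error.
    """
    ref = np.asarray(reference_coords, dtype=float)
    if reference_names is not None:
        if sorted(reference_names) != sorted(pose.atom_names):
            raise ValueError("atom-name sets differ between pose and reference")
        order = [list(reference_names).index(n) for n in pose.atom_names]
        ref = ref[order]
    if ref.shape != pose.coords.shape:
        raise ValueError(
            f"atom count mismatch: pose {pose.coords.shape[0]} vs "
            f"reference {ref.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((pose.coords - ref) ** 2, axis=1))))


def score_vs_experiment(dock: Mapping[str, float], exp: Mapping[str, float],
                        tol: float = 2.0) -> pd.DataFrame:
    """Per-compound difference between docking score and experimental dG.

    Both in kcal/mol; rows flagged when |dock - exp| exceeds ``tol``. The
    returned frame carries a ``max_abs_diff`` attribute.
    """
    shared = sorted(set(dock) & set(exp))
    if not shared:
        raise ValueError("no shared compound ids between docking and experiment")
    rows = []
    for cid in shared:
        diff = dock[cid] - exp[cid]
        rows.append({"id": cid, "dock_dg": dock[cid], "exp_dg": exp[cid],
                     "diff": diff, "flagged": abs(diff) > tol})
    df = pd.DataFrame(rows)
    df.attrs["max_abs_diff"] = float(df["diff"].abs().max())
    df.attrs["tol"] = tol
    return df


def scaffold_group_stats(scores: pd.DataFrame, whisker_k: float = 1.5,
                         dg_tol: float = 1.0, le_tol: float = 0.5,
                         ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-scaffold Tukey boxplot statistics and outliers for dG and LE.

    ``scores`` needs columns id, score, scaffold and (for LE) heavy_atoms.
    Returns a stats frame (one row per scaffold: median/Q1/Q3/whiskers for
    dG and, when available, LE) and the outlier sets:
    ``whisker_dg`` / ``whisker_le`` from points beyond whiskers, and
    ``deviation`` from the leave-one-out median rule (> ``dg_tol`` kcal/mol
    on dG or > ``le_tol`` on LE).
    """
    required = {"id", "score", "scaffold"}
    if required - set(scores.columns):
        raise ValueError(f"need columns {sorted(required)}")
    has_le = "heavy_atoms" in scores.columns
    stats_rows = []
    whisker_dg: list[str] = []
    whisker_le: list[str] = []
    groups: dict[str, list[EnergyRecord]] = {}
    for scaffold, grp in scores.groupby("scaffold", sort=False):
        dg = grp["score"].to_numpy(dtype=float)
        row: dict = {"scaffold": scaffold, "n": len(grp)}
        row.update(_tukey_stats("dg", dg, whisker_k))
        if len(grp) >= 2:
            lo, hi = row["dg_whisker_lo"], row["dg_whisker_hi"]
            whisker_dg += [str(i) for i, v in zip(grp["id"], dg)
                           if v < lo or v > hi]
        le = None
        if has_le:
            le = dg / grp["heavy_atoms"].to_numpy(dtype=float)
            row.update(_tukey_stats("le", le, whisker_k))
            if len(grp) >= 2:
                lo, hi = row["le_whisker_lo"], row["le_whisker_hi"]
                whisker_le += [str(i) for i, v in zip(grp["id"], le)
                               if v < lo or v > hi]
        stats_rows.append(row)
        groups[str(scaffold)] = [
            EnergyRecord(compound_id=str(cid), dg=float(d),
                         le=float(l) if le is not None else None)
            for cid, d, l in zip(grp["id"], dg,
                                 le if le is not None else dg)]
    deviation_flags = flag_group_outliers(groups, dg_tol=dg_tol, le_tol=le_tol)
    outliers = {
        "whisker_dg": whisker_dg,
        "whisker_le": whisker_le,
        "deviation": sorted({f.compound_id for f in deviation_flags}),
    }
    return pd.DataFrame(stats_rows), outliers


def _tukey_stats(prefix: str, values: np.ndarray, k: float) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return {
        f"{prefix}_median": float(med),
        f"{prefix}_q1": float(q1),
        f"{prefix}_q3": float(q3),
        f"{prefix}_whisker_lo": float(q1 - k * iqr),
        f"{prefix}_whisker_hi": float(q3 + k * iqr),
    }
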