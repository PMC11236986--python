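"""Potency filtering, IC50 -> binding free energy conversion, ligand
efficiency, and group-outlier rules.

The thermodynamic conversion is dG = R*T*ln(Kd / c) with the standard
reference concentration c = 1 M, R = 1.987e-3 kcal/(mol K) and T defaulting
to 298.15 K.  IC50 is used directly as Kd by default (the usual shortcut
when comparing assay potencies with docking energies); a Cheng-Prusoff
style correction factor can be supplied but defaults off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

R_KCAL = 1.987e-3  # kcal / (mol K)
STANDARD_CONC_M = 1.0
DEFAULT_TEMPERATURE_K = 298.15
NM_TO_M = 1e-9


@dataclass(frozen=True)
class ActivityRecord:
    """A measured potency: ``ic50`` in nM, with free-text provenance."""

    compound_id: str
    ic50: float  # nM
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.ic50 > 0):
            raise ValueError(
                f"{self.compound_id!r}: ic50 must be positive, got {self.ic50}")


@dataclass(frozen=True)
class EnergyRecord:
    """Thermodynamic view of a potency measurement.

    ``dg`` in kcal/mol; ``le`` = dg / heavy-atom count (kcal/mol per heavy
    atom); ``temperature`` in K.
    """

    compound_id: str
    dg: float
    le: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_K


@dataclass(frozen=True)
class OutlierFlag:
    compound_id: str
    group: str
    criterion: str   # "dg" or "le"
    value: float
    deviation: float
    threshold: float


def filter_actives(records: Sequence[ActivityRecord],
                   threshold: float = 500.0) -> list[ActivityRecord]:
    """Keep records with ic50 strictly below ``threshold`` (nM).

    Input order is preserved. Records with non-positive ic50 cannot be
    constructed; if raw (id, ic50) pairs are screened use
    :func:`records_from_pairs` which warns and rejects rather than drops
    silently.
    """
    if not (threshold > 0):
        raise ValueError(f"threshold must be positive, got {threshold}")
    return [r for r in records if r.ic50 < threshold]


def records_from_pairs(pairs: Iterable[tuple[str, float]],
                       source: str = "") -> tuple[list[ActivityRecord], list[str]]:
    """Build records from raw (id, ic50 nM) pairs; non-positive potencies are
    rejected with a warning and their ids returned."""
    records, rejected = [], []
    for cid, ic50 in pairs:
        if ic50 is None or not (ic50 > 0):
            logger.warning("rejecting %r: non-positive IC50 %r", cid, ic50)
            rejected.append(cid)
            continue
        records.append(ActivityRecord(compound_id=cid, ic50=float(ic50),
                                      source=source))
    return records, rejected


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy dG = R*T*ln(kd / 1 M) in kcal/mol.

    ``kd`` in molar. Strictly increasing in kd; exactly 0 at kd = 1 M.
    """
    if not (kd > 0):
        raise ValueError(f"kd must be positive, got {kd}")
    if not (temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature * math.log(kd / STANDARD_CONC_M)


def kd_from_dg(dg: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse of :func:`dg_from_kd` (kd in molar)."""
    return STANDARD_CONC_M * math.exp(dg / (R_KCAL * temperature))


def dg_from_ic50_nm(ic50_nm: float, temperature: float = DEFAULT_TEMPERATURE_K,
                    cheng_prusoff_factor: float = 1.0) -> float:
    """dG from an IC50 in nM, treating IC50 as Kd.

    ``cheng_prusoff_factor`` divides the IC50 (Kd = IC50 / (1 + [S]/Km));
    the default of 1.0 means IC50 is used as Kd directly.
    """
    return dg_from_kd(ic50_nm * NM_TO_M / cheng_prusoff_factor, temperature)


def ligand_efficiency(dg: float, heavy_atoms: int) -> float:
    """Binding free energy per heavy atom (kcal/mol per heavy atom)."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return dg / heavy_atoms


def energy_records(records: Sequence[ActivityRecord],
                   heavy_atoms: Mapping[str, int] | None = None,
                   temperature: float = DEFAULT_TEMPERATURE_K,
                   ) -> list[EnergyRecord]:
    """Convert activity records to energy records (IC50 treated as Kd)."""
    out = []
    for r in records:
        dg = dg_from_ic50_nm(r.ic50, temperature)
        le = None
        if heavy_atoms is not None and r.compound_id in heavy_atoms:
            le = ligand_efficiency(dg, heavy_atoms[r.compound_id])
        out.append(EnergyRecord(compound_id=r.compound_id, dg=dg, le=le,
                                temperature=temperature))
    return out


def _loo_median_deviation(values: np.ndarray) -> np.ndarray:
    """|v_i - median(values without i)| for each member."""
    n = len(values)
    devs = np.empty(n)
    for i in range(n):
        others = np.delete(values, i)
        devs[i] = abs(values[i] - np.median(others))
    return devs


def flag_group_outliers(groups: Mapping[str, Sequence[EnergyRecord]],
                        dg_tol: float = 1.0,
                        le_tol: float = 0.5) -> list[OutlierFlag]:
    """Flag members deviating from the rest of their group.

    A member is flagged on ``dg`` when its binding free energy deviates by
    more than ``dg_tol`` kcal/mol from the median of the *other* members,
    and analogously on ``le`` with ``le_tol``. Singleton groups are skipped
    with a warning. Each flag records which criterion fired.
    """
    flags: list[OutlierFlag] = []
    for gid, members in groups.items():
        if len(members) < 2:
            logger.warning("group %r has < 2 members; skipped", gid)
            continue
        dg = np.array([m.dg for m in members], dtype=float)
        for i, dev in enumerate(_loo_median_deviation(dg)):
            if dev > dg_tol:
                flags.append(OutlierFlag(members[i].compound_id, gid, "dg",
                                         dg[i], float(dev), dg_tol))
        if all(m.le is not None for m in members):
            le = np.array([m.le for m in members], dtype=float)
            for i, dev in enumerate(_loo_median_deviation(le)):
                if dev > le_tol:
                    flags.append(OutlierFlag(members[i].compound_id, gid, "le",
                                             le[i], float(dev), le_tol))
    return flags


def tukey_outliers(values: Sequence[float], k: float = 1.5) -> list[int]:
    """Indices of points outside the Tukey boxplot whiskers (k * IQR)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return []
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [i for i, x in enumerate(v) if x < lo or x > hi]
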