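"""Orchestration of the two workflows: library triage and structure profiling.

Stage products are flat TSV/CSV files plus a JSON manifest that records
every parameter and the record counts entering and leaving each stage, so a
run can be audited and diffed. Reruns with the same config and seed are
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import activity, chem, cluster, docking, scaffolds, structure
from .structure import CavityDefinition, DEFAULT_CAVITIES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, with the screening protocol's values as
    defaults where the protocol fixes one (fingerprint radius 3 / 2048 bits,
    similarity threshold 0.3, IC50 cut 500 nM, scaffold min-counts 5 and 20,
    outlier tolerances 1.0 / 0.5 kcal/mol, score-vs-experiment 2.0
    kcal/mol)."""

    # inputs
    reference_smiles: str | None = None     # CSV/TSV: id, smiles, ic50_nM
    candidate_smiles: str | None = None     # CSV/TSV: id, smiles
    complexes: list[str] = field(default_factory=list)  # PDB paths
    ligand_selector: str = "LIG"
    score_table: str | None = None
    # chem/cluster parameters
    fp_radius: int = 3
    fp_nbits: int = 2048
    ic50_threshold_nm: float = 500.0
    similarity_threshold: float = 0.3
    butina_cutoff: float = 0.4
    top_k_clusters: int = 10
    min_count_reference: int = 5
    min_count_candidates: int = 20
    apply_pains: bool = True
    apply_ro5: bool = True
    # thermodynamics / outliers
    temperature_k: float = 298.15
    dg_tol: float = 1.0
    le_tol: float = 0.5
    score_exp_tol: float = 2.0
    # geometry
    hbond_max: float = 3.5
    contact_max: float = 4.0
    d_stack_max: float = 5.5
    angle_parallel_max: float = 30.0
    offset_parallel_max: float = 1.5
    angle_t_min: float = 60.0
    capture_radius: float = 4.0
    key_residues: tuple[str, ...] = structure.DEFAULT_KEY_RESIDUES
    # misc
    seed: int = 0
    out_dir: str = "tg2screen_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(out: Path, workflow: str, config: RunConfig,
                    stages: list[dict]) -> dict:
    manifest = {
        "workflow": workflow,
        "parameters": config.to_dict(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_triage(config: RunConfig,
               reference: tuple[list, list] | None = None,
               candidates: list | None = None) -> dict:
    """Library triage: activity filter -> fingerprints -> Butina clustering
    -> representatives -> similarity search -> PAINS/Ro5 -> scaffold tables
    -> scaffold overlap -> (optional) docking statistics.

    Inputs may come from the config paths or be passed in memory as
    ``reference=(molecules, activity_records)`` and ``candidates``
    (molecule list). Returns the manifest dict; all tables are written
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        stages.append({"stage": name, **info})

    # --- load inputs
    if reference is None:
        if not config.reference_smiles:
            raise ValueError("triage: no reference set supplied")
        mols, acts, rejected = chem.read_smiles_table(config.reference_smiles)
        records, bad = activity.records_from_pairs(acts.items())
        rejected += bad
    else:
        mols, records = reference
        rejected = []
    stage("load_reference", n_in=len(mols) + len(rejected), n_out=len(mols),
          rejected=rejected)

    if candidates is None:
        cand_mols = []
        if config.candidate_smiles:
            cand_mols, _, cand_rejected = chem.read_smiles_table(
                config.candidate_smiles, activity_col=None)
            stage("load_candidates", n_out=len(cand_mols),
                  rejected=cand_rejected)
    else:
        cand_mols = candidates
        stage("load_candidates", n_out=len(cand_mols))

    # --- activity filter
    actives = activity.filter_actives(records, config.ic50_threshold_nm)
    active_ids = {r.compound_id for r in actives}
    active_mols = [m for m in mols if m.id in active_ids]
    stage("filter_actives", threshold_nm=config.ic50_threshold_nm,
          n_in=len(records), n_out=len(actives))

    # --- clustering of the active reference set
    fps = [chem.circular_fingerprint(m, config.fp_radius, config.fp_nbits)
           for m in active_mols]
    assignment = cluster.butina_cluster(fps, cutoff=config.butina_cutoff,
                                        ids=[m.id for m in active_mols])
    top_k = min(config.top_k_clusters, assignment.n_clusters)
    reps = cluster.select_representatives(assignment, top_k)
    pd.DataFrame(
        [{"compound_id": cid, "cluster": k, "is_centroid": cid == assignment.centroids[k]}
         for k, members in enumerate(assignment.clusters) for cid in members]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    stage("butina_cluster", cutoff=config.butina_cutoff,
          n_in=len(fps), n_clusters=assignment.n_clusters,
          representatives=list(reps))

    # --- similarity search of candidates against the representatives
    hits = []
    hit_mols = []
    if cand_mols:
        rep_mols = [m for m in active_mols if m.id in set(reps)]
        hits = cluster.similarity_search(
            rep_mols, cand_mols, threshold=config.similarity_threshold,
            radius=config.fp_radius, nbits=config.fp_nbits)
        hit_ids = {h.candidate_id for h in hits}
        hit_mols = [m for m in cand_mols if m.id in hit_ids]
        pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
            out / "similarity_hits.tsv", sep="\t", index=False)
    stage("similarity_search", threshold=config.similarity_threshold,
          n_in=len(cand_mols), n_out=len(hits))

    # --- PAINS / Ro5 filters on the hits
    filtered = hit_mols
    if config.apply_pains and filtered:
        patterns = chem.load_patterns()
        filtered = [m for m in filtered if not chem.pains_match(m, patterns)]
    stage("pains_filter", enabled=config.apply_pains,
          n_in=len(hit_mols), n_out=len(filtered))
    n_in_ro5 = len(filtered)
    if config.apply_ro5 and filtered:
        filtered = [m for m in filtered
                    if chem.ro5_pass(chem.descriptors(m))]
    stage("ro5_filter", enabled=config.apply_ro5, n_in=n_in_ro5,
          n_out=len(filtered))

    # --- scaffold mining on both sets
    ref_table = scaffolds.scaffold_frequency(
        active_mols, min_count=config.min_count_reference, label="reference")
    cand_table = scaffolds.scaffold_frequency(
        filtered, min_count=config.min_count_candidates, label="candidates")
    for table, fname in ((ref_table, "scaffolds_reference.tsv"),
                         (cand_table, "scaffolds_candidates.tsv")):
        pd.DataFrame([{"scaffold_smiles": r.scaffold_smiles,
                       "frequency": r.frequency,
                       "member_ids": ",".join(r.member_ids)}
                      for r in table.rows]).to_csv(out / fname, sep="\t",
                                                   index=False)
    overlap = scaffolds.scaffold_overlap(ref_table, cand_table)
    stage("scaffold_frequency",
          min_count_reference=config.min_count_reference,
          min_count_candidates=config.min_count_candidates,
          n_reference_scaffolds=len(ref_table.rows),
          n_candidate_scaffolds=len(cand_table.rows),
          overlap=[s for s, _, _ in overlap])

    # --- optional docking statistics
    if config.score_table:
        scores = docking.read_score_table(config.score_table)
        stats, outliers = docking.scaffold_group_stats(
            scores, dg_tol=config.dg_tol, le_tol=config.le_tol)
        stats.to_csv(out / "scaffold_stats.tsv", sep="\t", index=False)
        stage("scaffold_group_stats", n_groups=len(stats),
              outliers=outliers)

    return _write_manifest(out, "triage", config, stages)


def run_profile(config: RunConfig,
                complexes: Sequence[structure.StructureComplex] | None = None,
                cavities: Sequence[CavityDefinition] = DEFAULT_CAVITIES,
                ) -> dict:
    """Structure profiling: contacts, aromatic interactions, cavity
    occupancy and the per-complex summary; with two or more structures also
    the cross-structure catalytic-residue deviations."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    if complexes is None:
        if not config.complexes:
            raise ValueError("profile: no complexes supplied")
        complexes = [structure.read_complex(p, config.ligand_selector)
                     for p in config.complexes]
    stages.append({"stage": "read_complexes", "n_out": len(complexes)})

    rows = []
    for cx in complexes:
        contacts = structure.close_contacts(cx, config.hbond_max,
                                            config.contact_max)
        aromatics = structure.aromatic_interactions(
            cx, config.d_stack_max, config.angle_parallel_max,
            config.offset_parallel_max, config.angle_t_min)
        classified = [a for a in aromatics if a.klass != "unclassified"]
        try:
            occ = structure.cavity_occupancy(cx, cavities,
                                             config.capture_radius)
            occupied = ",".join(occ.occupied)
            two_of_three = occ.meets_two_of_three
        except ValueError:
            occupied, two_of_three = "n/a", None
        rows.append({
            "complex": cx.source,
            "n_close_contacts": len(contacts),
            "n_hydrogen_bonds": sum(r.klass == "hydrogen_bond"
                                    for r in contacts),
            "n_aromatic": len(classified),
            "n_unclassified_aromatic": len(aromatics) - len(classified),
            "cavities_occupied": occupied,
            "two_of_three": two_of_three,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "interaction_summary.tsv", sep="\t", index=False)
    stages.append({"stage": "interaction_summary", "n_out": len(summary),
                   "cutoffs": {"hbond_max": config.hbond_max,
                               "contact_max": config.contact_max,
                               "d_stack_max": config.d_stack_max,
                               "angle_parallel_max": config.angle_parallel_max,
                               "offset_parallel_max": config.offset_parallel_max,
                               "angle_t_min": config.angle_t_min}})

    if len(complexes) >= 2:
        try:
            dev = structure.residue_deviations(
                list(complexes), residues=tuple(config.key_residues))
            dev.to_csv(out / "residue_deviations.tsv", sep="\t")
            stages.append({"stage": "residue_deviations",
                           "n_residues": len(dev)})
        except ValueError as exc:
            stages.append({"stage": "residue_deviations",
                           "skipped": str(exc)})
    return _write_manifest(out, "profile", config, stages)
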