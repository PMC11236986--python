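"""Butina sphere-exclusion clustering, representative selection, and
similarity search over circular fingerprints.

The clustering is the sphere-exclusion variant: at each round the
unassigned item with the most unassigned neighbours (Tanimoto distance
<= cutoff) seeds a new cluster and captures those neighbours. Ties are
broken by input order. This is written directly from that definition —
neighbour counts are recomputed over the surviving items each round — so
clusters are a true partition of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Fingerprint, Molecule, circular_fingerprint, tanimoto


@dataclass
class ClusterAssignment:
    """A partition of the input into clusters, largest first.

    ``clusters`` holds member indices into the input list (or ids when ids
    were supplied); ``centroids`` holds the seeding member of each cluster.
    """

    clusters: list[list]
    centroids: list
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


@dataclass(frozen=True)
class SimilarityHit:
    candidate_id: str
    reference_id: str
    similarity: float


def distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Pairwise Tanimoto-distance matrix (1 - similarity)."""
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    return d


def butina_cluster(fps: Sequence[Fingerprint], cutoff: float = 0.4,
                   ids: Sequence | None = None) -> ClusterAssignment:
    """Cluster fingerprints by sphere exclusion at a Tanimoto-distance cutoff.

    Returns clusters ordered by size descending (ties by formation order);
    items with no neighbours within the cutoff end up as singletons.
    """
    if len(fps) == 0:
        raise ValueError("butina_cluster requires at least one fingerprint")
    if not (0 < cutoff < 1):
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    n = len(fps)
    d = distance_matrix(fps)
    neighbours = [set(np.flatnonzero(d[i] <= cutoff)) - {i} for i in range(n)]

    unassigned = set(range(n))
    raw: list[tuple[int, list[int]]] = []  # (centroid, members)
    while unassigned:
        # most unassigned neighbours; ties -> lowest input index
        best = min(unassigned,
                   key=lambda i: (-len(neighbours[i] & unassigned), i))
        members = sorted(neighbours[best] & unassigned)
        cluster = [best] + [m for m in members if m != best]
        raw.append((best, cluster))
        unassigned -= set(cluster)

    order = sorted(range(len(raw)), key=lambda k: (-len(raw[k][1]), k))
    label = (lambda i: ids[i]) if ids is not None else (lambda i: i)
    return ClusterAssignment(
        clusters=[[label(i) for i in raw[k][1]] for k in order],
        centroids=[label(raw[k][0]) for k in order],
        cutoff=cutoff,
    )


def select_representatives(assignment: ClusterAssignment, top_k: int) -> list:
    """Centroids of the ``top_k`` largest clusters."""
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if top_k > assignment.n_clusters:
        raise ValueError(
            f"top_k={top_k} exceeds cluster count {assignment.n_clusters}")
    return assignment.centroids[:top_k]


def similarity_search(references: Sequence[Molecule],
                      candidates: Sequence[Molecule],
                      threshold: float = 0.3,
                      radius: int = 3, nbits: int = 2048,
                      ) -> list[SimilarityHit]:
    """Candidates whose best Tanimoto similarity to any reference reaches
    ``threshold``; the best-matching reference is reported per hit."""
    if not references or not candidates:
        raise ValueError("references and candidates must both be non-empty")
    ref_fps = [circular_fingerprint(m, radius, nbits) for m in references]
    hits = []
    for cand in candidates:
        cfp = circular_fingerprint(cand, radius, nbits)
        sims = [tanimoto(cfp, rfp) for rfp in ref_fps]
        best = int(np.argmax(sims))
        if sims[best] >= threshold:
            hits.append(SimilarityHit(candidate_id=cand.id,
                                      reference_id=references[best].id,
                                      similarity=float(sims[best])))
    return hits
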