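"""Phylotype reclassification from a phylogenetic tree / distance structure.

Sequences are reclassified by average-linkage hierarchical clustering of
alignment distances cut to k groups, with an outlier class (label ``T0``)
for tiny clusters and sequences far from their cluster mates — mirroring a
small "unclassifiable" group sitting apart on the tree.  Trees are built by
neighbor joining (exact on additive matrices) and serialized to Newick.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

import skbio
from skbio.tree import TreeNode

from .curation import ProteinRecord, make_aligner, pairwise_identity

__all__ = [
    "DistanceMatrix",
    "PhylotypeAssignment",
    "AssignResult",
    "PhylotypeCensus",
    "distance_matrix",
    "build_tree",
    "cut_phylotypes",
    "assign_phylotype",
    "phylotype_census",
]

POISSON_CAP = 10.0  # distance assigned when p-distance saturates at 1


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.d, ids=self.ids)

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])


@dataclass
class PhylotypeAssignment:
    labels: dict[str, str]
    k: int
    outlier_label: str = "T0"
    degenerate: bool = False

    def members(self, label: str) -> list[str]:
        return sorted(i for i, lab in self.labels.items() if lab == label)

    def regular_labels(self) -> list[str]:
        return sorted(
            {lab for lab in self.labels.values() if lab != self.outlier_label},
            key=lambda lab: int(lab[1:]),
        )


@dataclass(frozen=True)
class AssignResult:
    label: str
    distance: float
    tied: bool = False


def distance_matrix(
    seqs: list[ProteinRecord],
    correction: str = "p",
    matrix_name: str = "blosum62",
) -> DistanceMatrix:
    """Pairwise distances from global alignments.

    p-distance = 1 - identity/100; Poisson correction -ln(1 - p), capped at
    ``POISSON_CAP`` (with a warning) when p saturates at 1.
    """
    if len(seqs) < 3:
        raise ValueError("distance_matrix needs >= 3 sequences")
    if correction not in ("p", "poisson"):
        raise ValueError(f"correction must be 'p' or 'poisson', got {correction!r}")
    ordered = sorted(seqs, key=lambda r: r.id)
    ids = [r.id for r in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    aligner = make_aligner("global", matrix_name)
    n = len(ordered)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - pairwise_identity(ordered[i], ordered[j], aligner=aligner).pct_identity / 100.0
            if correction == "poisson":
                if p >= 1.0:
                    warnings.warn(
                        f"p-distance saturated for pair ({ids[i]}, {ids[j]}); "
                        f"capping Poisson distance at {POISSON_CAP}"
                    )
                    dist = POISSON_CAP
                else:
                    dist = -math.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids, d)


def build_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree over the matrix ids (exact on additive matrices)."""
    if len(dm.ids) < 3:
        raise ValueError("build_tree needs >= 3 taxa")
    return skbio.tree.nj(dm.to_skbio())


def cut_phylotypes(
    dm: DistanceMatrix,
    k: int,
    outlier_quantile: float = 0.95,
    min_cluster_size: int = 2,
    tree: TreeNode | None = None,
) -> PhylotypeAssignment:
    """Average-linkage clustering of the distances cut to *k* phylotypes.

    Clusters smaller than ``min_cluster_size``, and sequences whose mean
    within-cluster distance exceeds the ``outlier_quantile`` of the global
    pairwise-distance distribution, are routed to the outlier label (T0).
    Remaining clusters are labeled T1..Tk' by decreasing size (ties by the
    lexicographically smallest member).  The optional *tree* argument is
    accepted for workflows that carry one, but the partition is defined by
    the distances.
    """
    n = len(dm.ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of sequences ({n})")
    ordered = sorted(dm.ids)
    dm = dm.reorder(ordered)  # canonical order => permutation-stable labels
    condensed = squareform(dm.d, checks=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sch.ClusterWarning)
        linkage = sch.linkage(condensed, method="average")
    flat = sch.fcluster(linkage, t=k, criterion="maxclust")
    degenerate = len(set(flat)) < k

    clusters: dict[int, list[int]] = {}
    for idx, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(idx)

    cutoff = float(np.quantile(condensed, outlier_quantile)) if len(condensed) else 0.0
    outliers: set[int] = set()
    for members in clusters.values():
        if len(members) < min_cluster_size:
            outliers.update(members)
            continue
        for idx in members:
            others = [m for m in members if m != idx]
            if others and float(np.mean(dm.d[idx, others])) > cutoff:
                outliers.add(idx)

    regular = [
        sorted(m for m in members if m not in outliers)
        for members in clusters.values()
    ]
    regular = [members for members in regular if members]
    regular.sort(key=lambda members: (-len(members), ordered[members[0]]))

    labels: dict[str, str] = {ordered[i]: "T0" for i in outliers}
    for rank, members in enumerate(regular, start=1):
        for idx in members:
            labels[ordered[idx]] = f"T{rank}"
    return PhylotypeAssignment(labels=labels, k=k, degenerate=degenerate)


def assign_phylotype(
    seq: ProteinRecord,
    assignment: PhylotypeAssignment,
    refs: list[ProteinRecord],
    max_distance: float | None = None,
    correction: str = "p",
    matrix_name: str = "blosum62",
) -> AssignResult:
    """Label a new sequence by its nearest classified reference sequence.

    Distance above *max_distance* (when set) yields the outlier label.
    Exact distance ties across phylotypes break toward the smaller
    phylotype index and are flagged.
    """
    classified = [r for r in refs if r.id in assignment.labels]
    if not classified:
        raise ValueError("no classified reference sequences supplied")
    aligner = make_aligner("global", matrix_name)
    best: dict[str, float] = {}
    for ref in sorted(classified, key=lambda r: r.id):
        p = 1.0 - pairwise_identity(seq, ref, aligner=aligner).pct_identity / 100.0
        dist = p if correction == "p" else (POISSON_CAP if p >= 1 else -math.log(1 - p))
        label = assignment.labels[ref.id]
        if label not in best or dist < best[label] - 1e-12:
            best[label] = dist
    min_dist = min(best.values())
    tying = sorted(
        (lab for lab, dist in best.items() if abs(dist - min_dist) <= 1e-12),
        key=lambda lab: int(lab[1:]),
    )
    if max_distance is not None and min_dist > max_distance:
        return AssignResult(assignment.outlier_label, min_dist, tied=False)
    return AssignResult(tying[0], min_dist, tied=len(tying) > 1)


@dataclass
class PhylotypeCensus:
    table: pd.DataFrame  # phylotype, n_sequences, n_strains
    total_sequences: int
    same_phylotype_strains: int
    cross_phylotype_strains: int
    #: strain -> sorted list of (phylotype, count) for strains with >= 2 sequences
    paralog_profiles: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def phylotype_census(
    assignment: PhylotypeAssignment, strain_of: dict[str, str]
) -> PhylotypeCensus:
    """Sequence/strain counts per phylotype and the paralog cross-phylotype table.

    A strain with >= 2 classified sequences counts as "same phylotype" when
    all of them share one label and "cross phylotype" otherwise.
    """
    missing = [i for i in assignment.labels if i not in strain_of]
    if missing:
        raise ValueError(f"classified sequences without a strain: {missing[:5]}")
    rows = [
        {"sequence_id": i, "phylotype": lab, "strain_id": strain_of[i]}
        for i, lab in assignment.labels.items()
    ]
    frame = pd.DataFrame(rows)
    table = (
        frame.groupby("phylotype")
        .agg(n_sequences=("sequence_id", "nunique"), n_strains=("strain_id", "nunique"))
        .reset_index()
        .sort_values("phylotype", key=lambda s: s.str.slice(1).astype(int))
        .reset_index(drop=True)
    )
    profiles: dict[str, list[tuple[str, int]]] = {}
    same = cross = 0
    for strain, sub in frame.groupby("strain_id"):
        if len(sub) < 2:
            continue
        counts = sub["phylotype"].value_counts().sort_index()
        profiles[str(strain)] = list(counts.items())
        if counts.size == 1:
            same += 1
        else:
            cross += 1
    return PhylotypeCensus(
        table=table,
        total_sequences=int(table["n_sequences"].sum()),
        same_phylotype_strains=same,
        cross_phylotype_strains=cross,
        paralog_profiles=profiles,
    )
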