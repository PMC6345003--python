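"""Gene-catalog construction, read mapping, and relative abundance.

The relative abundance (RA) of gene g in individual i is the length-
normalized mapped count divided by the individual's total:

    RA(g, i) = (c(g, i) / L(g)) / sum_g' (c(g', i) / L(g'))

with L in amino acids (a nucleotide denominator would rescale every density
by 3 and cancel in the normalization).  Rows therefore sum to 1 for every
retained sample; zero-total samples are excluded and logged, never
silently zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import BSHHit, ProteinRecord, homology_screen, make_aligner, pairwise_identity

__all__ = [
    "GeneCatalog",
    "AbundanceMatrix",
    "CumulativeRA",
    "build_nr_catalog",
    "map_reads",
    "relative_abundance",
    "detect_family_members",
    "detection_fraction",
    "cumulative_ra",
]


@dataclass
class GeneCatalog:
    """Non-redundant clusters: (representative id, member ids) plus aa lengths."""

    clusters: list[tuple[str, list[str]]]
    lengths: dict[str, int]

    def representative_of(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]


@dataclass
class AbundanceMatrix:
    samples: list[str]
    genes: list[str]
    ra: pd.DataFrame  # samples x genes, rows sum to 1
    counts: pd.DataFrame  # samples x genes, mapped read counts
    excluded: list[str] = field(default_factory=list)


@dataclass
class CumulativeRA:
    grouping: str
    #: (group, population) -> aggregated per-individual group RA sum
    values: dict[tuple[str, str], float]
    per_sample: pd.DataFrame | None = None  # samples x groups


def build_nr_catalog(
    proteins: list[ProteinRecord],
    min_identity: float = 95.0,
    min_overlap: float = 90.0,
    matrix_name: str = "blosum62",
    kmer_prefilter: bool = True,
) -> GeneCatalog:
    """Greedy length-descending clustering into a non-redundant catalog.

    A protein joins the first existing representative it matches at
    >= min_identity over >= min_overlap percent of the shorter sequence,
    else founds a new cluster.  Deterministic: input sorted by
    (-length, id); representatives probed in founding order.  The k-mer
    prefilter (shared 8-mers) skips pairs that cannot reach the default
    95% identity / 90% overlap thresholds.
    """
    if not proteins:
        raise ValueError("build_nr_catalog requires a non-empty protein collection")
    from .curation import _shares_kmer

    aligner = make_aligner("local", matrix_name)
    ordered = sorted(proteins, key=lambda r: (-r.length, r.id))
    reps: list[ProteinRecord] = []
    clusters: list[tuple[str, list[str]]] = []
    for protein in ordered:
        joined = False
        for idx, rep in enumerate(reps):
            if kmer_prefilter and not _shares_kmer(rep.sequence, protein.sequence, k=8):
                continue
            res = pairwise_identity(rep, protein, aligner=aligner)
            overlap = 100.0 * res.aln_length / min(rep.length, protein.length)
            if res.pct_identity >= min_identity and overlap >= min_overlap:
                clusters[idx][1].append(protein.id)
                joined = True
                break
        if not joined:
            reps.append(protein)
            clusters.append((protein.id, [protein.id]))
    lengths = {r.id: r.length for r in proteins}
    return GeneCatalog(clusters=clusters, lengths=lengths)


def _kmer_index(gene_nt: dict[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gene_id, nt in gene_nt.items():
        for i in range(len(nt) - k + 1):
            index.setdefault(nt[i : i + k], set()).add(gene_id)
    return index


def map_reads(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    gene_nt: dict[str, str],
    k: int = 21,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each read to at most one gene by exact-substring best match.

    Candidate genes are found through a k-mer seed on the read; a candidate
    counts only if the read is an exact substring.  Ties go to the
    lexicographically smallest gene id.  Returns (counts samples x genes,
    unmapped counts per sample).  Malformed reads raise with context.
    """
    if not gene_nt:
        raise ValueError("gene catalog is empty")
    index = _kmer_index(gene_nt, k)
    genes = sorted(gene_nt)
    samples = sorted(reads_by_sample)
    counts = pd.DataFrame(0, index=samples, columns=genes, dtype=int)
    unmapped: dict[str, int] = {}
    for sample in samples:
        n_unmapped = 0
        for line_no, (read_id, seq) in enumerate(reads_by_sample[sample], start=1):
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(
                    f"malformed read {read_id!r} (sample {sample!r}, record {line_no})"
                )
            candidates: set[str] = set()
            for pos in (0, max(len(seq) - k, 0)):
                candidates |= index.get(seq[pos : pos + k], set())
            matches = sorted(g for g in candidates if seq in gene_nt[g])
            if matches:
                counts.loc[sample, matches[0]] += 1
            else:
                n_unmapped += 1
        unmapped[sample] = n_unmapped
    return counts, unmapped


def relative_abundance(
    counts: pd.DataFrame,
    lengths: dict[str, int],
    min_total: int = 1,
) -> AbundanceMatrix:
    """Length-normalized relative abundances from a samples x genes count matrix."""
    missing = [g for g in counts.columns if g not in lengths]
    if missing:
        raise ValueError(f"no length for genes: {missing}")
    length_vec = pd.Series({g: lengths[g] for g in counts.columns}, dtype=float)
    if (length_vec <= 0).any():
        bad = list(length_vec.index[length_vec <= 0])
        raise ValueError(f"non-positive lengths for genes: {bad}")
    totals = counts.sum(axis=1)
    excluded = list(totals.index[totals < min_total])
    kept = counts.loc[totals >= min_total]
    density = kept / length_vec
    ra = density.div(density.sum(axis=1), axis=0)
    return AbundanceMatrix(
        samples=list(kept.index),
        genes=list(kept.columns),
        ra=ra,
        counts=kept,
        excluded=excluded,
    )


def detect_family_members(
    sample_proteins: dict[str, list[ProteinRecord]],
    reference: list[ProteinRecord],
    min_identity: float = 62.0,
    min_score: float = 150.0,
    matrix_name: str = "blosum62",
) -> dict[str, set[str]]:
    """Per-sample detection of curated family members among sample proteins.

    A reference member is detected in a sample when some sample protein's
    best-hit query at the cutoff is that member.  The union over samples is
    the population-detected subset of the reference.
    """
    if not reference:
        raise ValueError("curated reference is empty")
    detected: dict[str, set[str]] = {}
    for sample, proteins in sorted(sample_proteins.items()):
        if not proteins:
            detected[sample] = set()
            continue
        hits = homology_screen(
            queries=reference,
            targets=proteins,
            min_identity=min_identity,
            min_score=min_score,
            matrix_name=matrix_name,
        )
        detected[sample] = {h.query_id for h in hits}
    return detected


def detection_fraction(detected_ids: set[str], reference_ids: set[str]) -> float:
    """Percent of the reference detected (e.g. 156 of 591 -> 26.40)."""
    if not reference_ids:
        raise ValueError("reference id set is empty")
    stray = detected_ids - reference_ids
    if stray:
        raise ValueError(f"detected ids outside the reference: {sorted(stray)[:5]}")
    return 100.0 * len(detected_ids) / len(reference_ids)


def cumulative_ra(
    abundance: AbundanceMatrix,
    sample_meta: pd.DataFrame,
    gene_groups: dict[str, str] | None = None,
    grouping: str = "genus",
    agg: str = "mean",
) -> CumulativeRA:
    """Per-population aggregate of within-sample RA sums over gene groups.

    ``grouping='all'`` pools every gene into one group.  Aggregation over a
    population's samples is the mean by default (``agg='sum'`` selectable);
    additivity over disjoint groups holds exactly either way.
    """
    if agg not in ("mean", "sum"):
        raise ValueError(f"agg must be 'mean' or 'sum', got {agg!r}")
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    missing_samples = [s for s in abundance.samples if s not in meta.index]
    if missing_samples:
        raise ValueError(f"samples without population labels: {missing_samples}")
    if grouping == "all":
        gene_groups = {g: "all" for g in abundance.genes}
    if gene_groups is None:
        raise ValueError("gene_groups is required unless grouping='all'")
    unlabeled = [g for g in abundance.genes if g not in gene_groups]
    if unlabeled:
        raise ValueError(f"genes without a group label: {unlabeled}")
    group_of = pd.Series({g: gene_groups[g] for g in abundance.genes})
    per_sample = abundance.ra.T.groupby(group_of).sum().T  # samples x groups
    populations = meta.loc[per_sample.index, "population"]
    aggregated = per_sample.groupby(populations).agg(agg)
    values = {
        (group, population): float(aggregated.loc[population, group])
        for population in aggregated.index
        for group in aggregated.columns
    }
    return CumulativeRA(grouping=grouping, values=values, per_sample=per_sample)
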