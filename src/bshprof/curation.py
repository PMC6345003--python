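"""Reference curation: length filtering, pairwise protein identity, homology
screening at an identity cutoff, and within/between-genus identity densities.

Identity is computed BLAST-style: identical aligned residue pairs divided by
the alignment length, with gap columns included in the denominator.  Local
(Smith-Waterman) alignment is the screening default; global (Needleman-
Wunsch) alignment is used for density analysis and distance estimation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinRecord",
    "IdentityResult",
    "IdentityDensity",
    "BSHHit",
    "filter_by_length",
    "pairwise_identity",
    "homology_screen",
    "identity_density",
    "read_fasta",
    "write_fasta",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: (gap open, gap extend) costs per matrix family; a gap of length k costs
#: open + k * extend, mirroring the BLASTP defaults for each matrix.
GAP_COSTS = {"blosum62": (11, 1), "blosum45": (15, 2)}


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence plus the taxonomy parsed from its strain name."""

    id: str
    sequence: str
    strain_id: str = ""
    genus: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IdentityResult:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    score: float


@dataclass
class IdentityDensity:
    """Within/between-genus identity values and a derived screening threshold.

    ``suggested_threshold`` is the grid point (1-point steps, ties resolved to
    the midpoint of the tying range) minimizing the count of within-genus
    values below it plus between-genus values at or above it.  When the
    between-genus list is empty the threshold is undefined and flagged.
    """

    within_genus_values: list[float]
    between_genus_values: list[float]
    suggested_threshold: float | None
    threshold_defined: bool = True


@dataclass(frozen=True)
class BSHHit:
    """A target sequence accepted by the homology screen, with its best query."""

    subject_id: str
    query_id: str
    pct_identity: float
    aln_length: int
    score: float
    strain_id: str = ""
    genus: str = ""


def make_aligner(mode: str = "local", matrix_name: str = "blosum62") -> PairwiseAligner:
    """Configure a PairwiseAligner with the documented gap costs for *matrix_name*."""
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    key = matrix_name.lower()
    if key not in GAP_COSTS:
        raise ValueError(f"unsupported matrix {matrix_name!r}; choose from {sorted(GAP_COSTS)}")
    gap_open, gap_extend = GAP_COSTS[key]
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(key.upper())
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _validate_sequence(record: ProteinRecord) -> None:
    # ProteinRecord validates at construction; raw strings are re-checked here
    bad = set(record.sequence) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters in {record.id!r}: {sorted(bad)}")


def _identity_from_alignment(alignment) -> tuple[float, int]:
    counts = alignment.counts()
    aln_length = counts.identities + counts.mismatches + counts.gaps
    if aln_length == 0:
        return 0.0, 0
    return 100.0 * counts.identities / aln_length, aln_length


def pairwise_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    mode: str = "global",
    matrix_name: str = "blosum62",
    aligner: PairwiseAligner | None = None,
) -> IdentityResult:
    """Percent identity of the optimal pairwise alignment of *a* and *b*.

    Empty local alignments (sequences with no positively scoring pairing)
    report identity 0 over alignment length 0.
    """
    _validate_sequence(a)
    _validate_sequence(b)
    if aligner is None:
        aligner = make_aligner(mode, matrix_name)
    alignments = aligner.align(a.sequence, b.sequence)
    if len(alignments) == 0:
        return IdentityResult(a.id, b.id, 0.0, 0, 0.0)
    best = alignments[0]
    pct, aln_length = _identity_from_alignment(best)
    return IdentityResult(a.id, b.id, pct, aln_length, float(best.score))


def filter_by_length(
    records: list[ProteinRecord], min_aa: int, max_aa: int
) -> list[ProteinRecord]:
    """Keep records with min_aa <= length <= max_aa (inclusive bounds)."""
    if min_aa > max_aa:
        raise ValueError(f"min_aa ({min_aa}) exceeds max_aa ({max_aa})")
    return [r for r in records if min_aa <= r.length <= max_aa]


def _shares_kmer(a: str, b: str, k: int = 5) -> bool:
    if len(a) < k or len(b) < k:
        return True  # too short for the prefilter to be meaningful
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def homology_screen(
    queries: list[ProteinRecord],
    targets: list[ProteinRecord],
    min_identity: float = 45.0,
    min_score: float = 150.0,
    mode: str = "local",
    matrix_name: str = "blosum45",
    kmer_prefilter: bool = False,
) -> list[BSHHit]:
    """Screen *targets* against *queries*; a target is a hit iff its best
    alignment to any query reaches ``min_identity`` and ``min_score``.

    Best-query ties are broken by higher identity, then longer alignment,
    then lexicographic query id.  The optional k-mer prefilter (shared
    5-mers >= 1) skips hopeless pairs; it never removes a pair that could
    pass a cutoff of >= 40% identity on sequences of family length.
    """
    if not queries or not targets:
        raise ValueError("homology_screen requires non-empty queries and targets")
    aligner = make_aligner(mode, matrix_name)
    hits: list[BSHHit] = []
    for target in targets:
        best: IdentityResult | None = None
        for query in sorted(queries, key=lambda r: r.id):
            if kmer_prefilter and not _shares_kmer(query.sequence, target.sequence):
                continue
            res = pairwise_identity(query, target, aligner=aligner)
            if best is None or (res.pct_identity, res.aln_length) > (
                best.pct_identity,
                best.aln_length,
            ):
                best = res
        if best is None:
            continue
        if best.pct_identity >= min_identity and best.score >= min_score:
            hits.append(
                BSHHit(
                    subject_id=target.id,
                    query_id=best.query_id,
                    pct_identity=best.pct_identity,
                    aln_length=best.aln_length,
                    score=best.score,
                    strain_id=target.strain_id,
                    genus=target.genus,
                )
            )
    return hits


def identity_density(
    records: list[ProteinRecord],
    mode: str = "global",
    matrix_name: str = "blosum45",
) -> IdentityDensity:
    """All within- and between-genus pairwise identities plus a threshold.

    Requires >= 2 genera with >= 2 sequences in at least one genus for a
    defined threshold; single-genus input yields an empty between list and a
    flagged, undefined threshold.
    """
    labelled = [r for r in records if r.genus]
    if len(labelled) < 2:
        raise ValueError("identity_density needs >= 2 genus-labelled records")
    aligner = make_aligner(mode, matrix_name)
    within: list[float] = []
    between: list[float] = []
    for a, b in itertools.combinations(sorted(labelled, key=lambda r: r.id), 2):
        pct = pairwise_identity(a, b, aligner=aligner).pct_identity
        (within if a.genus == b.genus else between).append(pct)
    if not between:
        return IdentityDensity(within, between, None, threshold_defined=False)
    best_overlap = None
    best_ts: list[int] = []
    for t in range(101):
        overlap = sum(v < t for v in within) + sum(v >= t for v in between)
        if best_overlap is None or overlap < best_overlap:
            best_overlap, best_ts = overlap, [t]
        elif overlap == best_overlap:
            best_ts.append(t)
    threshold = (best_ts[0] + best_ts[-1]) / 2.0
    return IdentityDensity(within, between, threshold)


def read_fasta(path) -> list[ProteinRecord]:
    from Bio import SeqIO

    return [ProteinRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[ProteinRecord], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for r in records:
            desc = descriptions.get(r.id, "")
            header = f">{r.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
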