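"""Synthetic data with plantable structure for every pipeline stage.

The generator is a stand-in for real reference proteomes and population
metagenomes: it plants a protein family with controllable within-genus and
between-genus identity, a configurable per-strain paralog-count (NP)
distribution, per-individual gene abundances, and cohort covariates with a
plantable population effect.  All randomness flows from a single master seed
via documented stream splitting (stream 0: reference set, stream 1:
metagenomes, stream 2: phenotype table; per-sample substreams are spawned
from stream 1 by sample index).

Generative model
----------------
Genus ancestors share a conserved position skeleton: each position is
"global" (identical across all genera), "pair" (identical within a genus
pair), or free.  The category probabilities are solved so that cross-pair
identity sits near the low between-genus mode and within-pair identity near
the high mode.  Strain genes mutate the genus ancestor at a per-position
rate calibrated so two strains of one genus meet the within-genus identity
target; paralogs are within-strain duplications with extra divergence.
All planted genes share one family length drawn from ``family_length_range``
so that global-alignment identity (gap columns in the denominator) is not
confounded by length differences; decoy lengths vary freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import ProteinRecord, write_fasta

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_reference_set",
    "generate_metagenomes",
    "generate_phenotype_table",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# one deterministic codon per amino acid for nucleotide back-translation
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

DEFAULT_PARALOG_DISTRIBUTION = {1: 0.7248, 2: 0.2349, 3: 0.0336, 4: 0.0067}


@dataclass
class SimConfig:
    seed: int = 0
    n_genera: int = 4
    strains_per_genus: int = 5
    family_length_range: tuple[int, int] = (300, 400)
    within_genus_identity: float = 82.0
    between_genus_identity: tuple[float, ...] = (35.0, 50.0)
    paralog_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PARALOG_DISTRIBUTION)
    )
    n_decoys_per_strain: int = 2
    n_individuals_per_population: int = 5
    populations: tuple[str, ...] = ("US", "CN", "HZ")
    read_length: int = 90
    coverage_per_gene: float = 20.0
    #: factor -> {level -> multiplicative effect on family abundance}
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    disease_labels: tuple[str, ...] = ()
    disease_fraction: float = 0.0
    exact_quota: bool = True
    paralog_divergence: float = 0.005

    def validate(self) -> None:
        total = sum(self.paralog_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"paralog_distribution sums to {total}, not 1")
        if any(np_ < 1 for np_ in self.paralog_distribution):
            raise ValueError("paralog counts must be >= 1")
        idents = [self.within_genus_identity, *self.between_genus_identity]
        if any(not (0 < v < 100) for v in idents):
            raise ValueError("identity targets must lie in (0, 100)")
        if self.within_genus_identity <= max(self.between_genus_identity):
            raise ValueError(
                "within-genus identity target must exceed every between-genus mode"
            )
        lo, hi = self.family_length_range
        if lo <= 0 or lo > hi:
            raise ValueError(f"bad family_length_range {self.family_length_range}")
        for name, value in [
            ("n_genera", self.n_genera),
            ("strains_per_genus", self.strains_per_genus),
            ("n_individuals_per_population", self.n_individuals_per_population),
            ("read_length", self.read_length),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    def n_strains(self) -> int:
        return self.n_genera * self.strains_per_genus


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, keyed by ids in the outputs."""

    planted_bsh: dict[str, list[str]] = field(default_factory=dict)  # strain -> gene ids
    phylotype: dict[str, str] = field(default_factory=dict)  # gene id -> clade label
    gene_sequences: dict[str, str] = field(default_factory=dict)  # family gene id -> aa seq
    background_sequences: dict[str, str] = field(default_factory=dict)  # decoy id -> aa seq
    gene_nt: dict[str, str] = field(default_factory=dict)  # any gene id -> back-translation
    strain_names: dict[str, str] = field(default_factory=dict)  # strain id -> raw name
    genus_of_strain: dict[str, str] = field(default_factory=dict)
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> gene -> depth weight
    metadata: pd.DataFrame | None = None

    def all_gene_ids(self) -> list[str]:
        return sorted(self.gene_sequences)


def _quota_allocation(distribution: dict[int, float], n: int) -> dict[int, int]:
    """Largest-remainder (Hamilton) apportionment of *n* strains over NP classes."""
    nps = sorted(distribution)
    exact = {np_: distribution[np_] * n for np_ in nps}
    counts = {np_: math.floor(exact[np_]) for np_ in nps}
    short = n - sum(counts.values())
    by_remainder = sorted(nps, key=lambda np_: (exact[np_] - counts[np_], np_), reverse=True)
    for np_ in by_remainder[:short]:
        counts[np_] += 1
    return counts


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability *rate* to a different residue."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def _solve_strain_rate(within_target: float) -> float:
    """Per-strain substitution rate d with (1-d)^2 + (2d(1-d)+d^2)/19 = target."""
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = (lo + hi) / 2
        value = (1 - mid) ** 2 + (2 * mid * (1 - mid) + mid * mid) / 19.0
        if value > within_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _genus_ancestors(
    config: SimConfig, length: int, rng: np.random.Generator, strain_rate: float = 0.0
) -> list[np.ndarray]:
    modes = sorted(config.between_genus_identity)
    match_p = 1.0 / len(AMINO_ACIDS)
    # Invert the strain-level identity model to ancestor agreement targets.
    # Two strain genes agree at a position with probability
    #   s = a * (1-d)^2 + (2d(1-d) + d^2) / 19
    # where a is the ancestor agreement probability and d the per-strain
    # substitution rate, so a = (s - noise) / survival.
    d = strain_rate
    survival = (1.0 - d) ** 2
    noise = (2 * d * (1 - d) + d * d) / 19.0
    adjust = lambda s: min(max((s - noise) / survival, 0.0), 0.97)
    low = adjust(modes[0] / 100.0)
    high = adjust(modes[-1] / 100.0)
    p_global = max((low - match_p) / (1 - match_p), 0.0)
    p_pair = max((high - low) / (1 - match_p), 0.0) if len(modes) > 1 else 0.0
    p_free = 1.0 - p_global - p_pair
    category = rng.choice(3, size=length, p=[p_global, p_pair, p_free])
    global_res = rng.choice(AMINO_ACIDS, size=length)
    ancestors = []
    n_pairs = (config.n_genera + 1) // 2
    pair_res = [rng.choice(AMINO_ACIDS, size=length) for _ in range(n_pairs)]
    for g in range(config.n_genera):
        seq = rng.choice(AMINO_ACIDS, size=length)
        seq[category == 0] = global_res[category == 0]
        seq[category == 1] = pair_res[g // 2][category == 1]
        ancestors.append(seq)
    return ancestors


def generate_reference_set(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[dict[str, list[ProteinRecord]], SyntheticTruth]:
    """Generate per-strain proteomes with planted family members and decoys.

    Returns ``(proteomes, truth)`` where *proteomes* maps strain id to its
    ProteinRecord list.  If *out_dir* is given, one FASTA per strain is
    written there (sequence ids carry the strain name as description, so
    taxonomy can be re-parsed from the files).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lo, hi = config.family_length_range
    length = int(rng.integers(lo, hi + 1))

    # per-strain divergence rate so two strains of one genus hit the target
    strain_rate = _solve_strain_rate(config.within_genus_identity / 100.0)
    ancestors = _genus_ancestors(config, length, rng, strain_rate=strain_rate)

    n_strains = config.n_strains()
    quota = _quota_allocation(config.paralog_distribution, n_strains)
    if config.exact_quota:
        np_values = [np_ for np_ in sorted(quota) for _ in range(quota[np_])]
        np_per_strain = rng.permutation(np.array(np_values, dtype=int))
    else:
        nps = sorted(config.paralog_distribution)
        probs = [config.paralog_distribution[np_] for np_ in nps]
        np_per_strain = rng.choice(nps, size=n_strains, p=probs)

    truth = SyntheticTruth()
    proteomes: dict[str, list[ProteinRecord]] = {}
    strain_index = 0
    for g in range(config.n_genera):
        genus = f"Simulatedgenus{chr(ord('A') + g % 26)}{g // 26 if g >= 26 else ''}".rstrip()
        for s in range(config.strains_per_genus):
            strain_id = f"S{g:02d}_{s:02d}"
            raw_name = f"{genus} species{s} STR-{g}{s}"
            truth.strain_names[strain_id] = raw_name
            truth.genus_of_strain[strain_id] = genus
            np_count = int(np_per_strain[strain_index])
            strain_index += 1
            base = _mutate(ancestors[g], strain_rate, rng)
            records: list[ProteinRecord] = []
            gene_ids: list[str] = []
            for k in range(np_count):
                gene = base if k == 0 else _mutate(base, config.paralog_divergence, rng)
                gene_id = f"{strain_id}|bsh{k + 1}"
                seq = "".join(gene)
                truth.gene_sequences[gene_id] = seq
                truth.phylotype[gene_id] = genus
                gene_ids.append(gene_id)
                records.append(
                    ProteinRecord(id=gene_id, sequence=seq, strain_id=strain_id, genus=genus)
                )
            truth.planted_bsh[strain_id] = gene_ids
            for k in range(config.n_decoys_per_strain):
                decoy_len = int(rng.integers(150, 451))
                seq = "".join(rng.choice(AMINO_ACIDS, size=decoy_len))
                decoy_id = f"{strain_id}|decoy{k + 1}"
                truth.background_sequences[decoy_id] = seq
                records.append(
                    ProteinRecord(
                        id=decoy_id, sequence=seq, strain_id=strain_id, genus=genus
                    )
                )
            proteomes[strain_id] = records

    for gene_id, seq in {**truth.gene_sequences, **truth.background_sequences}.items():
        truth.gene_nt[gene_id] = "".join(CODON_OF[aa] for aa in seq)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for strain_id, records in sorted(proteomes.items()):
            desc = {r.id: truth.strain_names[strain_id] for r in records}
            write_fasta(records, out_dir / f"{strain_id}.faa", descriptions=desc)
    return proteomes, truth


def _sample_covariates(rng: np.random.Generator, config: SimConfig, population: str) -> dict:
    gender = str(rng.choice(["female", "male"]))
    age = float(np.round(rng.uniform(18, 70), 1))
    bmi = float(np.round(rng.normal(24, 2.5), 1))
    status = "healthy"
    if config.disease_labels and rng.random() < config.disease_fraction:
        status = str(rng.choice(list(config.disease_labels)))
    return {"population": population, "gender": gender, "age": age, "bmi": bmi, "status": status}


def _family_multiplier(config: SimConfig, covariates: dict) -> float:
    mult = 1.0
    for factor, levels in config.effect_sizes.items():
        level = covariates.get(factor)
        if level in levels:
            mult *= levels[level]
    return mult


def generate_metagenomes(
    config: SimConfig,
    truth: SyntheticTruth,
    out_dir: str | Path | None = None,
    abundance_weights: dict[str, float] | None = None,
    coverage_overrides: dict[str, float] | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Per-individual error-free read sets drawn from planted gene abundances.

    Reads are exact substrings of deterministic nucleotide back-translations
    of both family genes and background (decoy) genes.  Per-gene read counts
    are Poisson with mean ``coverage_per_gene`` times the individual's
    planted abundance weight for the gene; planted weights are recorded in
    ``truth.abundances``.  Metadata covariates get planted ``effect_sizes``
    applied multiplicatively to *family* gene abundance only.

    *abundance_weights* fixes the per-gene weight vector for every
    individual (instead of per-individual lognormal draws);
    *coverage_overrides* sets per-gene coverage (0 allowed, meaning no
    reads for that gene).
    """
    config.validate()
    if config.coverage_per_gene <= 0:
        raise ValueError("coverage_per_gene must be positive")
    if coverage_overrides and any(c < 0 for c in coverage_overrides.values()):
        raise ValueError("per-gene coverage overrides must be >= 0")
    if not truth.gene_nt:
        raise ValueError("generate_reference_set must run before generate_metagenomes")
    gene_ids = sorted(truth.gene_nt)
    family = set(truth.gene_sequences)
    coverage_overrides = coverage_overrides or {}
    meta_rows = []
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    sample_index = 0
    for population in config.populations:
        for i in range(config.n_individuals_per_population):
            sample_id = f"{population}_{i:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1, sample_index])
            )
            sample_index += 1
            covariates = _sample_covariates(rng, config, population)
            meta_rows.append({"sample_id": sample_id, **covariates})
            mult = _family_multiplier(config, covariates)
            if abundance_weights is not None:
                weights = np.array([abundance_weights.get(g, 0.0) for g in gene_ids])
                rng.lognormal(mean=0.0, sigma=0.5, size=len(gene_ids))  # keep stream aligned
            else:
                weights = rng.lognormal(mean=0.0, sigma=0.5, size=len(gene_ids))
            weights = weights * np.array([mult if g in family else 1.0 for g in gene_ids])
            truth.abundances[sample_id] = dict(zip(gene_ids, weights))
            reads: list[tuple[str, str]] = []
            for gene_id, w in zip(gene_ids, weights):
                nt = truth.gene_nt[gene_id]
                n_positions = len(nt) - config.read_length + 1
                if n_positions <= 0:
                    continue
                coverage = coverage_overrides.get(gene_id, config.coverage_per_gene)
                n_reads = int(rng.poisson(coverage * w))
                starts = rng.integers(0, n_positions, size=n_reads)
                for start in sorted(starts.tolist()):
                    reads.append(
                        (
                            f"{sample_id}|r{len(reads):06d}",
                            nt[start : start + config.read_length],
                        )
                    )
            reads_by_sample[sample_id] = reads
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "population", "gender", "age", "bmi", "status"]
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample_id, reads in sorted(reads_by_sample.items()):
            with open(out_dir / f"{sample_id}.fasta", "w") as fh:
                for read_id, seq in reads:
                    fh.write(f">{read_id}\n{seq}\n")
        metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return reads_by_sample, metadata


INDICATORS = ("diabetes_death_rate", "cvd_death_rate", "mean_cholesterol", "obesity_bmi")


def generate_phenotype_table(
    config: SimConfig,
    truth: SyntheticTruth,
    link_indicator: str | None = None,
    link_target: float = 0.0,
) -> pd.DataFrame:
    """Country-level phenotype indicators, one row per population.

    When *link_indicator* is set, that column is generated with a monotone
    relationship to the population mean planted family abundance targeting a
    Spearman correlation of *link_target* (exact at +/-1, approximate in
    between); the other indicators are independent noise.
    """
    if len(config.populations) < 3:
        raise ValueError("need >= 3 populations for a usable phenotype table")
    if link_indicator is not None and link_indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {link_indicator!r}; choose from {INDICATORS}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    populations = list(config.populations)
    rows = {"population": populations}
    scales = {"diabetes_death_rate": 40, "cvd_death_rate": 300, "mean_cholesterol": 5, "obesity_bmi": 30}
    for name in INDICATORS:
        rows[name] = np.round(rng.uniform(0.5, 1.5, size=len(populations)) * scales[name], 2)
    table = pd.DataFrame(rows)
    if link_indicator is not None:
        pop_mean = _population_mean_family_abundance(config, truth, populations)
        ranks = pd.Series(pop_mean).rank().to_numpy()
        z = (ranks - ranks.mean()) / ranks.std(ddof=0)
        if abs(link_target) >= 1.0:
            values = np.sign(link_target) * ranks
        else:
            noise = rng.standard_normal(len(populations))
            values = link_target * z + math.sqrt(max(1 - link_target**2, 0.0)) * noise
        base = scales[link_indicator]
        values = base * (1.0 + 0.2 * (values - values.mean()) / (values.std(ddof=0) or 1.0))
        table[link_indicator] = np.round(values, 4)
    return table


def _population_mean_family_abundance(
    config: SimConfig, truth: SyntheticTruth, populations: list[str]
) -> list[float]:
    if not truth.abundances:
        raise ValueError("generate_metagenomes must run before a linked phenotype table")
    family = set(truth.gene_sequences)
    means = []
    for population in populations:
        totals = [
            sum(w for g, w in gene_weights.items() if g in family)
            for sample, gene_weights in truth.abundances.items()
            if sample.startswith(f"{population}_")
        ]
        means.append(float(np.mean(totals)) if totals else 0.0)
    return means
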