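"""End-to-end orchestration with deterministic, cacheable file-based stages.

Stages run in dependency order ``simulate -> curate -> census -> profile ->
phylotype -> associate``.  Every stage reads its inputs from files written by
upstream stages and records SHA-256 checksums of inputs and outputs in a
manifest; a stage whose parameter hash, input checksums, and output
checksums all match the previous manifest is skipped (cached).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    build_nr_catalog,
    cumulative_ra,
    map_reads,
    relative_abundance,
)
from .curation import (
    BSHHit,
    ProteinRecord,
    filter_by_length,
    homology_screen,
    read_fasta,
    write_fasta,
)
from .phylotyping import build_tree, cut_phylotypes, distance_matrix, phylotype_census
from .simulate import SimConfig, generate_metagenomes, generate_phenotype_table, generate_reference_set
from .stats import cohort_compare, multivariable_adjust, spearman_phenotype
from .taxonomy import genus_summary, load_phylum_lookup, paralog_census, parse_strain_taxonomy

__all__ = ["RunConfig", "RunManifest", "ValidationError", "StageError", "run_pipeline"]

STAGES = ("simulate", "curate", "census", "profile", "phylotype", "associate")


class ValidationError(ValueError):
    """Configuration rejected before any stage ran."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "bshprof_run"
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    curate: dict = field(default_factory=dict)
    census: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    phylotype: dict = field(default_factory=dict)
    associate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stages: {bad}")
        for key, block in [("curate", self.curate), ("profile", self.profile)]:
            for name in ("min_identity", "nr_identity", "nr_overlap", "detect_identity"):
                value = block.get(name)
                if value is not None and not (0 <= value <= 100):
                    raise ValidationError(f"{key}.{name} must be in [0, 100], got {value}")
        k = self.phylotype.get("k", 8)
        if k < 2:
            raise ValidationError(f"phylotype.k must be >= 2, got {k}")
        try:
            SimConfig(seed=self.seed, **self.simulate).validate()
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"simulate block invalid: {exc}") from exc


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: float
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "started": self.started,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )

    def output_files(self) -> list[str]:
        return sorted(
            path for stage in self.stages.values() for path in stage["outputs"]
        )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _checksum_map(root: Path, paths: list[Path]) -> dict[str, str]:
    return {str(p.relative_to(root)): _sha256(p) for p in sorted(paths)}


def _stage_cached(previous: dict | None, name: str, params_hash: str, root: Path) -> bool:
    if not previous or name not in previous.get("stages", {}):
        return False
    entry = previous["stages"][name]
    if entry.get("params_hash") != params_hash:
        return False
    for rel, digest in {**entry.get("inputs", {}), **entry.get("outputs", {})}.items():
        path = root / rel
        if not path.exists() or _sha256(path) != digest:
            return False
    return True


def _read_proteomes(proteome_dir: Path) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Read per-strain FASTAs; sequence descriptions carry the raw strain name."""
    from Bio import SeqIO

    records: list[ProteinRecord] = []
    strain_names: dict[str, str] = {}
    for path in sorted(proteome_dir.glob("*.faa")):
        strain_id = path.stem
        for rec in SeqIO.parse(str(path), "fasta"):
            raw_name = rec.description.split(" ", 1)[1] if " " in rec.description else strain_id
            strain_names[strain_id] = raw_name
            taxonomy = parse_strain_taxonomy(raw_name, strain_id=strain_id)
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    strain_id=strain_id,
                    genus=taxonomy.genus,
                )
            )
    return records, strain_names


def _read_reads_dir(reads_dir: Path) -> dict[str, list[tuple[str, str]]]:
    from Bio import SeqIO

    reads: dict[str, list[tuple[str, str]]] = {}
    for path in sorted(reads_dir.glob("*.fasta")):
        reads[path.stem] = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return reads


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the configured stages; halt on the first failure, naming the stage."""
    config.validate()
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    config_hash = _hash_obj(
        {f: getattr(config, f) for f in config.__dataclass_fields__}
    )
    previous = None
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)
    manifest = RunManifest(config_hash=config_hash, version=__version__, started=time.time())

    runners = {
        "simulate": _run_simulate,
        "curate": _run_curate,
        "census": _run_census,
        "profile": _run_profile,
        "phylotype": _run_phylotype,
        "associate": _run_associate,
    }
    for name in STAGES:
        if name not in config.stages:
            continue
        params = {"seed": config.seed, **getattr(config, name)}
        params_hash = _hash_obj(params)
        if _stage_cached(previous, name, params_hash, root):
            entry = dict(previous["stages"][name])
            entry["cached"] = True
            manifest.stages[name] = entry
            continue
        try:
            inputs, outputs = runners[name](config, root)
        except Exception as exc:  # halt; downstream outputs not emitted
            raise StageError(name, exc) from exc
        manifest.stages[name] = {
            "params_hash": params_hash,
            "inputs": _checksum_map(root, inputs),
            "outputs": _checksum_map(root, outputs),
            "cached": False,
        }
    manifest_path.write_text(manifest.to_json())
    return manifest


# --- stage implementations -------------------------------------------------


def _run_simulate(config: RunConfig, root: Path) -> tuple[list[Path], list[Path]]:
    sim = SimConfig(seed=config.seed, **config.simulate)
    proteome_dir = root / "proteomes"
    reads_dir = root / "reads"
    proteomes, truth = generate_reference_set(sim, out_dir=proteome_dir)
    _, metadata = generate_metagenomes(sim, truth, out_dir=reads_dir)
    phenotype = generate_phenotype_table(sim, truth)

    # one query per genus (the first planted gene of the first strain)
    queries = []
    seen_genera: set[str] = set()
    for strain_id in sorted(truth.planted_bsh):
        genus = truth.genus_of_strain[strain_id]
        if genus in seen_genera or not truth.planted_bsh[strain_id]:
            continue
        seen_genera.add(genus)
        gene_id = truth.planted_bsh[strain_id][0]
        queries.append(ProteinRecord(id=gene_id, sequence=truth.gene_sequences[gene_id]))
    write_fasta(queries, root / "queries.faa")

    pd.DataFrame(
        [(g, nt) for g, nt in sorted(truth.gene_nt.items())], columns=["gene_id", "nt"]
    ).to_csv(root / "gene_nt.tsv", sep="\t", index=False)
    phenotype.to_csv(root / "phenotype.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (strain, ";".join(genes), truth.genus_of_strain[strain])
            for strain, genes in sorted(truth.planted_bsh.items())
        ],
        columns=["strain_id", "planted_genes", "genus"],
    ).to_csv(root / "truth_planted.tsv", sep="\t", index=False)
    outputs = (
        sorted(proteome_dir.glob("*.faa"))
        + sorted(reads_dir.glob("*.fasta"))
        + [
            reads_dir / "metadata.tsv",
            root / "queries.faa",
            root / "gene_nt.tsv",
            root / "phenotype.tsv",
            root / "truth_planted.tsv",
        ]
    )
    return [], outputs


def _run_curate(config: RunConfig, root: Path) -> tuple[list[Path], list[Path]]:
    params = config.curate
    proteome_dir = Path(params.get("proteomes", root / "proteomes"))
    query_path = Path(params.get("queries", root / "queries.faa"))
    records, strain_names = _read_proteomes(proteome_dir)
    queries = read_fasta(query_path)
    candidates = filter_by_length(
        records, params.get("min_length", 300), params.get("max_length", 400)
    )
    hits = homology_screen(
        queries,
        candidates,
        min_identity=params.get("min_identity", 45.0),
        min_score=params.get("min_score", 150.0),
        matrix_name=params.get("matrix", "blosum45"),
    )
    hits_frame = pd.DataFrame(
        [
            (h.query_id, h.subject_id, round(h.pct_identity, 2), h.aln_length, h.score, h.strain_id, h.genus)
            for h in hits
        ],
        columns=["query_id", "subject_id", "pct_identity", "aln_length", "score", "strain_id", "genus"],
    )
    hits_frame.to_csv(root / "hits.tsv", sep="\t", index=False)
    by_id = {r.id: r for r in records}
    write_fasta([by_id[h.subject_id] for h in hits], root / "family.faa")
    pd.DataFrame(
        sorted(strain_names.items()), columns=["strain_id", "raw_name"]
    ).to_csv(root / "strains.tsv", sep="\t", index=False)
    inputs = sorted(proteome_dir.glob("*.faa")) + [query_path]
    return inputs, [root / "hits.tsv", root / "family.faa", root / "strains.tsv"]


def _load_hits(root: Path) -> list[BSHHit]:
    frame = pd.read_csv(root / "hits.tsv", sep="\t")
    return [
        BSHHit(
            subject_id=row.subject_id,
            query_id=row.query_id,
            pct_identity=row.pct_identity,
            aln_length=int(row.aln_length),
            score=float(row.score),
            strain_id=row.strain_id,
            genus=row.genus,
        )
        for row in frame.itertuples()
    ]


def _run_census(config: RunConfig, root: Path) -> tuple[list[Path], list[Path]]:
    hits = _load_hits(root)
    strains_frame = pd.read_csv(root / "strains.tsv", sep="\t")
    lookup = load_phylum_lookup()
    strains = [
        parse_strain_taxonomy(row.raw_name, strain_id=row.strain_id, phylum_lookup=lookup)
        for row in strains_frame.itertuples()
    ]
    census = paralog_census(hits)
    census.to_frame().to_csv(root / "census.tsv", sep="\t", index=False)
    genus_table, phylum_table = genus_summary(hits, strains)
    genus_table.to_csv(root / "genus_table.tsv", sep="\t", index=False)
    phylum_table.to_csv(root / "phylum_table.tsv", sep="\t", index=False)
    inputs = [root / "hits.tsv", root / "strains.tsv"]
    return inputs, [root / "census.tsv", root / "genus_table.tsv", root / "phylum_table.tsv"]


def _run_profile(config: RunConfig, root: Path) -> tuple[list[Path], list[Path]]:
    params = config.profile
    proteome_dir = Path(config.curate.get("proteomes", root / "proteomes"))
    records, _ = _read_proteomes(proteome_dir)
    catalog = build_nr_catalog(
        records,
        min_identity=params.get("nr_identity", 95.0),
        min_overlap=params.get("nr_overlap", 90.0),
    )
    pd.DataFrame(
        [(rep, m, catalog.lengths[m]) for rep, members in catalog.clusters for m in members],
        columns=["cluster_rep", "member", "length"],
    ).to_csv(root / "catalog.tsv", sep="\t", index=False)

    nt_frame = pd.read_csv(root / "gene_nt.tsv", sep="\t")
    nt_all = dict(zip(nt_frame["gene_id"], nt_frame["nt"]))
    gene_nt = {rep: nt_all[rep] for rep in catalog.representatives if rep in nt_all}
    reads_dir = root / "reads"
    reads = _read_reads_dir(reads_dir)
    counts, _ = map_reads(reads, gene_nt)
    counts.to_csv(root / "counts.tsv", sep="\t", index_label="sample_id")
    lengths = {rep: catalog.lengths[rep] for rep in gene_nt}
    abundance = relative_abundance(counts, lengths)
    abundance.ra.to_csv(root / "ra.tsv", sep="\t", index_label="sample_id")

    # detect family members among catalog representatives at the 62% rule
    family_ref = read_fasta(root / "family.faa")
    by_id = {r.id: r for r in records}
    rep_records = [by_id[rep] for rep in abundance.genes]
    hits62 = homology_screen(
        family_ref,
        rep_records,
        min_identity=params.get("detect_identity", 62.0),
        min_score=params.get("detect_min_score", 150.0),
        matrix_name="blosum62",
        kmer_prefilter=True,
    )
    family_reps = sorted({h.subject_id for h in hits62})

    meta = pd.read_csv(reads_dir / "metadata.tsv", sep="\t")
    strains = pd.read_csv(root / "strains.tsv", sep="\t")
    genus_of = {
        row.strain_id: parse_strain_taxonomy(row.raw_name, strain_id=row.strain_id).genus
        for row in strains.itertuples()
    }
    gene_groups = {
        g: (genus_of.get(g.split("|")[0], "unknown") if g in family_reps else "background")
        for g in abundance.genes
    }
    pd.DataFrame(
        [(g, gene_groups[g], int(g in family_reps)) for g in abundance.genes],
        columns=["gene_id", "group", "is_family"],
    ).to_csv(root / "gene_groups.tsv", sep="\t", index=False)
    cum = cumulative_ra(abundance, meta, gene_groups=gene_groups, grouping="genus")
    pd.DataFrame(
        [(grp, pop, val) for (grp, pop), val in sorted(cum.values.items())],
        columns=["group", "population", "value"],
    ).to_csv(root / "cumulative_ra.tsv", sep="\t", index=False)
    inputs = sorted(proteome_dir.glob("*.faa")) + [
        root / "family.faa",
        root / "gene_nt.tsv",
        root / "strains.tsv",
    ] + sorted(reads_dir.glob("*.fasta")) + [reads_dir / "metadata.tsv"]
    outputs = [
        root / "catalog.tsv",
        root / "counts.tsv",
        root / "ra.tsv",
        root / "gene_groups.tsv",
        root / "cumulative_ra.tsv",
    ]
    return inputs, outputs


def _run_phylotype(config: RunConfig, root: Path) -> tuple[list[Path], list[Path]]:
    params = config.phylotype
    family = read_fasta(root / "family.faa")
    dm = distance_matrix(family, correction=params.get("correction", "p"))
    tree = build_tree(dm)
    (root / "tree.nwk").write_text(str(tree).strip() + "\n")
    assignment = cut_phylotypes(
        dm,
        k=params.get("k", 8),
        outlier_quantile=params.get("outlier_quantile", 0.95),
        min_cluster_size=params.get("min_cluster_size", 2),
    )
    pd.DataFrame(
        sorted(assignment.labels.items()), columns=["sequence_id", "phylotype"]
    ).to_csv(root / "assignment.tsv", sep="\t", index=False)
    strain_of = {seq_id: seq_id.split("|")[0] for seq_id in assignment.labels}
    census = phylotype_census(assignment, strain_of)
    census.table.to_csv(root / "phylotype_census.tsv", sep="\t", index=False)
    inputs = [root / "family.faa"]
    outputs = [root / "tree.nwk", root / "assignment.tsv", root / "phylotype_census.tsv"]
    return inputs, outputs


def _run_associate(config: RunConfig, root: Path) -> tuple[list[Path], list[Path]]:
    params = config.associate
    ra = pd.read_csv(root / "ra.tsv", sep="\t", index_col="sample_id")
    meta = pd.read_csv(root / "reads" / "metadata.tsv", sep="\t")
    assignment = pd.read_csv(root / "assignment.tsv", sep="\t")
    phenotype = pd.read_csv(root / "phenotype.tsv", sep="\t")

    gene_groups = pd.read_csv(root / "gene_groups.tsv", sep="\t")
    family_genes = list(gene_groups.loc[gene_groups["is_family"] == 1, "gene_id"])

    rows = []
    family_ra = ra[[g for g in family_genes if g in ra.columns]].sum(axis=1).rename("ra")
    model_data = meta.set_index("sample_id").join(family_ra, how="inner")
    try:
        for res in multivariable_adjust(model_data.reset_index(), response="ra"):
            rows.append((res.factor, res.test_name, res.statistic, res.p_raw, res.q_fdr, res.variance_explained, res.n_used))
    except ValueError:
        pass  # too few samples or single-level factor at desk scale

    pop_ra = family_ra.groupby(meta.set_index("sample_id")["population"]).mean()
    indicator = params.get("indicator", "diabetes_death_rate")
    if len(pop_ra) >= 3:
        res = spearman_phenotype(pop_ra.to_dict(), phenotype, indicator)
        rows.append((res.factor, res.test_name, res.statistic, res.p_raw, res.q_fdr, None, res.n_used))

    label_of = dict(zip(assignment["sequence_id"], assignment["phylotype"]))
    family_in_ra = [g for g in family_genes if g in ra.columns]
    phylo_groups = {g: label_of.get(g, "T0") for g in family_in_ra}
    phylo_ra = ra[family_in_ra].T.groupby(pd.Series(phylo_groups)).sum().T
    statuses = set(meta["status"])
    disease = sorted(statuses - {"healthy"})
    if disease:
        for res in cohort_compare(phylo_ra, meta, contrast=("healthy", disease[0])):
            rows.append((res.factor, res.test_name, res.statistic, res.p_raw, res.q_fdr, None, res.n_used))

    pd.DataFrame(
        rows,
        columns=["factor", "test_name", "statistic", "p_raw", "q_fdr", "variance_explained", "n_used"],
    ).to_csv(root / "associations.tsv", sep="\t", index=False)
    inputs = [
        root / "ra.tsv",
        root / "gene_groups.tsv",
        root / "reads" / "metadata.tsv",
        root / "assignment.tsv",
        root / "phenotype.tsv",
    ]
    return inputs, [root / "associations.tsv"]
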