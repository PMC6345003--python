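"""Strain-name taxonomy parsing, paralog census, and genus/phylum rollups."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .curation import BSHHit

__all__ = [
    "StrainRecord",
    "ParalogCensus",
    "parse_strain_taxonomy",
    "paralog_census",
    "census_from_np_counts",
    "encoding_fraction",
    "genus_summary",
    "load_phylum_lookup",
]

_PHYLUM_LOOKUP_PATH = Path(__file__).parent / "data" / "genus_phylum.tsv"


@dataclass(frozen=True)
class StrainRecord:
    strain_id: str
    raw_name: str
    genus: str
    species: str = ""
    strain_token: str = ""
    phylum: str = ""
    parse_ok: bool = True


@dataclass
class ParalogCensus:
    """Per-strain family copy-number (NP) distribution and derived totals."""

    np_counts: dict[int, int]
    total_strains: int = field(init=False)
    total_sequences: int = field(init=False)
    pct_by_np: dict[int, float] = field(init=False)
    pct_multi: float = field(init=False)

    def __post_init__(self) -> None:
        if any(np_ < 1 or count < 0 for np_, count in self.np_counts.items()):
            raise ValueError(f"invalid np_counts {self.np_counts}")
        self.total_strains = sum(self.np_counts.values())
        self.total_sequences = sum(np_ * c for np_, c in self.np_counts.items())
        if self.total_strains:
            self.pct_by_np = {
                np_: round(100.0 * c / self.total_strains, 2)
                for np_, c in sorted(self.np_counts.items())
            }
            multi = sum(c for np_, c in self.np_counts.items() if np_ >= 2)
            self.pct_multi = round(100.0 * multi / self.total_strains, 2)
        else:
            self.pct_by_np = {}
            self.pct_multi = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "np": sorted(self.np_counts),
                "strain_count": [self.np_counts[np_] for np_ in sorted(self.np_counts)],
                "pct": [self.pct_by_np[np_] for np_ in sorted(self.np_counts)],
            }
        )


def _normalize_name(raw: str) -> str:
    name = raw.replace("_", " ")
    name = re.sub(r"[\[\]]", "", name)
    return re.sub(r"\s+", " ", name).strip()


def parse_strain_taxonomy(
    raw_name: str,
    strain_id: str | None = None,
    phylum_lookup: dict[str, str] | None = None,
) -> StrainRecord:
    """Parse "Genus species strain-token" from a strain name.

    Underscores and square brackets are normalized away.  Names with fewer
    than two tokens are flagged (``parse_ok=False``) rather than dropped.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("empty strain name")
    name = _normalize_name(raw_name)
    tokens = name.split(" ")
    genus = tokens[0]
    species = tokens[1] if len(tokens) > 1 else ""
    strain_token = " ".join(tokens[2:]) if len(tokens) > 2 else ""
    phylum = (phylum_lookup or {}).get(genus, "")
    return StrainRecord(
        strain_id=strain_id if strain_id is not None else name,
        raw_name=raw_name,
        genus=genus,
        species=species,
        strain_token=strain_token,
        phylum=phylum,
        parse_ok=len(tokens) >= 2,
    )


def load_phylum_lookup(path: str | Path | None = None) -> dict[str, str]:
    """Load the bundled (editable) genus -> phylum lookup table."""
    path = Path(path) if path is not None else _PHYLUM_LOOKUP_PATH
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["genus"], table["phylum"]))


def paralog_census(hits: list[BSHHit]) -> ParalogCensus:
    """Census NP per strain from screen hits (distinct subject ids per strain)."""
    by_strain: dict[str, set[str]] = {}
    for hit in hits:
        if not hit.strain_id:
            raise ValueError(f"hit {hit.subject_id!r} carries no strain_id")
        by_strain.setdefault(hit.strain_id, set()).add(hit.subject_id)
    np_counts: dict[int, int] = {}
    for members in by_strain.values():
        np_counts[len(members)] = np_counts.get(len(members), 0) + 1
    return ParalogCensus(np_counts)


def census_from_np_counts(np_counts: dict[int, int]) -> ParalogCensus:
    """Build a census directly from an NP -> strain-count table."""
    return ParalogCensus(dict(np_counts))


def encoding_fraction(hits: list[BSHHit], all_strains: list[StrainRecord]) -> float:
    """Percent of strains in the universe carrying >= 1 hit."""
    if not all_strains:
        raise ValueError("strain universe is empty")
    universe = {s.strain_id for s in all_strains}
    hit_strains = {h.strain_id for h in hits}
    missing = hit_strains - universe
    if missing:
        raise ValueError(f"hit strains absent from universe: {sorted(missing)}")
    return 100.0 * len(hit_strains) / len(universe)


def genus_summary(
    hits: list[BSHHit], strains: list[StrainRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genus and per-phylum counts of hit sequences and distinct strains.

    Tables are sorted by sequence count descending, ties lexicographic.
    """
    taxonomy = {s.strain_id: s for s in strains}
    rows = []
    for hit in hits:
        strain = taxonomy.get(hit.strain_id)
        rows.append(
            {
                "subject_id": hit.subject_id,
                "strain_id": hit.strain_id,
                "genus": strain.genus if strain else hit.genus,
                "phylum": strain.phylum if strain else "",
            }
        )
    if not rows:
        empty = pd.DataFrame(columns=["n_sequences", "n_strains"])
        return empty, empty.copy()
    frame = pd.DataFrame(rows).drop_duplicates("subject_id")

    def roll(level: str) -> pd.DataFrame:
        out = (
            frame.groupby(level)
            .agg(n_sequences=("subject_id", "nunique"), n_strains=("strain_id", "nunique"))
            .reset_index()
        )
        return out.sort_values(
            ["n_sequences", level], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)

    return roll("genus"), roll("phylum")
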