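import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from bshprof.curation import ProteinRecord
from bshprof.simulate import SimConfig, generate_metagenomes, generate_reference_set


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic reference set shared across read-only tests."""
    config = SimConfig(seed=11, n_genera=4, strains_per_genus=3, n_decoys_per_strain=2)
    proteomes, truth = generate_reference_set(config)
    return config, proteomes, truth


@pytest.fixture(scope="session")
def small_metagenomes(small_sim):
    config, proteomes, truth = small_sim
    reads, metadata = generate_metagenomes(config, truth)
    return config, truth, reads, metadata


@pytest.fixture
def family_records(small_sim):
    _, _, truth = small_sim
    return [
        ProteinRecord(
            id=g,
            sequence=s,
            strain_id=g.split("|")[0],
            genus=truth.phylotype[g],
        )
        for g, s in sorted(truth.gene_sequences.items())
    ]


def genus_queries(truth):
    """One planted gene per genus (the screen's query set)."""
    queries = []
    seen = set()
    for strain in sorted(truth.planted_bsh):
        genus = truth.genus_of_strain[strain]
        if genus in seen or not truth.planted_bsh[strain]:
            continue
        seen.add(genus)
        gid = truth.planted_bsh[strain][0]
        queries.append(ProteinRecord(id=gid, sequence=truth.gene_sequences[gid]))
    return queries
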