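import numpy as np
import pytest

from panoen.config import (CassetteLocusConfig, HgtSegmentConfig,
                           PhageInsertConfig, SimConfig)
from panoen.orthology import build_pan_loci
from panoen.pangenome import build_matrix
from panoen.simulate import simulate_collection

# prefilter strength used for genome-scale runs (library default stays 2)
GENOME_SCALE_KMERS = 8


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    base = dict(
        n_strains=6, n_core_genes=300, accessory_pool_size=60,
        cassette_loci=(CassetteLocusConfig(100, 3, 4),),
        phage_configs=(PhageInsertConfig(0, (1,), "full"),
                       PhageInsertConfig(1, (2,), "fragment"),
                       PhageInsertConfig(2, (3,), "full", copy_number=2)),
        hgt_segments=(HgtSegmentConfig("donorA", 5, (0, 4), 95.0),),
        n_trna_sites=4, n_paralog_pairs=5, n_tandem_dups=2,
        plasmid_strains=(1, 3), n_published_omitted=10, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """A 6-strain, 300-core-gene collection with one of everything."""
    return simulate_collection(small_sim_config())


@pytest.fixture(scope="session")
def small_loci(small_sim):
    return build_pan_loci(small_sim.strains,
                          min_shared_kmers=GENOME_SCALE_KMERS)


@pytest.fixture(scope="session")
def small_matrix(small_sim, small_loci):
    return build_matrix(small_loci, small_sim.strains, chromosomal_only=True)


@pytest.fixture(scope="session")
def default_run():
    """Study-scale conditions: 14 strains, ~1800 intact genes each.

    One shared run backs ortholog-recovery, pseudogene-classification
    and tree-recovery checks.
    """
    sim = simulate_collection(SimConfig(seed=1))
    loci = build_pan_loci(sim.strains, min_shared_kmers=GENOME_SCALE_KMERS)
    matrix = build_matrix(loci, sim.strains, chromosomal_only=True)
    return sim, loci, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
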