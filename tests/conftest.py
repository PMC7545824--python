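"""Shared fixtures: a small desk-scale genome, strains, and a mutant."""

import numpy as np
import pytest

from tetramap.genome import build_genome_model, synthesize_reference
from tetramap.simulate import SimConfig, mutagenize, spawn_strains


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Two 0.5 Mbp chromosomes, 4 genes; fast enough for per-test reuse."""
    return SimConfig(
        seed=7,
        n_chromosomes=2,
        chromosome_length=500_000,
        n_genes=4,
        n_background_snps=30,
        n_outcross_snps=60,
        n_mutations=12,
        causative_gene="g03",
        n_tetrads=5,
    )


@pytest.fixture(scope="session")
def small_model(small_cfg):
    return build_genome_model(small_cfg)


@pytest.fixture(scope="session")
def small_reference(small_model):
    return synthesize_reference(small_model, 7)


@pytest.fixture(scope="session")
def small_strains(small_cfg, small_model, small_reference):
    rng = np.random.default_rng(71)
    return spawn_strains(
        small_model,
        small_reference,
        n_outcross_snps=small_cfg.n_outcross_snps,
        n_background_snps=small_cfg.n_background_snps,
        seed=rng,
    )


@pytest.fixture(scope="session")
def small_mutant(small_cfg, small_model, small_reference, small_strains):
    background, _ = small_strains
    return mutagenize(
        background,
        small_model,
        small_reference,
        n_mutations=small_cfg.n_mutations,
        causative_gene=small_cfg.causative_gene,
        seed=72,
        strain_id="mutant",
    )
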