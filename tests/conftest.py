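"""Shared fixtures: small, fast study configurations and cached runs."""

from dataclasses import replace

import pytest

from trra.pipeline import PipelineConfig, run_pipeline
from trra.synthetic_data import SynthConfig, generate_genomes

# Desk-scale config for unit tests: small enough to run in milliseconds,
# large enough to exercise every code path.
SMALL = SynthConfig(
    n_genomes=10,
    n_redundant_groups=2,
    redundant_group_size=2,
    genes_per_genome=50,
    n_focal_genes=30,
    n_functional_groups=5,
    group_size=4,
    seed=1,
)

# Cleanly separable intergenic-distance classes: same-operon gaps can reach
# ~80 bp, boundaries start at 200 bp, so operon prediction can be exact.
SEPARABLE = replace(
    SMALL,
    intergenic_within=(40.0, 10.0, -20.0),
    intergenic_between=(400.0, 50.0, 200.0),
)

SMALL_PIPELINE = PipelineConfig(synth=SMALL, min_species=5)


@pytest.fixture(scope="session")
def small_genomes():
    return generate_genomes(SMALL)


@pytest.fixture(scope="session")
def separable_genomes():
    return generate_genomes(SEPARABLE)


@pytest.fixture(scope="session")
def small_run():
    return run_pipeline(SMALL_PIPELINE, seed=1)
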