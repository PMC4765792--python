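import numpy as np
import pytest

from allomirna.simulate import SimulationConfig, simulate_genomes, simulate_srna_libraries


TINY = dict(
    seed=5,
    n_chromosomes_per_subgenome=1,
    chromosome_length=150_000,
    n_mirna_loci_per_subgenome=10,
    n_protein_genes_per_chromosome=32,
    n_losses=2,
    n_gains=1,
    library_depth=30_000,
    n_cleavage_sites=10,
    mutation_rate=0.0,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """One small simulated dataset shared across tests (read-only)."""
    ga, gc, gt, ann, truth = simulate_genomes(tiny_config)
    return {
        "config": tiny_config, "A": ga, "C": gc, "tetraploid": gt,
        "annotations": ann, "truth": truth,
    }


@pytest.fixture(scope="session")
def tiny_libraries(tiny_dataset):
    return simulate_srna_libraries(
        tiny_dataset["truth"], tiny_dataset["tetraploid"], tiny_dataset["config"],
        rng=np.random.default_rng(6),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
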