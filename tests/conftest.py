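import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chipcompare.core import SimulationConfig
from chipcompare import simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


#: small-but-nontrivial scale used by most integration-style unit tests;
#: the acceptance suite exercises the full default scale
SMALL = dict(
    genome_length=4_000_000,
    n_genes=300,
    n_true_sites=60,
    n_reads=200_000,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=5, **SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One fully simulated small experiment shared across tests (read-only)."""
    return simulate.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_chrom_lengths(small_bundle):
    return {c: len(s) for c, s in small_bundle.genome.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_gene_table(rng, n, chrom="chrS", chrom_length=1_000_000):
    tss = rng.integers(5_000, chrom_length - 5_000, size=n)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n),
            "expression": rng.lognormal(1.0, 1.0, size=n),
        }
    )
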