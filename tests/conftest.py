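import numpy as np
import pandas as pd
import pytest

from biogeo import synth


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    """Scaled-down transect: fast enough for per-test use, still has all
    four latitude bands populated and every planted feature."""
    return synth.SynthConfig(
        n_sites=40,
        n_otus_per_domain={"bacteria": 80, "archaea": 60, "fungi": 50},
        n_specialists_per_region=2,
        n_cooc_blocks=2,
        block_size=5,
        sequencing_depth=5000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_meta(small_config):
    return synth.generate_metadata(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_meta):
    return synth.generate_community(small_config, small_meta, "bacteria")


@pytest.fixture(scope="session")
def small_taxonomy(small_config):
    return synth.generate_taxonomy(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_count_table(rng, n_samples=6, n_otus=10, high=50) -> pd.DataFrame:
    counts = rng.integers(0, high, size=(n_samples, n_otus))
    return pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"O{j}" for j in range(n_otus)],
    )
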