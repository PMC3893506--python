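import numpy as np
import pandas as pd
import pytest

from tempomir import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A modest bundle: fast enough for unit tests, rich enough to analyze."""
    return SyntheticConfig(
        n_genes=120,
        n_mirnas=20,
        n_true_pairs=12,
        decoys_per_mirna=10,
        n_pathways=5,
        pathway_size=10,
        n_pwms=12,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free bundle: every planted quantity is exact."""
    return generate_dataset(
        SyntheticConfig(
            n_genes=60,
            n_mirnas=10,
            n_true_pairs=6,
            decoys_per_mirna=5,
            n_pathways=4,
            pathway_size=8,
            n_pwms=8,
            noise_sd=0.0,
            seed=7,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def expr_frame(values, index=None, columns=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    if index is None:
        index = [f"f{i}" for i in range(values.shape[0])]
    if columns is None:
        columns = [f"t{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(index, name="feature_id"), columns=columns)
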