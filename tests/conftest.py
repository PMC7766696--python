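import numpy as np
import pytest

from rampgk import (
    CleaningConfig,
    SyntheticConfig,
    encode_dataset,
    generate_dataset,
    make_worked_example,
)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def tuned_cleaning():
    """Cleaning tuned per training set to the ~1:2 target ratio."""
    return CleaningConfig(target_ratio=2.0)


def null_config(seed: int) -> SyntheticConfig:
    """Balanced, signal-free dataset of roughly 400 sites."""
    return SyntheticConfig(
        num_proteins=60,
        length_range=(60, 200),
        positive_fraction=0.5,
        signal_strength=0.0,
        seed=seed,
    )


def strong_signal_config(seed: int) -> SyntheticConfig:
    """Strongly enriched local composition around positive sites."""
    return SyntheticConfig(
        num_proteins=70,
        length_range=(60, 200),
        positive_fraction=0.15,
        signal_strength=20.0,
        signal_residues=("A", "G", "S"),
        signal_window=7,
        seed=seed,
    )


@pytest.fixture(scope="session")
def strong_signal_features():
    """Encoded strong-signal dataset shared across tests (seed 1)."""
    dataset, _ = generate_dataset(strong_signal_config(seed=1))
    table, labels = encode_dataset(dataset, n=6)
    return table, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
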