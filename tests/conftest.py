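import numpy as np
import pytest

from snfnn import (
    HeterogeneousDataset,
    InteractionMatrix,
    ModelConfig,
    SimilarityMatrix,
    SyntheticConfig,
    generate_dataset,
)


def random_similarity(p: int, rng: np.random.Generator, name: str = "rand") -> SimilarityMatrix:
    values = rng.uniform(0.0, 1.0, size=(p, p))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix([f"e{i}" for i in range(p)], values, view_name=name)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def toy_y() -> InteractionMatrix:
    # 4 drugs x 3 diseases with a mix of profiles
    return InteractionMatrix(
        drug_ids=["r1", "r2", "r3", "r4"],
        disease_ids=["d1", "d2", "d3"],
        values=np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]]),
    )


@pytest.fixture
def tiny_model_config() -> ModelConfig:
    """Small network for fast unit tests of the training machinery."""
    return ModelConfig(
        n_hidden_layers=1, n_neurons=16, dropout_rate=0.0,
        batch_size=16, epochs=30, seed=5,
    )
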