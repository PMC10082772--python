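import numpy as np
import pytest

from octdenoise.experiments import (desk_dataset, evaluate_desk_model,
                                    train_desk_model)

DESK_SEED = 7


@pytest.fixture(scope="session")
def phantom_dataset():
    """Default phantom dataset: 10 train / 2 val / 10 eval, 100-frame averages."""
    return desk_dataset(seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_model(phantom_dataset):
    """U-Net (no residual, no top skip, n=4) trained with the reduced profile."""
    return train_desk_model(phantom_dataset, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_evaluation(desk_model, phantom_dataset):
    return evaluate_desk_model(desk_model.model, phantom_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
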