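import pytest

from pupilorbit import (
    DatasetConfig,
    GroundTruthModel,
    generate_ideal_dataset,
    generate_noise_dataset,
)

TRUE_ORCP = (250.0, 250.0)
TRUE_RADIUS = 250.0


@pytest.fixture(scope="session")
def model() -> GroundTruthModel:
    """Ground truth of the study geometry: 500x500 px space, center at
    (250, 250), orbit radius 250 px, pupil radius 50 px."""
    return GroundTruthModel(250.0, 250.0, 250.0, 50.0)


@pytest.fixture(scope="session")
def dataset_cfg() -> DatasetConfig:
    return DatasetConfig(seed=7)


@pytest.fixture(scope="session")
def ideal_dataset(model, dataset_cfg):
    return generate_ideal_dataset(model, dataset_cfg)


@pytest.fixture(scope="session")
def noise_dataset(dataset_cfg):
    return generate_noise_dataset(dataset_cfg)


@pytest.fixture(scope="session")
def mixed_dataset(ideal_dataset, noise_dataset):
    """100 ideal + 100 noise ellipses: the simulation study's dataset."""
    return ideal_dataset + noise_dataset
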