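import pytest

from soilmetal.core_io import BackgroundValues, DetectionLimits
from soilmetal.health_risk import (BioconcentrationFactors, ExposureParameters,
                                   ToxicologicalReference)
from soilmetal.pollution_indices import ToxicityCoefficients
from soilmetal.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One default paired-depth dataset with its ground truth."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def samples(default_dataset):
    return default_dataset[0]


@pytest.fixture(scope="session")
def truth(default_dataset):
    return default_dataset[1]


@pytest.fixture(scope="session")
def background():
    return BackgroundValues.load()


@pytest.fixture(scope="session")
def mdl():
    return DetectionLimits.load()


@pytest.fixture(scope="session")
def tox():
    return ToxicityCoefficients.load()


@pytest.fixture(scope="session")
def exposure():
    return ExposureParameters.load()


@pytest.fixture(scope="session")
def toxref():
    return ToxicologicalReference.load()


@pytest.fixture(scope="session")
def bcfs():
    return BioconcentrationFactors.load()
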