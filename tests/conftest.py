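import logging

import pytest

from pathpsn import (PSNClassifier, RunConfig, SimulationDesign,
                     generate_dataset)

logging.getLogger("pathpsn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dataset():
    """Default separable cohort: 40+40 patients, three planted pathways,
    one planted ncRNA target set, class-biased mutations."""
    return generate_dataset(SimulationDesign(seed=7))


@pytest.fixture(scope="session")
def fitted(dataset):
    """One full training fit on the separable cohort."""
    model = PSNClassifier.from_dataset(dataset, RunConfig(seed=7))
    return model.fit()
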