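import pytest

from gpprenatal import SimulationConfig, generate_dataset, make_manual_labels
from gpprenatal.phases import build_phase_calendar


@pytest.fixture(scope="session")
def calendar():
    return build_phase_calendar()


@pytest.fixture(scope="session")
def medium_dataset():
    """One moderately sized synthetic dataset shared across the suite."""
    config = SimulationConfig(n_patients=3000, seed=7)
    patients, contacts, truth = generate_dataset(config)
    return config, patients, contacts, truth


@pytest.fixture(scope="session")
def medium_manual_labels(medium_dataset):
    _, _, contacts, truth = medium_dataset
    return make_manual_labels(contacts, truth)
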