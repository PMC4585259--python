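import hypothesis
import pytest

from naviph.protocol import Protocol
from naviph.simulate import SimCohortConfig, class_preset, simulate_cohort

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def class_a():
    return class_preset("A")


@pytest.fixture(scope="session")
def noiseless_a_traces(class_a, protocol):
    cohort = SimCohortConfig(n_cells=2, noise_cv=0.0, seed=0)
    return simulate_cohort(class_a, cohort, protocol)


@pytest.fixture(scope="session")
def noisy_a_traces(class_a, protocol):
    cohort = SimCohortConfig(n_cells=5, noise_cv=0.03, seed=11)
    return simulate_cohort(class_a, cohort, protocol)
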