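import warnings

import pytest

from miaminer import ClassifierConfig, SimulationConfig, generate_study, run_pipeline

# Reduced-epoch training protocol used throughout the suite (the library
# default of 1500 epochs is the published protocol; 150 suffices for the
# planted signal and keeps the suite fast).
TEST_EPOCHS = 150


@pytest.fixture(scope="session")
def default_study():
    return generate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            default_study,
            classifier_config=ClassifierConfig(epochs=TEST_EPOCHS),
            run_cv=False,
        )
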