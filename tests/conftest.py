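import warnings

import pytest

from reefbudget import synth

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def palau_yap_realization():
    """One full two-island survey realization with its closed-form truth."""
    scenario = synth.palau_yap_scenario(seed=20180508)
    return synth.generate_survey_dataset(scenario)


@pytest.fixture(scope="session")
def traits():
    return synth.default_trait_table()
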