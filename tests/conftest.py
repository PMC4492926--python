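import pytest

from dxtrial import reference
from dxtrial.bayes_core import TestAccuracy
from dxtrial.synthetic_cohort import default_model_from_reference
from dxtrial.trial_analysis import ArmOutcomeTable


@pytest.fixture(scope="session")
def vignette_acc() -> TestAccuracy:
    return reference.VIGNETTE_ACCURACY


@pytest.fixture(scope="session")
def quiz_acc() -> TestAccuracy:
    return reference.QUIZ_ACCURACY


@pytest.fixture(scope="session")
def published_table() -> ArmOutcomeTable:
    return ArmOutcomeTable.from_reference()


@pytest.fixture(scope="session")
def default_model():
    return default_model_from_reference(seed=20120710)
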