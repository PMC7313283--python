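import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wearwell.scores import load_norms
from wearwell.synthetic import worked_example_fixture


@pytest.fixture(scope="session")
def norms():
    return load_norms()


@pytest.fixture(scope="session")
def golden_cohort():
    return worked_example_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20190301)
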