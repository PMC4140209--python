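import sys
from pathlib import Path

import numpy as np
import pytest

# make the sibling oracle module importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_cohorts():
    """Tiny separated-preset cohorts for fast sweep-shape tests."""
    from hrventropy.synthetic import make_study_fixture

    return make_study_fixture("separated", seed=7, n_records=8, record_length=320)
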