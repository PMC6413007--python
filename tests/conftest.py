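import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from topoqsar.fixtures import make_fixtures


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixtures(seed=7, n_random=8)


@pytest.fixture(scope="session")
def small_molecules(fixture_set):
    """Named fixture molecules with at most 12 heavy atoms."""
    return fixture_set.small(max_atoms=12)
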