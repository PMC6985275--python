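import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # tests.oracles

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from pks3evo.trees import parse_newick  # noqa: E402


@pytest.fixture
def species_abc():
    """((A,B),C) — the smallest asymmetric species tree."""
    return parse_newick("((A,B),C);")


@pytest.fixture
def caterpillar9():
    return parse_newick("((((((((A,B),C),D),E),F),G),H),I);")


@pytest.fixture(scope="session")
def sim_species16():
    from pks3evo.simulate import simulate_species_tree

    return simulate_species_tree(16, 1.0, 0.0, seed=20260929)
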