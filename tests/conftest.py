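import pytest

from aarsphylo import annotation_map, build_scaffold
from aarsphylo.synthetic_data import ScaffoldConfig


@pytest.fixture(scope="session")
def scaffold():
    return build_scaffold(ScaffoldConfig(seed=0))


@pytest.fixture(scope="session")
def scaffold_ann(scaffold):
    return scaffold.ann
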