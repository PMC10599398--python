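import numpy as np
import pytest

from intronbench.fixtures import FixtureSpec, build_bundle
from intronbench.metrics import ToolConfig


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic bundle: 10 event slots per gene, both strands."""
    return build_bundle(FixtureSpec(seed=7, n_slots=10))


@pytest.fixture(scope="session")
def bundle_tools(small_bundle):
    return [
        ToolConfig(t.name, t.name, reference_threshold=t.reference_threshold)
        for t in small_bundle.spec.tools
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
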