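import numpy as np
import pytest

from petscreen import synthetic
from petscreen.msa import AlignedSet


@pytest.fixture(scope="session")
def landscape():
    """Default planted landscape at a fixed seed."""
    return synthetic.default_landscape(seed=1)


@pytest.fixture
def small_alignment():
    return AlignedSet(
        ids=["ref", "homA", "homB"],
        rows=["ACDE", "ACFF", "AC-E"],
        ref_id="ref",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
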