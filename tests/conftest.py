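import numpy as np
import pytest

from ryseed import (
    IndexParams,
    PanelSequence,
    ReferencePanel,
    build_minimizer_index,
    build_rymer_index,
    random_panel,
)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_panel(rng):
    """Two short linear sequences plus one circular one."""
    return ReferencePanel([
        PanelSequence("lin1", random_dna(180, rng), False),
        PanelSequence("lin2", random_dna(150, rng), False),
        PanelSequence("circ", random_dna(120, rng), True),
    ])


@pytest.fixture(scope="session")
def mito_panel():
    """The shipped synthetic circular stand-in for a mitogenome."""
    return random_panel(seed=11)


@pytest.fixture(scope="session")
def mito_indexes(mito_panel):
    idx = build_minimizer_index(mito_panel, IndexParams(k=29, w=11))
    return idx, build_rymer_index(idx)
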