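import numpy as np
import pytest

import spikequant as sq


@pytest.fixture(scope="session")
def default_panel() -> sq.ISPanel:
    """One default-spec panel shared across the suite (design is deterministic)."""
    return sq.design_panel(sq.DesignSpec(), seed=11)


@pytest.fixture(scope="session")
def mock10(default_panel) -> sq.SampleComposition:
    return sq.preset("mock10", default_panel)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
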