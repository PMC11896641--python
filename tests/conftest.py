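import numpy as np
import pandas as pd
import pytest

import microstand as ms


@pytest.fixture
def small_table():
    """3 features x 2 samples with column sums (6, 9)."""
    return pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=pd.Index(["F1", "F2", "F3"], name="feature_id"),
        columns=["S1", "S2"],
    )


@pytest.fixture
def community():
    """One default synthetic community (4 ages x 5 replicates)."""
    cfg = ms.SimulationConfig(seed=42)
    return ms.generate_community(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
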