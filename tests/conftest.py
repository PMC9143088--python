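import numpy as np
import pytest

import seatherm as st


@pytest.fixture(scope="session")
def default_batch() -> st.BatchResult:
    """Full default 32-trial pipeline run at a fixed master seed.

    Session-scoped: simulate + EMD-FSI + LM training takes on the order
    of a minute, and several end-to-end checks share the result.
    """
    return st.run_batch(st.BatchConfig(master_seed=1))


@pytest.fixture()
def condition() -> st.TrialCondition:
    """The worked-example condition: low density, 5 cm."""
    return st.TrialCondition(density=10.8, thickness=5.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
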