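import numpy as np
import pytest

from calmod import session_io, synthgen


@pytest.fixture(scope="session")
def wt_session():
    """One seeded wild-type-like synthetic session."""
    cfg = synthgen.wildtype_config(seed=7, n_mice=1, sessions_per_mouse=1)
    return synthgen.generate_session(cfg, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def wt_result(wt_session):
    """Full pipeline output for the shared wild-type session."""
    return session_io.run_pipeline(wt_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
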