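import pytest

import cannakin as ck


@pytest.fixture(scope="session")
def default_model():
    """The shipped calibrated model under the default batch scenario."""
    return ck.build_default_model()


@pytest.fixture(scope="session")
def default_traj(default_model):
    """One full 40-h default run, shared by every test that only reads it."""
    return ck.simulate(default_model, t_end=40.0, dt_out=0.05)
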