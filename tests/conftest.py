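import numpy as np
import pytest
from hypothesis import settings

from cerloop.model import ModelParams

# property tests run the same example sequence everywhere
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_params(
    n_rnn=3,
    n_input=2,
    n_out=2,
    n_granule=4,
    n_windows=1,
    alpha=0.5,
    scale=0.3,
    activation="tanh",
    readout_feedback=False,
    seed=7,
):
    """Small dense random parameter set for hand-checkable oracles."""
    r = np.random.default_rng(seed)
    n_fb = n_out * n_windows
    return ModelParams(
        alpha=alpha,
        W_hh=r.normal(0, scale, (n_rnn, n_rnn)),
        W_ih=r.normal(0, scale, (n_rnn, n_input)),
        W_Ch=r.normal(0, scale, (n_rnn, n_fb)),
        W_rdt=r.normal(0, scale, (n_out, n_rnn)),
        b_rdt=r.normal(0, scale, n_out),
        W_MF=r.normal(0, scale, (n_granule, n_rnn)),
        W_PF=r.normal(0, scale, (n_fb, n_granule)),
        W_zh=r.normal(0, scale, (n_rnn, n_out)) if readout_feedback else None,
        activation=activation,
    )


@pytest.fixture
def params():
    return toy_params()
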