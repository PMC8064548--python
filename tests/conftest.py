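import numpy as np
import pytest

from odnaseg import germline as gl
from odnaseg import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def neutral_dataset():
    """One synthetic oocyte dataset at the canonical neutral truth."""
    cfg = synth.GeneratorConfig(seed=11)
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def selection_dataset():
    """Synthetic oocyte dataset with germline selection (rho = 5e-3/day)."""
    cfg = synth.GeneratorConfig(
        truth={"b": 670.0, "nu_f_over_n": 1.4e-4, "rho": 5e-3, "n_d": 1},
        seed=21,
    )
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def desk_schedule():
    """A small-copy-number developmental schedule usable by the exact
    stochastic backend."""
    return gl.GermlineSchedule(
        phases=[(6, 0.3, 1000.0, 200.0), (3, 0.6, 200.0, 600.0)],
        ageing_turnover=1e-3,
        final_amplify_to=1000.0,
    )
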