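import numpy as np
import pytest

import nanosyn as ns


@pytest.fixture
def params():
    return ns.SimulationParameters()


@pytest.fixture
def numerics():
    return ns.NumericsConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fig3_run():
    """A moderate fixed-layout run of the canonical single-release protocol.

    nnt = 1000, n_c = n_r = 40, ani = 0.5, H_c = 20 nm; shared by the engine,
    analysis and acceptance tests to keep the suite fast.
    """
    p = ns.SimulationParameters(nnt=1000, ani=0.5)
    num = ns.NumericsConfig(duration_ms=3.0)
    return ns.run_ensemble(p, num, n_reps=20, seed=42,
                           options=ns.EngineOptions(fixed_layout=True))
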