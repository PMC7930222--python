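import numpy as np
import pytest

import lagcausal as lc


@pytest.fixture(scope="session")
def motor_model():
    return lc.motor_task_model()


@pytest.fixture(scope="session")
def motor_fixture_dir(tmp_path_factory, motor_model):
    """The packaged 14-ROI study-scale fixture: T=280 samples at 2.8 s."""
    directory = tmp_path_factory.mktemp("motor_fixture")
    series = lc.simulate(motor_model, 280, seed=42, sampling_interval=2.8)
    lc.write_fixture(series, motor_model, directory)
    return directory


@pytest.fixture(scope="session")
def chain_phi():
    """Hand-built chain 0 -> 1 -> 2 (lags 1, 1; coefficients 0.5, 0.4)."""
    phi = np.zeros((3, 3, 2))
    phi[1, 0, 1] = 0.5
    phi[2, 1, 1] = 0.4
    return phi


@pytest.fixture(scope="session")
def diamond_phi():
    """Two parallel lag-1+lag-1 paths 0->1->3 (0.5*0.4) and 0->2->3 (0.4*0.3)."""
    phi = np.zeros((4, 4, 2))
    phi[1, 0, 1] = 0.5
    phi[3, 1, 1] = 0.4
    phi[2, 0, 1] = 0.4
    phi[3, 2, 1] = 0.3
    return phi
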