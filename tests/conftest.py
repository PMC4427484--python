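import numpy as np
import pytest
import warnings

from ventriflow.fixtures import run_channel


COARSE_CFG = {
    "fluid": {"nx": 48, "ny": 84, "h_mm": 1.875, "dt_ms": 1.936},
    "geometry": {"resolution_mm": 1.5},
    "output": {"trace_stride": 2, "snapshot_t_stars": [0.25]},
}


@pytest.fixture(scope="session")
def coarse_run():
    """One coarse-grid full-diastole FSI run, shared across tests."""
    from ventriflow.coupling import run_diastole

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_diastole(COARSE_CFG)


@pytest.fixture(scope="session")
def channel():
    """Steady plane-channel benchmark at low Reynolds number."""
    return run_channel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
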