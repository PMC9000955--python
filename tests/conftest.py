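import numpy as np
import pytest

from crmacro import EnsembleParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def best_fit_params():
    """Human-gut best-fit ensemble parameters at a short series length."""
    return EnsembleParams(N=50, M=30, S=0.1, sigma=0.2, k=0.8, T=60, seed=7)


@pytest.fixture(scope="session")
def best_fit_series():
    """One simulated instance at the best-fit parameters (shared, read-only)."""
    from crmacro import simulate_timeseries

    params = EnsembleParams(N=50, M=30, S=0.1, sigma=0.2, k=0.8, T=120, seed=1234)
    return simulate_timeseries(params)


def make_series(x, detect=1e-4):
    from crmacro import AbundanceTimeSeries

    return AbundanceTimeSeries(x=np.asarray(x, dtype=float), detect=detect)
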