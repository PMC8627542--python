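import numpy as np
import pytest

import nitrikin as nk

#: canonical sigmoid used throughout: A1=0, A2=100, t0=30, dt=5
CANON = (0.0, 100.0, 30.0, 5.0)


@pytest.fixture(scope="session")
def canon_params():
    return CANON


@pytest.fixture(scope="session")
def canon_fit():
    """Boltzmann fit of noiseless samples of the canonical sigmoid."""
    t = np.arange(0.0, 81.0, 2.0)
    y = nk.generate_boltzmann_series(*CANON, times=t)
    return nk.fit_boltzmann(t, y, analyte="NOx")


@pytest.fixture(scope="session")
def sample_a_run():
    """One simulated sample-A-like incubation with its ground truth."""
    cfg = nk.get_preset("sample_A_like")
    series, truth = nk.simulate_incubation(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def sample_b_run():
    cfg = nk.get_preset("sample_B_like")
    series, truth = nk.simulate_incubation(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def closed_run():
    cfg = nk.get_preset("closed_system")
    series, truth = nk.simulate_incubation(cfg)
    return cfg, series, truth
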