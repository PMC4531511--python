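import warnings

import pytest

import rxnpbn as rp


@pytest.fixture(scope="session")
def worked_network():
    return rp.fixture_worked_example().network()


@pytest.fixture(scope="session")
def worked_pbn(worked_network):
    return rp.build_pbn(worked_network, rp.PBNParams(p_false=0.1, k_base=10.0))


@pytest.fixture(scope="session")
def hog_network():
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        return rp.fixture_hog("qualitative").network()


@pytest.fixture(scope="session")
def hog_model(hog_network):
    """Deterministic qualitative HOG model."""
    return rp.build_model(hog_network)


@pytest.fixture(scope="session")
def hog_reference_cycle(hog_model):
    """Deterministic reference trajectory and its detected cycle."""
    traj = rp.run(hog_model, rp.SimulationConfig(steps=300, seed=0))
    start, period = rp.detect_cycle(traj)
    return traj, start, period


def _hog_ensemble(hog_network, p_false):
    model = rp.build_pbn(hog_network, rp.PBNParams(p_false=p_false, k_base=100.0))
    cfg = rp.SimulationConfig(steps=280, runs=1000, seed=0)
    return rp.run_ensemble(model, cfg)


@pytest.fixture(scope="session")
def hog_ensemble_p01(hog_network):
    """1000 runs x 280 steps of the qualitative HOG model, false-rate 0.01."""
    return _hog_ensemble(hog_network, 0.01)


@pytest.fixture(scope="session")
def hog_ensemble_p03(hog_network):
    """Same conditions at false-rate 0.03."""
    return _hog_ensemble(hog_network, 0.03)


@pytest.fixture(scope="session")
def hog_summary_p01(hog_ensemble_p01):
    return rp.ensemble_mean(hog_ensemble_p01)


@pytest.fixture(scope="session")
def hog_summary_p03(hog_ensemble_p03):
    return rp.ensemble_mean(hog_ensemble_p03)
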