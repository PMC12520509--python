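import pytest

import spikestack as ss


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale decoder settings shared by the unit tests: four
    resolutions spanning the ladder (2000/500/100/20 ms), three bagging
    replicas, 5x3 nested folds."""
    return ss.DecoderConfig(
        segments=(1, 4, 20, 100),
        grid_ms=5.0,
        n_replicas=3,
        outer_folds=5,
        inner_folds=3,
        l1_grid=(0.01, 0.1, 0.316, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def temporal_ensemble():
    """20-neuron / 100-trial ensemble with a purely temporal category
    code (20-ms bumps, count-neutral dipoles)."""
    cfg = ss.temporal_code_config(
        n_neurons=20, n_trials=100, seed=1, neurons_per_category=6
    )
    return ss.simulate_ensemble(cfg)


@pytest.fixture(scope="session")
def temporal_result(temporal_ensemble, small_config):
    """Fitted nested-CV decoding of the temporal-code ensemble."""
    return ss.nested_cv_fit_predict(temporal_ensemble, small_config)
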