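import numpy as np
import pytest

from czdown import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Cheap 2-day, 1-channel simulator config."""
    return synthetic.SimulatorConfig(duration_days=2.0, n_channels=1,
                                     noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def locked_experiment():
    """Shared 60-day rhythm-injected record with phase-locked seizures."""
    cfg = synthetic.SimulatorConfig(duration_days=60.0, n_channels=2, seed=11)
    catalog = synthetic.phase_locked_catalog(
        cfg, 60, kappa_multidien=synthetic.kappa_for_si(0.9),
        kappa_circadian=4.0, min_separation_s=1800.0)
    features = synthetic.synthesize_rhythmic_features(cfg)
    return cfg, catalog, features
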