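import numpy as np
import pytest

import etongue as et
from etongue.pipeline import RunConfig


@pytest.fixture(scope="session")
def bank():
    return et.default_sensor_bank()


@pytest.fixture(scope="session")
def zero_noise():
    return et.NoiseSpec(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=42)


@pytest.fixture(scope="session")
def study(bank, default_config):
    """The default synthetic study: 27 train + 10 test samples measured at
    default noise with the seed-42 substreams, plus feature/target matrices."""
    cfg = default_config
    seeds = cfg.stream_seeds()
    train = et.make_factorial_design(et.DesignSpec())
    test = et.make_random_test_set(10, seed=seeds["test_design"])
    m_train = et.simulate_dataset(bank, train, noise=cfg.noise(seeds["train_noise"]))
    m_test = et.simulate_dataset(bank, test, noise=cfg.noise(seeds["test_noise"]))
    x_train, _ = et.feature_matrix(m_train)
    x_test, _ = et.feature_matrix(m_test)
    return {
        "config": cfg,
        "seeds": seeds,
        "train": train,
        "test": test,
        "m_train": m_train,
        "m_test": m_test,
        "x_train": x_train,
        "x_test": x_test,
        "y_train": np.vstack([s.concentrations for s in train]),
        "y_test": np.vstack([s.concentrations for s in test]),
    }


@pytest.fixture(scope="session")
def noiseless_study(bank, default_config, zero_noise):
    """Same design/measurement layout as `study`, at zero noise."""
    cfg = default_config
    seeds = cfg.stream_seeds()
    train = et.make_factorial_design(et.DesignSpec())
    test = et.make_random_test_set(10, seed=seeds["test_design"])
    m_train = et.simulate_dataset(bank, train, noise=zero_noise)
    m_test = et.simulate_dataset(bank, test, noise=zero_noise)
    x_train, _ = et.feature_matrix(m_train)
    x_test, _ = et.feature_matrix(m_test)
    return {
        "seeds": seeds,
        "x_train": x_train,
        "x_test": x_test,
        "y_train": np.vstack([s.concentrations for s in train]),
        "y_test": np.vstack([s.concentrations for s in test]),
    }
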