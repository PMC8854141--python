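import numpy as np
import pytest

from vocsense.simulate import NoiseConfig, PermittivityBiasConfig, SimulationConfig, simulate_run


def noiseless_config(**overrides) -> SimulationConfig:
    """A batch configuration with every noise and bias source switched off."""
    cfg = SimulationConfig.batch(
        noise=NoiseConfig(voc_multiplicative_sd=0.0, permittivity_sd=0.0,
                          offline_sd={k: 0.0 for k in
                                      ("vcd", "viability", "glucose", "lactate", "titer")}),
        permittivity_bias=PermittivityBiasConfig(amplitude=0.0, drift=0.0,
                                                 dip_depth=0.0, lag_tau=1e-9),
        **overrides,
    )
    return cfg


@pytest.fixture(scope="session")
def batch_run():
    return simulate_run(SimulationConfig.batch(seed=42), run_id="batch42")


@pytest.fixture(scope="session")
def transfected_run():
    return simulate_run(SimulationConfig.transfected(seed=43), run_id="transfected43")


@pytest.fixture(scope="session")
def training_triplicate():
    return [simulate_run(SimulationConfig.batch(seed=s), run_id=f"train_{s}")[0]
            for s in (101, 102, 103)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
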