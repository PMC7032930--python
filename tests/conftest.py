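import numpy as np
import pytest

import dgsep


@pytest.fixture(scope="session")
def desk_config():
    return dgsep.desk_network_config(scale=0.25, seed=0)


@pytest.fixture(scope="session")
def desk_net(desk_config):
    return dgsep.build_network(desk_config, 0)


@pytest.fixture(scope="session")
def full_net():
    """Full-size tuned network (2000 GCs); built once per session."""
    return dgsep.build_network(dgsep.NetworkConfig(scale=1.0, seed_network=0), 0)


@pytest.fixture(scope="session")
def short_family():
    """Small theta-modulated pattern family (5 patterns, 300 ms)."""
    cfg = dgsep.desk_input_config(scale=0.25, mod_freq=10.0, seed=0, n_patterns=5)
    cfg.duration = 300.0
    return dgsep.generate_pattern_family(cfg)


@pytest.fixture(scope="session")
def desk_results(desk_net, short_family):
    """FULL-condition results for the small family."""
    return dgsep.simulate_family(desk_net, short_family, "FULL")
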