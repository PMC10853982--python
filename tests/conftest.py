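import copy

import numpy as np
import pytest

from fixelpipe.simulate import SimulationConfig, generate_cohort, generate_template


def small_config(**overrides) -> SimulationConfig:
    """Down-scaled study for fast unit tests (structure preserved)."""
    cfg = SimulationConfig()
    sizes = {"HC": 30, "RRMS": 30, "SPMS": 15, "PPMS": 15}
    for g, n in sizes.items():
        cfg.groups[g].size = n
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def noise_free(cfg: SimulationConfig) -> SimulationConfig:
    cfg = copy.deepcopy(cfg)
    cfg.between_subject_sd_fd = 0.0
    cfg.between_subject_sd_fc = 0.0
    cfg.measurement_sd_fd = 0.0
    cfg.measurement_sd_fc = 0.0
    return cfg


@pytest.fixture(scope="session")
def template():
    return generate_template(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
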