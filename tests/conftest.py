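from datetime import date

import pytest

from plateletpanel import GeneratorConfig, build_panel, generate_cell_panel, generate_registry


@pytest.fixture(scope="session")
def small_registry_config():
    return GeneratorConfig(n_donors=8000, seed=11)


@pytest.fixture(scope="session")
def small_registry(small_registry_config):
    return generate_registry(small_registry_config)


@pytest.fixture(scope="session")
def small_panel(small_registry, small_registry_config):
    donors, donations = small_registry
    return build_panel(donors, donations, small_registry_config.scheme, min_cell_size=1)


@pytest.fixture(scope="session")
def noisy_cell_panel():
    return generate_cell_panel(GeneratorConfig(seed=7, sigma_u=0.3, sigma_e=0.3))


@pytest.fixture(scope="session")
def noiseless_cell_panel():
    return generate_cell_panel(GeneratorConfig(seed=7, sigma_u=0.0, sigma_e=1e-12))
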