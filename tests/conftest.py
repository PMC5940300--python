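import pytest

from cryptcycle import gating, population


@pytest.fixture(scope="session")
def homeostasis_cells():
    """Default homeostatic crypt, 10,000 cells, fixed seed."""
    config = population.load_config(n_cells=10_000, seed=0)
    return population.generate_population(config)


@pytest.fixture(scope="session")
def homeostasis_thresholds(homeostasis_cells):
    return gating.derive_thresholds(homeostasis_cells)


@pytest.fixture(scope="session")
def homeostasis_calls(homeostasis_cells, homeostasis_thresholds):
    """Cell table with six-state calls attached."""
    result = gating.gate_flow_profile(homeostasis_cells, homeostasis_thresholds)
    return homeostasis_cells.assign(called_phase=result.calls), result


@pytest.fixture(scope="session")
def noiseless_cells():
    """Homeostatic crypt generated without channel noise (ground-truth means)."""
    config = population.load_config(n_cells=6_000, seed=3)
    config.noise_cv = {"default": 0.0, "dna_content": 0.0}
    return population.generate_population(config)
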