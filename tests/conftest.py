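import pytest

from optomc import fiber_config, run_simulation, uled_config

# Full-scale study runs (10^6 photons) shared by the acceptance-level tests.
# Seed 1 throughout; the engines are deterministic per (seed, photon index).
STUDY_SEED = 1
STUDY_PHOTONS = 1_000_000


@pytest.fixture(scope="session")
def uled_run():
    """uLED probe scenario at full photon count: (config, grid, tallies)."""
    cfg = uled_config(STUDY_PHOTONS, STUDY_SEED)
    grid, tallies = run_simulation(cfg)
    return cfg, grid, tallies


@pytest.fixture(scope="session")
def fiber_run():
    """Optrode fiber scenario at full photon count: (config, grid, tallies)."""
    cfg = fiber_config(STUDY_PHOTONS, STUDY_SEED)
    grid, tallies = run_simulation(cfg)
    return cfg, grid, tallies
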