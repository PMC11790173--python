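import pytest

from turingrowth.engine import preset_config, run_simulation
from turingrowth.timing import delta_calibration


@pytest.fixture(scope="session")
def leopard_history():
    """One growth run of the leopard preset at reduced scale, shared by the
    scenario, rendering and spectral tests."""
    cfg = preset_config("leopard", shape=(128, 128), n_iter=45_000, seed=11,
                        max_surface=4.0)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def tetraodon_history():
    return run_simulation(preset_config("tetraodon", shape=(128, 128), n_iter=25_000,
                                        seed=2, max_surface=4.0))


@pytest.fixture(scope="session")
def emu_history():
    return run_simulation(preset_config("emu", shape=(128, 128), n_iter=25_000,
                                        seed=2, max_surface=4.0))


@pytest.fixture(scope="session")
def pomacanthus_history():
    return run_simulation(preset_config("pomacanthus", shape=(128, 128), n_iter=35_000,
                                        seed=2, max_surface=4.0))


@pytest.fixture(scope="session")
def ictidomys_history():
    return run_simulation(preset_config("ictidomys", shape=(128, 128), n_iter=30_000,
                                        seed=2, max_surface=2.5))


@pytest.fixture(scope="session")
def delta_report():
    """Full delta calibration at reduced scale (the published rate and size
    grids, three seeded replicates)."""
    return delta_calibration(reps=3, seed=7, shape=(128, 128))
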