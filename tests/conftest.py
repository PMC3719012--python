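import numpy as np
import pytest

import nanolever as nl
from nanolever.fokker_planck import SolverSettings


@pytest.fixture(scope="session")
def bare_system() -> nl.LeverSystem:
    """Default 48-bp lever, no protein, aqueous buffer at 298 K."""
    return nl.LeverSystem()


@pytest.fixture(scope="session")
def fast_settings() -> SolverSettings:
    return SolverSettings.fast()


@pytest.fixture(scope="session")
def quenching() -> nl.QuenchingModel:
    return nl.QuenchingModel()


@pytest.fixture(scope="session")
def grid192(bare_system) -> nl.AngleGrid:
    return nl.default_grid(bare_system, n_points=192)


@pytest.fixture(scope="session")
def bare_cycle(bare_system, fast_settings, grid192):
    """One full switching period of the bare lever at D_r = 0.49/us."""
    from nanolever.fokker_planck import switching_cycle

    return switching_cycle(bare_system, 0.49, fast_settings, grid=grid192)
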