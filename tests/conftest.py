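import numpy as np
import pytest

from pnpaging import BindingSystem, NoiseModel, generate_titration_series


@pytest.fixture(scope="session")
def phosphate_system():
    return BindingSystem((16.52, 154.24, 79.67), (-5.36, -0.13, -1.34))


@pytest.fixture(scope="session")
def one_site_system():
    return BindingSystem((25.0,), (-4.0,))


@pytest.fixture(scope="session")
def small_ligand_grid():
    """Coarse titration grid, zero plus 20 log-spaced points to 10 mM."""
    return np.concatenate([[0.0], np.logspace(0, 4, 20)])


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(scale=0.0)


@pytest.fixture(scope="session")
def two_site_series(small_ligand_grid, noiseless):
    """Noiseless two-site titration series at three protein concentrations."""
    system = BindingSystem((10.0, 500.0))
    return generate_titration_series(
        np.array([0.3, 0.6, 0.9]),
        small_ligand_grid,
        (-0.45, -0.3),
        system,
        noiseless,
    )
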