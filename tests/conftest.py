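import numpy as np
import pytest

from mlmmfe import (AtomicSystem, DescriptorConfig, OracleParams,
                    generate_fixtures, partition_regions)


@pytest.fixture(scope="session")
def small_config():
    """Compact descriptor config used throughout the unit tests."""
    return DescriptorConfig(eta_rad=(1.0, 4.0), eta_ang=(1.0,),
                            lambda_vals=(1, -1), zeta_vals=(1.0,),
                            r_cut=4.0)


@pytest.fixture()
def random_system():
    """A 10-atom mixed QM/MM system with random geometry and charges."""
    rng = np.random.default_rng(7)
    elements = ["C", "O", "H", "S", "Cl", "C", "H", "O", "H", "H"]
    regions = ["QM"] * 4 + ["MM"] * 6
    positions = rng.normal(scale=1.8, size=(10, 3))
    charges = rng.uniform(-0.4, 0.4, 10)
    return AtomicSystem(elements, positions, regions, charges)


@pytest.fixture(scope="session")
def solvated_ligand():
    return generate_fixtures("solvated_ligand", n_solvent=20, seed=5)


@pytest.fixture(scope="session")
def complex_fixture():
    return generate_fixtures("complex", n_solvent=20, seed=5)


@pytest.fixture(scope="session")
def oracle_params():
    return OracleParams()


def rigid_transform(positions, seed=0, shift=3.0):
    """Random rotation + translation applied to all coordinates."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return positions @ q.T + shift


@pytest.fixture()
def partitioned(random_system, small_config):
    return partition_regions(random_system, small_config.r_cut)
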