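import numpy as np
import pytest

from lnsaxs import decompose, default_truth
from lnsaxs.synthetic_data import SyntheticConfig, generate_asaxs


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def noisy_scan():
    """One seeded 20-energy, 200-Q scan at 1% relative noise."""
    cfg = SyntheticConfig(seed=42)
    comps, table = cfg.resolve()
    return cfg, generate_asaxs(cfg), comps, table


@pytest.fixture(scope="session")
def clean_scan():
    """The same measurement with the noise switched off entirely."""
    cfg = SyntheticConfig(seed=42, noise_rel=0.0, noise_floor=0.0)
    comps, table = cfg.resolve()
    return cfg, generate_asaxs(cfg), comps, table


@pytest.fixture(scope="session")
def noisy_terms(noisy_scan):
    _, ds, _, _ = noisy_scan
    return decompose(ds)


@pytest.fixture(scope="session")
def small_q_grid():
    return np.geomspace(0.003, 0.3, 60)


def build_three_energy_dataset(s=100.0, c=-5.0, r=1.0, nq=4):
    """The printed 3x3 construction: (f',f'') = (-10,2), (-15,2), (-20,3).

    With (S, C, R) = (100, -5, 1) the intensities are 304, 479 and 709.
    """
    from lnsaxs.scatter_factors import DispersionTable
    from lnsaxs.stuhrmann import EnergyScanDataset, design_matrix

    fp = np.array([-10.0, -15.0, -20.0])
    fpp = np.array([2.0, 2.0, 3.0])
    rows = np.column_stack([[7.30, 7.40, 7.50], fp[::-1], fpp[::-1]])
    table = DispersionTable("Tb", 7.514, rows)
    energies = np.array([7.50, 7.40, 7.30])
    q = np.linspace(0.01, 0.1, nq)
    a = design_matrix(fp, fpp)
    intensity = np.outer(a @ np.array([s, c, r]), np.ones(nq))
    sigma = np.ones_like(intensity)
    return EnergyScanDataset(q, energies, intensity, sigma, "Tb", table)


@pytest.fixture(scope="session")
def three_energy_factory():
    return build_three_energy_dataset
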