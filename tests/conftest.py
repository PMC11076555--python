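import numpy as np
import pytest

from pdzcoupling import synthetic_data as sd


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def chain50():
    """A 50-residue Ca trace shared by coupling-analysis tests."""
    return sd.build_chain_structure("A" * 50)


@pytest.fixture(scope="session")
def planted_two_block_cm(chain50):
    """Normalised DCCM of a trajectory with two planted 10-residue blocks
    (rho=0.8) among 50 residues, F=2000, seed 3."""
    import pdzcoupling as pz

    blocks = [sd.CovarianceBlock(tuple(range(10)), 0.8),
              sd.CovarianceBlock(tuple(range(10, 20)), 0.8)]
    cov = sd.planted_sector_covariance(50, blocks)
    traj = sd.gen_trajectory(cov, 2000, 3, chain50)
    return pz.dccm(traj, fit=False)
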