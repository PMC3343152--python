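import numpy as np
import pytest

from qensemble.ensemble_io import ConformationEnsemble
from qensemble import synthetic


@pytest.fixture(scope="session")
def named_fixtures():
    return synthetic.fixtures()


@pytest.fixture(scope="session")
def helix():
    return synthetic.ideal_helix(12)


@pytest.fixture(scope="session")
def q40_small():
    """Modest q40-like ensemble with mild short-range correlation."""
    spec = synthetic.q40_like(2000, seed=11, kernel=(0.5, 5.0, 7.0))
    labels, ens = synthetic.generate_ensemble(spec)
    return spec, labels, ens


def random_ensemble(n_conf=4, n_res=10, seed=0, names=None):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180.0, 180.0, (n_conf, n_res))
    psi = rng.uniform(-180.0, 180.0, (n_conf, n_res))
    omega = np.full((n_conf, n_res), 180.0)
    phi[:, 0] = np.nan
    psi[:, -1] = np.nan
    omega[:, -1] = np.nan
    return ConformationEnsemble(
        "random", names or ["GLN"] * n_res, phi, psi, omega
    )
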