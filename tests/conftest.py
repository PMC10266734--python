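"""Shared fixtures: one synthetic study, generated once per session."""

import numpy as np
import pytest

import pharmaconet as pn


@pytest.fixture(scope="session")
def geometry100():
    return pn.make_geometry(100, seed=1)


@pytest.fixture(scope="session")
def receptors(geometry100):
    return pn.make_receptor_panel(geometry100, n_receptors=19, seed=3)


@pytest.fixture(scope="session")
def planted(geometry100, receptors):
    """Receptor panel X, drug panel Y with a planted rank-1 latent, and truth."""
    Y, truth = pn.plant_drug_effects(receptors, geometry100, n_drugs=15,
                                     k_latent=1, snr=4.0, seed=3)
    return receptors, Y, truth


@pytest.fixture(scope="session")
def smooth_chol(geometry100):
    """Cholesky factor of the exponential GP kernel, for cheap smooth draws."""
    from pharmaconet.synth import _exp_kernel_chol

    return _exp_kernel_chol(geometry100, 30.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
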