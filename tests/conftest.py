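"""Shared fixtures: small, fast synthetic lungs reused across the suite."""

import numpy as np
import pytest

import porolung as pl
from porolung.calibrate import materials_to_theta
from porolung.forward import SimulationConfig


@pytest.fixture(scope="session")
def default_mats():
    return pl.default_true_materials()


@pytest.fixture(scope="session")
def recovery_mats():
    """Interior ground truth with every parameter mechanically visible.

    The airway and pleura contributions are small fractions of the total
    recoil at the generator defaults; for identifiability studies the
    truth uses a stiffer airway surrogate and pleura scale so that the
    optimizer's stopping tolerances resolve all nine parameters.
    """
    return pl.MaterialSet(
        parenchyma=pl.HyperfoamParams(3.0, 9.5, 0.3),
        permeabilities_1e3_mm2_s=(3.4, 7.3, 3.5, 10.0, 5.7),
        airways=pl.NeoHookeanParams(5.0),
        pleura=pl.PleuraMaterial(pl.DEFAULT_PLEURA_BASELINE, scale_lambda=0.4),
    )


@pytest.fixture(scope="session")
def noiseless_experiment(default_mats):
    """Default lung, 20 patches/lobe, no measurement noise."""
    return pl.make_experiment(
        default_mats, noise=pl.NoiseSpec(pv_rel_sd=0.0, strain_abs_sd=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def fast_experiment(default_mats):
    """Coarse (2 patches/lobe, loose solver) record for plumbing tests."""
    return pl.make_experiment(
        default_mats,
        noise=pl.NoiseSpec(pv_rel_sd=0.0, strain_abs_sd=0.0, seed=7),
        n_patches=2,
        sim_config=SimulationConfig(n_steps=100, rtol=1e-6, atol_mm3=1e-6),
    )


@pytest.fixture(scope="session")
def theta_true(default_mats):
    return materials_to_theta(default_mats)
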