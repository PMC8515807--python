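"""Shared fixtures: solvent susceptibilities and small reference systems.

The water susceptibility solve is the most expensive shared ingredient
(~10 s); it is computed once per session and reused across the 3D, EC-SCF
and acceptance tests.
"""

import numpy as np
import pytest

from ecrism.fields import SoluteConformer, build_grid
from ecrism.fixtures import nitroxide_fragment
from ecrism.solvent import (
    SolventModel,
    assemble_susceptibility,
    build_intramolecular_matrix,
    solve_rism1d,
    spce_water,
)


@pytest.fixture(scope="session")
def water_model():
    return spce_water()


@pytest.fixture(scope="session")
def water_rism1d(water_model):
    return solve_rism1d(water_model, "kh", n_points=1024, dr=0.04,
                        mix=0.3, max_iter=8000)


@pytest.fixture(scope="session")
def water_chi(water_model, water_rism1d):
    omega = build_intramolecular_matrix(water_model, water_rism1d.k)
    return assemble_susceptibility(omega, water_rism1d.h_k, water_model)


@pytest.fixture(scope="session")
def lj_solvent():
    """Neutral single-site LJ solvent at moderate density."""
    return SolventModel(
        site_names=["X"],
        site_coords=np.zeros((1, 3)),
        site_charges=np.array([0.0]),
        lj_sigma=np.array([3.0]),
        lj_epsilon=np.array([0.15]),
        number_density=0.01,
        dielectric_constant=1.0,
        temperature=300.0,
    )


@pytest.fixture(scope="session")
def lj_chi(lj_solvent):
    res = solve_rism1d(lj_solvent, "hnc", n_points=1024, dr=0.04)
    omega = build_intramolecular_matrix(lj_solvent, res.k)
    return assemble_susceptibility(omega, res.h_k, lj_solvent)


@pytest.fixture(scope="session")
def lj_solute():
    return SoluteConformer(
        elements=["C"], coords=[[0.0, 0.0, 0.0]], charges=[0.0],
        lj_sigma=[3.4], lj_epsilon=[0.1],
    )


@pytest.fixture
def small_grid():
    return build_grid(32, 0.5)


@pytest.fixture(scope="session")
def nitroxide():
    return nitroxide_fragment()
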