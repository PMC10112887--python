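"""Shared small fixtures: relaxed droplets and two-cell configurations."""

import numpy as np
import pytest

from extrudesim.dynamics import DynamicsParams, run_simulation
from extrudesim.energetics import EnergyParams, target_volume
from extrudesim.lattice import (
    CellField,
    LatticeSpec,
    MonolayerState,
    make_droplet,
    make_substrate,
)


@pytest.fixture(scope="session")
def small_lattice():
    return LatticeSpec(32, 32, 16, 1.0)


@pytest.fixture(scope="session")
def tiny_params():
    """Couplings used by the 16^3-scale oracle fixtures (R0 = 4.5)."""
    return EnergyParams(
        gamma=0.01,
        lam=2.0,
        mu=40.0,
        V0=target_volume(4.5),
        kappa_cc=0.5,
        kappa_cw=0.15,
        omega_cc=0.001,
        omega_cw=0.0025,
    )


def two_cell_state(lattice=None, sep=8.0, z=None, full_storage=False):
    """Two droplets along x, mirror-symmetric about both box midplanes."""
    lat = lattice or LatticeSpec(32, 32, 16, 1.0)
    width = 2.0
    sub = make_substrate(lat, width, z_surface=4.0)
    R0 = 4.5
    zc = z if z is not None else 7.5
    mid_x = lat.nx / 2.0
    c0 = make_droplet(0, (mid_x - sep / 2, lat.ny / 2.0, zc), R0, width, lat)
    c1 = make_droplet(1, (mid_x + sep / 2, lat.ny / 2.0, zc), R0, width, lat)
    if full_storage:
        c0 = CellField.from_full(0, c0.to_full(lat), lat)
        c1 = CellField.from_full(1, c1.to_full(lat), lat)
    return MonolayerState(lat, [c0, c1], sub)


@pytest.fixture()
def overlapping_pair(small_lattice):
    """Two overlapping droplets, stored on the full box for exact wrap ops."""
    return two_cell_state(small_lattice, sep=7.0, full_storage=True)


@pytest.fixture(scope="session")
def active_monolayer_analysis():
    """One full small active-monolayer run plus its complete analysis.

    Session-scoped because the run takes minutes; shared by the pipeline
    tests and the monolayer-level acceptance checks.
    """
    import warnings

    from extrudesim.io import make_scenario, run_from_config
    from extrudesim.pipeline import analyze_trajectory

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = make_scenario("small_active_monolayer", seed=1)
        result = run_from_config(sc.config, state=sc.state)
        analysis = analyze_trajectory(result, overlap_threshold=sc.config.overlap_threshold)
    return sc, result, analysis


@pytest.fixture(scope="session")
def relaxed_droplet():
    """A single droplet passively relaxed on the substrate (no activity)."""
    lat = LatticeSpec(32, 32, 20, 1.0)
    width = 2.0
    sub = make_substrate(lat, width, z_surface=4.0)
    R0 = 5.0
    params = EnergyParams(
        gamma=0.01, lam=width, mu=40.0, V0=target_volume(R0),
        kappa_cc=0.5, kappa_cw=0.15, omega_cc=0.001, omega_cw=0.0025,
    )
    cell = make_droplet(0, (16.0, 16.0, sub.z_surface + R0), R0, width, lat)
    state = MonolayerState(lat, [cell], sub)
    dyn = DynamicsParams(alpha=0.0, J=0.0, Dr=0.0, dt=0.25, n_steps=600, R0=R0)
    run_simulation(state, params, dyn, snapshot_every=600)
    return state, params, dyn
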