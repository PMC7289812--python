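"""Shared fixtures: voxelized tubes, converged steady solver runs, and the
synthetic sweep dataset.

The steady Poiseuille run is expensive (seconds), so it is computed once per
session and shared by the solver, boundary, metric and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from coarct import boundaries, metrics
from coarct import synthetic_response as sr
from coarct.doe import default_grid
from coarct.geometry import VesselSpec, voxelize_spec
from coarct.lbm_core import LatticeSpec, Simulation


NU_BLOOD = 3.3e-6  # m^2/s, physiological kinematic viscosity (3.5 cP / 1060)


class SteadyTubeRun:
    """A converged steady flow in a straight voxelized tube."""

    def __init__(self, D_lu=20, L_over_D=3, tau=0.8, u_mean_lb=0.01, dx=1e-4,
                 nu_phys=NU_BLOOD, R_outlet=0.0, n_outlets=1, max_steps=30_000):
        spec_g = VesselSpec(inlet_diameter=D_lu * dx, length=L_over_D * D_lu * dx,
                            dos=0.0)
        self.grid = voxelize_spec(spec_g, dx, n_outlets=n_outlets)
        self.spec = LatticeSpec(dx=dx, tau=tau, nu_phys=nu_phys)
        self.mid = self.grid.shape[0] // 2
        self.area_lu = int((self.grid.node_class[self.mid] != 0).sum())
        self.Q_lb = u_mean_lb * self.area_lu
        self.Q_phys = self.Q_lb * dx**3 / self.spec.dt
        self.sim = Simulation(self.grid, self.spec)
        self.inlet = boundaries.InletBC(self.grid, self.spec, Q_steady=self.Q_phys)
        self.outlet = boundaries.ResistanceOutletBC(self.grid, self.spec, R_outlet)
        self.sim.run_to_steady(boundaries=(self.inlet, self.outlet), tol=1e-8,
                               window=200, max_steps=max_steps)

    @property
    def R_eff_lu(self) -> float:
        """Area-equivalent lumen radius in lattice units."""
        return float(np.sqrt(self.area_lu / np.pi))

    def measured_flow_lb(self, i_plane=None) -> float:
        return self.sim.plane_flow_lattice(self.mid if i_plane is None else i_plane)


@pytest.fixture(scope="session")
def steady_tube():
    """D = 20 lu straight-tube Poiseuille run at Ma_centerline ~ 0.035."""
    return SteadyTubeRun()


@pytest.fixture(scope="session")
def synthetic_sweep():
    """Noiseless 10 x 5 synthetic sweep on the 65% stenosis geometry."""
    return sr.generate_dataset(default_grid(), sr.ResponseParams(), seed=0)


@pytest.fixture(scope="session")
def sweep_grid_default():
    return default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
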