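"""D3Q19 single-relaxation-time (BGK) lattice Boltzmann solver.

The fluid at each lattice node is described by 19 distribution values
f_i(x, t), one per discrete velocity c_i.  Each time step relaxes the
distributions towards a local second-order equilibrium at rate 1/tau
(collision) and propagates them to neighboring nodes (streaming).  No-slip
vessel walls use halfway bounce-back.  Density rho = sum_i f_i plays the
role of pressure through the ideal-gas relation P = c_s^2 rho, with
c_s = 1/sqrt(3) the lattice speed of sound.

Unit system
-----------
The solver works in lattice units (dx = dt = rho_ref = 1).  A
:class:`LatticeSpec` carries the physical lattice spacing dx (m), time step
dt (s), and blood density/viscosity, and :func:`redimensionalize` converts
lattice quantities back to SI.  The time step follows from the viscosity
match  dt = dx^2 * nu_lb / nu_phys,  with nu_lb = c_s^2 (tau - 1/2).

Stability is governed by the Mach number Ma = u_peak / c_s: the low-Mach
(weakly compressible) expansion behind the equilibrium requires Ma << 1,
and configurations exceeding the cap (default 0.1) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import SOLID, VoxelGrid

__all__ = [
    "CS",
    "CS2",
    "D3Q19_C",
    "D3Q19_W",
    "D3Q19_OPP",
    "LatticeSpec",
    "Simulation",
    "StabilityError",
    "DivergenceError",
    "equilibrium",
    "time_step",
    "mach_number",
    "check_mach",
    "pressure_lb",
    "redimensionalize",
    "nondimensionalize",
]

D3Q19_C = _kernels.C
D3Q19_W = _kernels.W
D3Q19_OPP = _kernels.OPP

CS2 = 1.0 / 3.0
CS = CS2**0.5

#: default blood density, kg/m^3
BLOOD_DENSITY = 1060.0


class StabilityError(ValueError):
    """Configuration violates the low-Mach stability requirement."""


class DivergenceError(RuntimeError):
    """The simulation produced NaN or non-positive density."""


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice/physical unit bridge for one run."""

    dx: float  # m
    tau: float  # lattice relaxation time
    nu_phys: float  # m^2/s
    rho_phys: float = BLOOD_DENSITY  # kg/m^3

    def __post_init__(self):
        if self.tau <= 0.5:
            raise StabilityError(f"tau must exceed 1/2, got {self.tau}")

    @property
    def nu_lb(self) -> float:
        return CS2 * (self.tau - 0.5)

    @property
    def dt(self) -> float:
        return time_step(self.dx, self.nu_lb, self.nu_phys)

    @property
    def mu_phys(self) -> float:
        """Dynamic viscosity (Pa s)."""
        return self.nu_phys * self.rho_phys

    @classmethod
    def from_physical(
        cls,
        dx: float,
        nu_phys: float,
        u_max_phys: float,
        rho_phys: float = BLOOD_DENSITY,
        ma_target: float = 0.05,
        ma_cap: float = 0.1,
        tau_bounds: tuple = (0.55, 1.0),
    ) -> "LatticeSpec":
        """Choose tau (hence dt) so the peak lattice velocity sits at
        ``ma_target * c_s`` while keeping tau within ``tau_bounds``.

        The peak lattice velocity is u_phys * dt/dx = u_phys * dx * nu_lb
        / nu_phys, so reducing nu_lb (tau -> 1/2) or refining dx lowers the
        Mach number, mirroring the resolution/stability trade-off of the
        method.
        """
        if u_max_phys <= 0:
            nu_lb = CS2 * (0.85 - 0.5)
        else:
            nu_lb = ma_target * CS * nu_phys / (u_max_phys * dx)
        tau = float(np.clip(0.5 + nu_lb / CS2, *tau_bounds))
        spec = cls(dx=dx, tau=tau, nu_phys=nu_phys, rho_phys=rho_phys)
        if u_max_phys > 0:
            u_lb = u_max_phys * spec.dt / spec.dx
            check_mach(u_lb, cap=ma_cap)
        return spec


def equilibrium(rho, u) -> np.ndarray:
    """Second-order D3Q19 equilibrium distributions.

    Parameters
    ----------
    rho : array_like, shape (...,)
    u : array_like, shape (..., 3), lattice velocity

    Returns
    -------
    ndarray, shape (..., 19) with exact zeroth and first moments:
    sum_i f_eq_i = rho and sum_i c_i f_eq_i = rho * u.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    cu = u @ D3Q19_C.T.astype(float)  # (..., 19)
    usq = np.sum(u * u, axis=-1)[..., None]
    return D3Q19_W * rho[..., None] * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq)


def time_step(dx: float, nu_lb: float, nu_phys: float) -> float:
    """Physical time step implied by matching lattice and physical viscosity."""
    if dx <= 0 or nu_lb <= 0 or nu_phys <= 0:
        raise ValueError("dx, nu_lb and nu_phys must be positive")
    return dx * dx * nu_lb / nu_phys


def mach_number(u0_lattice: float) -> float:
    """Mach number of a lattice velocity magnitude."""
    if u0_lattice < 0:
        raise ValueError("velocity magnitude must be non-negative")
    return u0_lattice / CS


def check_mach(u0_lattice: float, cap: float = 0.1) -> float:
    ma = mach_number(abs(u0_lattice))
    if ma >= cap:
        raise StabilityError(
            f"Ma = {ma:.3f} exceeds the cap {cap}; raise the resolution "
            "(smaller dx) or reduce tau to lower the lattice velocity"
        )
    return ma


def pressure_lb(rho):
    """Lattice pressure from density via the ideal-gas relation P = c_s^2 rho."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    return CS2 * rho


_DIM_KINDS = ("velocity", "time", "length", "flow", "shear_stress")


def _dim_factor(kind: str, spec: LatticeSpec) -> float:
    if kind == "velocity":
        return spec.dx / spec.dt
    if kind == "time":
        return spec.dt
    if kind == "length":
        return spec.dx
    if kind == "flow":
        return spec.dx**3 / spec.dt
    if kind == "shear_stress":
        return spec.rho_phys * spec.dx**2 / spec.dt**2
    raise ValueError(f"unknown kind {kind!r}; expected one of {_DIM_KINDS}")


def redimensionalize(quantity, kind: str, spec: LatticeSpec):
    """Convert a lattice-unit quantity to SI (pressure is handled separately
    by the least-squares rescaling in :mod:`coarct.metrics`)."""
    return np.asarray(quantity, dtype=float) * _dim_factor(kind, spec)


def nondimensionalize(quantity, kind: str, spec: LatticeSpec):
    """Inverse of :func:`redimensionalize`."""
    return np.asarray(quantity, dtype=float) / _dim_factor(kind, spec)


@dataclass
class Simulation:
    """Mutable solver state on one voxel grid.

    Boundary closures (inlet velocity, outlet resistance) are applied by the
    functions in :mod:`coarct.boundaries` between streaming steps.
    """

    grid: VoxelGrid
    spec: LatticeSpec
    f: np.ndarray = field(init=False)
    step_count: int = 0

    def __post_init__(self):
        shape = self.grid.shape + (19,)
        rho0 = np.ones(self.grid.shape)
        u0 = np.zeros(self.grid.shape + (3,))
        self.f = np.ascontiguousarray(equilibrium(rho0, u0))
        self._fnew = np.zeros(shape)
        self._active = self.grid.node_class != SOLID

    # -- moments -------------------------------------------------------
    def moments(self):
        """(rho, u) fields; solid nodes report rho = 1, u = 0."""
        rho = np.empty(self.grid.shape)
        u = np.empty(self.grid.shape + (3,))
        _kernels.moments(self.f, self.grid.node_class, rho, u)
        return rho, u

    def total_mass(self) -> float:
        return float(self.f[self._active].sum())

    def max_mach(self) -> float:
        _, u = self.moments()
        umag = np.linalg.norm(u[self._active], axis=-1)
        return float(umag.max() / CS) if umag.size else 0.0

    # -- stepping ------------------------------------------------------
    def step(self, n: int = 1, boundaries=(), check_every: int = 50):
        """Advance n steps, applying each boundary closure after streaming.

        ``boundaries`` is a sequence of callables ``bc(sim)``; they rebuild
        the distributions on inlet/outlet nodes.
        """
        for _ in range(n):
            # cap planes receive no stream from outside the domain; carry
            # their previous distributions so the boundary closures see a
            # sane state to extrapolate from
            self._fnew[0] = self.f[0]
            self._fnew[-1] = self.f[-1]
            _kernels.collide_stream(
                self.f, self._fnew, self.grid.node_class, self.spec.tau
            )
            self.f, self._fnew = self._fnew, self.f
            self.step_count += 1
            for bc in boundaries:
                bc(self)
            if check_every and self.step_count % check_every == 0:
                self._check_health()
        return self

    def _check_health(self):
        fa = self.f[self._active]
        rho = fa.sum(axis=-1)
        if not np.all(np.isfinite(fa)) or np.any(rho <= 0):
            raise DivergenceError(
                f"diverged at step {self.step_count}: "
                f"finite={bool(np.all(np.isfinite(fa)))}, "
                f"min rho={float(np.nanmin(rho)):.3g}, "
                f"max Ma={self._safe_max_mach():.3g}"
            )

    def _safe_max_mach(self) -> float:
        try:
            return self.max_mach()
        except Exception:
            return float("nan")

    # -- diagnostics ---------------------------------------------------
    def plane_flow_lattice(self, i_plane: int) -> float:
        """Volumetric flow (lattice units) through the transverse plane at
        axial index i_plane, positive along +x."""
        rho = self.f[i_plane].sum(axis=-1)
        mx = self.f[i_plane] @ D3Q19_C[:, 0].astype(float)
        mask = self.grid.node_class[i_plane] != SOLID
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(mask, mx / rho, 0.0)
        return float(ux.sum())

    def plane_mass_flow_lattice(self, i_plane: int) -> float:
        """Mass flow (lattice units) through a transverse plane; unlike the
        volume flow this is exactly conserved along a steady duct even in
        the weakly compressible regime."""
        mask = self.grid.node_class[i_plane] != SOLID
        mx = self.f[i_plane] @ D3Q19_C[:, 0].astype(float)
        return float(mx[mask].sum())

    def export_vtk(self, path) -> None:
        """Write the current density and velocity fields (lattice units)
        as legacy ASCII VTK for inspection in ParaView."""
        from .geometry import write_vtk

        rho, u = self.moments()
        write_vtk(
            self.grid,
            path,
            fields={
                "rho": rho,
                "ux": u[..., 0],
                "uy": u[..., 1],
                "uz": u[..., 2],
            },
        )

    def run_to_steady(
        self,
        boundaries=(),
        tol: float = 1e-7,
        window: int = 100,
        max_steps: int = 50_000,
    ):
        """Step until the relative change of mean |u| over ``window`` steps
        drops below tol (simple steady-state detector)."""
        prev = None
        while self.step_count < max_steps:
            self.step(window, boundaries=boundaries)
            _, u = self.moments()
            cur = float(np.abs(u[self._active]).mean())
            if prev is not None and abs(cur - prev) <= tol * max(cur, 1e-30):
                return self
            prev = cur
        return self
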