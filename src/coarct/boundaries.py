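"""Inlet and outlet closures for the D3Q19 solver.

Inlet: a pulsatile parabolic velocity profile (Poiseuille shape) scaled each
step to the instantaneous waveform flow rate.  Outlet: the lumped resistance
rule P_i = Q_i R_i, implemented on lattice density as rho_i = Q_i R_i + 1
(density one corresponds to zero gauge pressure).

Both are realized as equilibrium Dirichlet closures: the boundary node's
distributions are rebuilt from the local equilibrium at the imposed velocity
(inlet, density taken from the adjacent interior plane) or imposed density
(outlet, velocity taken from the adjacent interior plane).  The contract is
accuracy of the imposed quantity, not a particular closure scheme; the
discrete parabola is renormalized so the plane-summed inflow matches the
target flow exactly.
"""

from __future__ import annotations

import numpy as np

from .geometry import SOLID, INLET, OUTLET, VoxelGrid
from .lbm_core import CS2, LatticeSpec, Simulation, StabilityError, equilibrium, check_mach

__all__ = [
    "parabolic_profile",
    "InletBC",
    "PressureInletBC",
    "ResistanceOutletBC",
    "CalibrationError",
    "calibrate_resistances",
    "resistance_to_lattice",
]


def parabolic_profile(Q: float, R_tube: float, r):
    """Axial velocity of Poiseuille flow with volumetric rate Q in a tube of
    radius R_tube, at radial position r:  u(r) = 2Q/(pi R^2) (1 - r^2/R^2)."""
    r = np.asarray(r, dtype=float)
    if R_tube <= 0:
        raise ValueError("R_tube must be positive")
    if np.any(r < 0) or np.any(r > R_tube):
        raise ValueError("radial position outside [0, R_tube]")
    return 2.0 * Q / (np.pi * R_tube**2) * (1.0 - (r / R_tube) ** 2)


def resistance_to_lattice(R_phys: float, spec: LatticeSpec) -> float:
    """Non-dimensionalize a resistance (Pa s / m^3) for the density rule.

    Defined so that (rho - 1) = Q_lb * R_lb reproduces P = Q R with the
    pressure deviation c_s^2 (rho - 1) mapped through rho_phys dx^2/dt^2.
    """
    return R_phys * spec.dx * spec.dt / (CS2 * spec.rho_phys)


class InletBC:
    """Pulsatile (or steady) parabolic velocity inlet on the x = 0 cap."""

    def __init__(
        self,
        grid: VoxelGrid,
        spec: LatticeSpec,
        waveform=None,
        Q_steady: float | None = None,
        ma_cap: float = 0.1,
    ):
        if (waveform is None) == (Q_steady is None):
            raise ValueError("provide exactly one of waveform or Q_steady")
        self.grid = grid
        self.spec = spec
        self.waveform = waveform
        self.Q_steady = Q_steady

        idx = np.argwhere(grid.node_class == INLET)
        if idx.size == 0:
            raise ValueError("grid has no inlet nodes")
        self._idx = idx
        yc, zc = grid.meta.get("axis_yz", (0, 0))
        r = np.sqrt((idx[:, 1] - yc) ** 2 + (idx[:, 2] - zc) ** 2)
        # effective radius from the discrete cap area (pi R^2 = N dx^2)
        R_eff = max(np.sqrt(len(idx) / np.pi), r.max() + 0.5)
        shape = np.clip(1.0 - (r / R_eff) ** 2, 0.0, None)
        # renormalize so the node-summed lattice flux equals Q exactly
        self._shape = shape / shape.sum()
        self._u_center_per_Q = float(self._shape.max())

        Q_peak = waveform.peak_flow if waveform is not None else Q_steady
        self._Q_peak_lb = Q_peak * spec.dt / spec.dx**3
        check_mach(self._Q_peak_lb * self._u_center_per_Q, cap=ma_cap)

        # discrete-flux trim: the Dirichlet closure delivers slightly less
        # volume flux into the first interior plane than imposed (staircase
        # cap, overwritten outgoing populations); a slow feedback gain on
        # the imposed profile removes this geometry-dependent bias
        self._gain = 1.0
        self._last_target: float | None = None

    def flow_at(self, t: float) -> float:
        """Target physical flow rate (mm^3/s-free: same units as waveform)."""
        if self.waveform is not None:
            return float(self.waveform.sample(t))
        return float(self.Q_steady)

    def __call__(self, sim: Simulation):
        from .lbm_core import D3Q19_C

        t = sim.step_count * self.spec.dt
        Q_lb = self.flow_at(t) * self.spec.dt / self.spec.dx**3
        if (
            self._last_target is not None
            and abs(self._last_target) > 0.2 * self._Q_peak_lb
        ):
            q_meas = sim.plane_flow_lattice(1)
            err = (self._last_target - q_meas) / self._last_target
            self._gain = float(np.clip(self._gain * (1.0 + 0.05 * err), 0.8, 1.25))
        self._last_target = Q_lb
        ux = Q_lb * self._gain * self._shape
        i, j, k = self._idx.T
        # non-equilibrium extrapolation closure: equilibrium at the imposed
        # velocity (density from the neighbor) plus the neighbor's
        # non-equilibrium part
        fn = sim.f[np.minimum(i + 1, sim.grid.shape[0] - 1), j, k]
        rho_n = fn.sum(axis=-1)
        u_n = (fn @ D3Q19_C.astype(float)) / rho_n[:, None]
        fneq = fn - equilibrium(rho_n, u_n)
        u = np.zeros((len(i), 3))
        u[:, 0] = ux
        sim.f[i, j, k] = equilibrium(rho_n, u) + fneq
        return sim


class PressureInletBC:
    """Density (pressure) Dirichlet closure on the x = 0 cap, for
    pressure-driven duct flows."""

    def __init__(self, grid: VoxelGrid, rho_target: float):
        self._idx = np.argwhere(grid.node_class == INLET)
        if rho_target <= 0:
            raise ValueError("rho_target must be positive")
        self.rho_target = rho_target

    def __call__(self, sim: Simulation):
        i, j, k = self._idx.T
        fn = sim.f[np.minimum(i + 1, sim.grid.shape[0] - 1), j, k]
        rho_n = fn.sum(axis=-1)
        from .lbm_core import D3Q19_C

        u = (fn @ D3Q19_C.astype(float)) / rho_n[:, None]
        sim.f[i, j, k] = equilibrium(np.full(len(i), self.rho_target), u)
        return sim


class ResistanceOutletBC:
    """Resistance outlets: rho_i = Q_i R_i + 1 per outlet, with Q_i measured
    from the outward-normal velocities of the outlet's nodes each step."""

    def __init__(self, grid: VoxelGrid, spec: LatticeSpec, R_phys: dict | float):
        self.grid = grid
        self.spec = spec
        if not isinstance(R_phys, dict):
            R_phys = {oid: R_phys for oid in grid.outlet_ids}
        missing = set(grid.outlet_ids) - set(R_phys)
        if missing:
            raise ValueError(f"missing resistance for outlets {sorted(missing)}")
        for oid, R in R_phys.items():
            if R < 0:
                raise ValueError(f"negative resistance at outlet {oid}")
        self.R_phys = dict(R_phys)
        self.last_flow_lb: dict = {}
        self.last_rho_target: dict = {}
        # exponential smoothing of the measured outlet flow damps the
        # acoustic startup transient that would otherwise swing rho_target
        self.smoothing = 0.1
        self._q_filt: dict = {}

    def R_lattice(self, oid) -> float:
        return resistance_to_lattice(self.R_phys[oid], self.spec)

    def outlet_flow_lb(self, sim: Simulation, oid) -> float:
        """Outward (+x) lattice flow through outlet ``oid``."""
        idx = self.grid.outlet_ids[oid]
        i, j, k = idx.T
        f = sim.f[i, j, k]
        rho = f.sum(axis=-1)
        from .lbm_core import D3Q19_C

        ux = (f @ D3Q19_C[:, 0].astype(float)) / rho
        return float(ux.sum())

    def __call__(self, sim: Simulation):
        from .lbm_core import D3Q19_C, DivergenceError

        nxm1 = sim.grid.shape[0] - 1
        for oid, idx in self.grid.outlet_ids.items():
            i, j, k = idx.T
            q_now = self.outlet_flow_lb(sim, oid)
            Q_lb = self._q_filt.get(oid)
            Q_lb = (
                q_now
                if Q_lb is None
                else (1 - self.smoothing) * Q_lb + self.smoothing * q_now
            )
            self._q_filt[oid] = Q_lb
            rho_t = Q_lb * self.R_lattice(oid) + 1.0
            if rho_t <= 0:
                raise DivergenceError(
                    f"outlet {oid}: non-positive target density {rho_t:.3g}"
                )
            fn = sim.f[np.maximum(i - 1, 0), j, k]
            rho_n = fn.sum(axis=-1)
            u = (fn @ D3Q19_C.astype(float)) / rho_n[:, None]
            fneq = fn - equilibrium(rho_n, u)
            sim.f[i, j, k] = equilibrium(np.full(len(i), rho_t), u) + fneq
            self.last_flow_lb[oid] = Q_lb
            self.last_rho_target[oid] = rho_t
        return sim


class CalibrationError(RuntimeError):
    """Resistance calibration failed to reach the target flow split."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


def calibrate_resistances(
    runner,
    targets: dict,
    R_init: dict,
    tol: float = 0.02,
    max_iter: int = 20,
    damping: float = 0.5,
):
    """Tune per-outlet resistances until simulated flow fractions match targets.

    ``runner`` maps a resistance dict to a dict of steady per-outlet flows.
    The update is multiplicative with damping: raising an outlet's
    resistance raises its pressure and lowers its flow share, so
    R_i <- R_i * (q_i / t_i)^damping, with q_i the simulated fraction.

    Returns (R, trace); trace rows are (iteration, fractions, max rel error).
    """
    if abs(sum(targets.values()) - 1.0) > 1e-9:
        raise ValueError("target fractions must sum to 1")
    R = dict(R_init)
    if len(targets) == 1:
        return R, [(0, {next(iter(targets)): 1.0}, 0.0)]
    trace = []
    for it in range(max_iter):
        Q = runner(R)
        total = sum(Q.values())
        if total <= 0:
            raise CalibrationError("no net outflow during calibration", trace)
        frac = {oid: Q[oid] / total for oid in targets}
        err = max(abs(frac[o] - targets[o]) / targets[o] for o in targets)
        trace.append((it, frac, err))
        if err < tol:
            return R, trace
        for oid in targets:
            ratio = max(frac[oid] / targets[oid], 1e-6)
            R[oid] = max(R[oid], 1e-12) * ratio**damping
    raise CalibrationError(
        f"flow split not within {tol:.1%} after {max_iter} iterations "
        f"(last error {trace[-1][2]:.1%})",
        trace,
    )
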