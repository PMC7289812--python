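"""Clinical metric extraction: pressure rescaling, ΔP, WSS, TAWSS, sectors.

Pressure: the lattice solver produces density, related to lattice pressure
by P_LB = c_s^2 rho, known only up to an additive constant.  A linear map to
mmHg is fitted by ordinary least squares between the simulated inlet P_LB(t)
and a physiological reference pressure waveform sampled at 20 evenly spaced
cycle times; the rest reference is anchored at 115 mmHg systolic / 65 mmHg
diastolic.  The fitted map converts P_LB anywhere in the domain.

ΔP: cross-section-averaged pressure difference between a plane one inlet
diameter proximal to the stenosis span and one diameter distal to it,
reported at peak systole (the instant of maximum inlet flow).

WSS: the deviatoric stress is assembled from non-equilibrium second moments,
sigma_ab = -(1 - 1/(2 tau)) sum_i c_ia c_ib (f_i - f_i^eq); the tangential
traction magnitude on the wall normal is the wall shear stress.  TAWSS is
its cycle average (trapezoidal quadrature).  A transverse slice half an
inlet diameter beyond the stenosis is split into four angular sectors
(sector 1 starting at +y, numbered clockwise viewed from upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SOLID, VoxelGrid
from .lbm_core import CS2, LatticeSpec, Simulation, equilibrium, pressure_lb

__all__ = [
    "PressureSeries",
    "WSSSlice",
    "CoverageError",
    "InvalidPlaneError",
    "MMHG_PER_PA",
    "reference_pressure_waveform",
    "fit_pressure_scaling",
    "plane_average",
    "default_dp_planes",
    "default_wss_slice_plane",
    "delta_p",
    "wss_field",
    "tawss",
    "sector_tawss",
    "early_wss_features",
    "EARLY_TIMES_S",
]

MMHG_PER_PA = 1.0 / 133.322387415
#: early-cycle WSS feature times (s)
EARLY_TIMES_S = (0.035, 0.07, 0.105)


class CoverageError(ValueError):
    """A time series does not cover the required interval."""


class InvalidPlaneError(ValueError):
    """A measurement plane intersects no fluid nodes."""


@dataclass
class PressureSeries:
    """Cross-section-averaged pressures proximal/distal to the stenosis."""

    times: np.ndarray
    p_prox: np.ndarray
    p_dist: np.ndarray
    units: str = "mmHg"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.p_prox = np.asarray(self.p_prox, dtype=float)
        self.p_dist = np.asarray(self.p_dist, dtype=float)
        if not (len(self.times) == len(self.p_prox) == len(self.p_dist)):
            raise ValueError("series lengths differ")


@dataclass
class WSSSlice:
    """Wall samples on one transverse slice with per-sample WSS series."""

    angles: np.ndarray  # radians, angle from +y, clockwise viewed from upstream
    sectors: np.ndarray  # in {1, 2, 3, 4}
    times: np.ndarray  # s
    wss: np.ndarray  # (n_samples, n_times), Pa

    def __post_init__(self):
        self.wss = np.atleast_2d(np.asarray(self.wss, dtype=float))
        if self.wss.shape != (len(self.angles), len(self.times)):
            raise ValueError("wss must be (n_samples, n_times)")


def reference_pressure_waveform(times, period: float, preset: str = "rest"):
    """Physiological aortic-root pressure (mmHg) at the given times.

    The rest preset attains exactly 115 mmHg at peak systole and 65 mmHg at
    end diastole; the stress preset uses 140/80 mmHg (a representative
    exercise response; only the rest anchors are clinically pinned).
    """
    anchors = {"rest": (65.0, 115.0), "stress": (80.0, 140.0)}
    if preset not in anchors:
        raise ValueError(f"unknown preset {preset!r}")
    lo, hi = anchors[preset]
    t = np.atleast_1d(np.asarray(times, dtype=float))
    x = np.mod(t, period) / period
    # smooth systolic bump peaking mid-systole, minimum at the cycle seam;
    # the sampled waveform is adjusted (normalized) to hit the anchors exactly
    shape = np.sin(np.pi * np.clip(x / (1.0 / 3.0), 0.0, 1.0)) ** 2
    shape = shape + 0.25 * np.sin(np.pi * x) ** 2
    shape = (shape - shape.min()) / max(np.ptp(shape), 1e-30)
    out = lo + (hi - lo) * shape
    return out if np.ndim(times) else float(out[0])


def fit_pressure_scaling(p_lb_series, p_phys_series):
    """OLS slope/intercept mapping lattice pressure to physical pressure.

    Both series must be sampled at the same (typically 20 evenly spaced)
    cycle times.  Raises on a constant lattice series (singular fit).
    """
    x = np.asarray(p_lb_series, dtype=float)
    y = np.asarray(p_phys_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D series")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant lattice pressure series: singular fit")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def plane_average(field: np.ndarray, grid: VoxelGrid, i_plane: int) -> float:
    """Average of a per-node field over the fluid nodes of one axial plane."""
    if not 0 <= i_plane < grid.shape[0]:
        raise InvalidPlaneError(f"plane {i_plane} outside grid")
    mask = grid.node_class[i_plane] != SOLID
    if not mask.any():
        raise InvalidPlaneError(f"plane {i_plane} intersects no fluid nodes")
    return float(np.asarray(field)[i_plane][mask].mean())


def default_dp_planes(grid: VoxelGrid) -> tuple[int, int]:
    """Default ΔP planes: one inlet diameter proximal to the stenosis span
    start and one diameter distal to its end (clipped inside the domain)."""
    dx = grid.dx
    D = grid.meta.get("inlet_diameter", 2 * grid.meta.get("radius", dx))
    zc = grid.meta.get("stenosis_center", 0.5 * grid.meta.get("length", dx))
    span = grid.meta.get("stenosis_span", 0.0)
    nx = grid.shape[0]
    prox = int(round((zc - 0.5 * span - D) / dx))
    dist = int(round((zc + 0.5 * span + D) / dx))
    return max(prox, 1), min(dist, nx - 2)


def default_wss_slice_plane(grid: VoxelGrid) -> int:
    """TAWSS slice: half an inlet diameter beyond the stenosis span end."""
    dx = grid.dx
    D = grid.meta.get("inlet_diameter", 2 * grid.meta.get("radius", dx))
    zc = grid.meta.get("stenosis_center", 0.5 * grid.meta.get("length", dx))
    span = grid.meta.get("stenosis_span", 0.0)
    return min(int(round((zc + 0.5 * span + 0.5 * D) / dx)), grid.shape[0] - 2)


def delta_p(series: PressureSeries, t_peak: float | None = None) -> float:
    """ΔP = <P>_prox - <P>_dist, reported at peak systole.

    With ``t_peak`` (time of maximum inlet flow) given, ΔP is interpolated
    there; otherwise the cycle maximum is returned (the two coincide in
    well-behaved runs).
    """
    dp_t = series.p_prox - series.p_dist
    if t_peak is None:
        return float(np.max(dp_t))
    return float(np.interp(t_peak, series.times, dp_t))


def wss_field(sim: Simulation, spec: LatticeSpec | None = None) -> np.ndarray:
    """Wall shear stress (Pa) at the grid's wall-adjacent fluid nodes.

    Deviatoric stress from non-equilibrium moments, projected on the stored
    wall normals; the tangential traction magnitude is returned in the order
    of ``grid.wall_nodes``.
    """
    grid = sim.grid
    spec = spec or sim.spec
    if grid.wall_nodes is None or grid.wall_normals is None:
        raise ValueError("grid has no wall normals; re-voxelize the geometry")
    from .lbm_core import D3Q19_C

    i, j, k = grid.wall_nodes.T
    f = sim.f[i, j, k]  # (n, 19)
    rho = f.sum(axis=-1)
    c = D3Q19_C.astype(float)
    u = (f @ c) / rho[:, None]
    fneq = f - equilibrium(rho, u)
    # sigma_ab = -(1 - 1/(2 tau)) sum_i c_ia c_ib f_i^neq  (lattice units)
    coef = -(1.0 - 0.5 / spec.tau)
    sigma = coef * np.einsum("ni,ia,ib->nab", fneq, c, c)
    n = grid.wall_normals
    traction = np.einsum("nab,nb->na", sigma, n)
    normal_comp = np.einsum("na,na->n", traction, n)
    tangential = traction - normal_comp[:, None] * n
    wss_lb = np.linalg.norm(tangential, axis=-1)
    return wss_lb * spec.rho_phys * spec.dx**2 / spec.dt**2


def tawss(wss_series, times, T: float) -> np.ndarray:
    """Time-averaged WSS magnitude, (1/T) integral |WSS| dt over one cycle.

    ``wss_series`` is (..., n_times); snapshots must cover [0, T] (a final
    seam sample equal to the first is appended when times end before T,
    using periodicity).
    """
    w = np.abs(np.atleast_2d(np.asarray(wss_series, dtype=float)))
    t = np.asarray(times, dtype=float)
    if w.shape[-1] != len(t) or len(t) < 2:
        raise CoverageError("series and times lengths differ or too short")
    if T <= 0:
        raise ValueError("cycle duration must be positive")
    span = t[-1] - t[0]
    dt_snap = np.median(np.diff(t))
    if span < T - 1.5 * dt_snap:
        raise CoverageError(
            f"series spans {span:.4g} s but one cycle is {T:.4g} s"
        )
    if span < T:  # periodic seam closure
        t = np.concatenate([t, [t[0] + T]])
        w = np.concatenate([w, w[..., :1]], axis=-1)
    out = np.trapezoid(w, t, axis=-1) / (t[-1] - t[0])
    return out[0] if np.ndim(wss_series) == 1 else out


def sector_tawss(sl: WSSSlice, T: float):
    """Mean TAWSS per quadrant sector and the circumferential mean.

    Returns (sector_means, circumferential_mean); an empty sector yields a
    NaN entry and a warning.
    """
    import warnings

    per_sample = tawss(sl.wss, sl.times, T)
    sector_means = np.full(4, np.nan)
    for s in range(1, 5):
        m = sl.sectors == s
        if not m.any():
            warnings.warn(f"sector {s} has no wall samples", stacklevel=2)
            continue
        sector_means[s - 1] = per_sample[m].mean()
    return sector_means, float(per_sample.mean())


def early_wss_features(times, wss_circ_series, sample_times=EARLY_TIMES_S):
    """Circumferentially averaged WSS at the early-cycle feature times
    (defaults 0.035, 0.07, 0.105 s)."""
    t = np.asarray(times, dtype=float)
    w = np.asarray(wss_circ_series, dtype=float)
    if t.shape != w.shape:
        raise ValueError("times and series must align")
    if t[-1] < max(sample_times) - 1e-12:
        raise CoverageError(
            f"series ends at {t[-1]:.4g} s, before {max(sample_times)} s"
        )
    return tuple(float(np.interp(ts, t, w)) for ts in sample_times)


def make_wss_slice(
    sim: Simulation, i_plane: int, times, wss_history: np.ndarray
) -> WSSSlice:
    """Assemble a :class:`WSSSlice` from stored wall-WSS snapshots.

    ``wss_history`` is (n_wall, n_times) over all wall nodes in grid order;
    the slice keeps the wall nodes on axial plane ``i_plane``.  Angles are
    measured from +y, clockwise when viewed from upstream (+x towards the
    viewer); sectors are the four quadrants starting at +y.
    """
    grid = sim.grid
    on_plane = grid.wall_nodes[:, 0] == i_plane
    if not on_plane.any():
        raise InvalidPlaneError(f"no wall samples on plane {i_plane}")
    yc, zc = grid.meta.get("axis_yz", (0, 0))
    nodes = grid.wall_nodes[on_plane]
    vy = nodes[:, 1] - yc
    vz = nodes[:, 2] - zc
    ang = np.mod(np.arctan2(-vz, vy), 2 * np.pi)  # clockwise from +y
    sectors = (ang // (np.pi / 2)).astype(int) + 1
    return WSSSlice(
        angles=ang,
        sectors=np.clip(sectors, 1, 4),
        times=np.asarray(times, dtype=float),
        wss=wss_history[on_plane],
    )
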