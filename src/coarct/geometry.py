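"""Stenosed-vessel geometry generation and voxelization.

A coarctation is modelled as an axisymmetric tube whose radius narrows
smoothly (cosine profile) to a throat inside a stenosis span.  The degree
of stenosis (DoS) is defined as the fractional *diameter* reduction at the
throat: a 65% DoS vessel has a throat diameter equal to 35% of the inlet
diameter.  This is the convention of the clinical literature on stenosis
grading; an area-based definition would give different throat sizes.

Geometries are discretized onto a node-centered Cartesian lattice for the
D3Q19 solver.  Solid walls are realized at the halfway point between fluid
and solid nodes, matching the halfway bounce-back rule of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "VesselSpec",
    "VoxelGrid",
    "InvalidSpecError",
    "ResolutionError",
    "STLImportError",
    "make_stenosed_tube",
    "voxelize",
    "voxelize_mesh",
    "load_stl",
    "write_vtk",
]

# node classification labels
SOLID = 0
FLUID = 1
INLET = 2
OUTLET = 3

#: minimum throat diameter, in lattice units, for a meaningful flow solution
MIN_THROAT_LU = 6


class InvalidSpecError(ValueError):
    """Raised for geometrically impossible vessel specifications."""


class ResolutionError(ValueError):
    """Raised when the lattice spacing under-resolves the stenosis throat."""


class STLImportError(ValueError):
    """Raised for unreadable or non-manifold surface meshes."""


@dataclass(frozen=True)
class VesselSpec:
    """Parametric description of a stenosed straight vessel.

    Parameters
    ----------
    inlet_diameter : float
        Vessel diameter away from the stenosis (m).
    length : float
        Axial length of the vessel (m).
    dos : float
        Degree of stenosis as fractional diameter reduction, in [0, 1).
    stenosis_center : float
        Axial position of the throat (m).  Defaults to mid-vessel.
    stenosis_span : float
        Axial extent of the constriction (m).  Defaults to 2 diameters.
    """

    inlet_diameter: float
    length: float
    dos: float = 0.0
    stenosis_center: float | None = None
    stenosis_span: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.dos < 1.0):
            raise InvalidSpecError(f"dos must lie in [0, 1), got {self.dos}")
        if self.inlet_diameter <= 0 or self.length <= 0:
            raise InvalidSpecError("inlet_diameter and length must be positive")
        if self.stenosis_center is None:
            object.__setattr__(self, "stenosis_center", 0.5 * self.length)
        if self.stenosis_span is None:
            object.__setattr__(
                self, "stenosis_span", min(2.0 * self.inlet_diameter, self.length)
            )
        if self.stenosis_span > self.length:
            raise InvalidSpecError("stenosis_span exceeds vessel length")
        if self.stenosis_span <= 0:
            raise InvalidSpecError("stenosis_span must be positive")

    @property
    def radius(self) -> float:
        return 0.5 * self.inlet_diameter

    @property
    def throat_diameter(self) -> float:
        return self.inlet_diameter * (1.0 - self.dos)


@dataclass
class VoxelGrid:
    """Cartesian lattice with per-node classification.

    Attributes
    ----------
    dx : float
        Lattice spacing (m).
    node_class : ndarray of uint8, shape (nx, ny, nz)
        Per-node label: 0 solid, 1 fluid, 2 inlet, 3 outlet.  The x axis is
        the vessel axis; inlet and outlet caps sit on the axial boundary
        planes.
    outlet_ids : dict
        Maps an outlet id to the (i, j, k) index arrays of its nodes.
    wall_normals : ndarray, shape (n_wall, 3)
        Outward (into-solid) unit normals at wall-adjacent fluid nodes.
    wall_nodes : ndarray, shape (n_wall, 3)
        Indices of the wall-adjacent fluid nodes the normals belong to.
    meta : dict
        Geometry provenance (spec parameters, axis location).
    """

    dx: float
    node_class: np.ndarray
    outlet_ids: dict = field(default_factory=dict)
    wall_normals: np.ndarray | None = None
    wall_nodes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return tuple(self.node_class.shape)

    @property
    def fluid_mask(self) -> np.ndarray:
        """All nodes the solver updates (fluid plus inlet/outlet caps)."""
        return self.node_class != SOLID

    def counts(self) -> dict:
        u, c = np.unique(self.node_class, return_counts=True)
        names = {SOLID: "solid", FLUID: "fluid", INLET: "inlet", OUTLET: "outlet"}
        return {names[k]: int(n) for k, n in zip(u, c)}


def make_stenosed_tube(spec: VesselSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return the analytic radius profile r(z) of a stenosed tube.

    Outside the stenosis span the radius is the inlet radius R; inside, a
    cosine constriction narrows the tube to ``R * (1 - dos)`` at the center:

        r(z) = R * (1 - dos/2 * (1 + cos(2*pi*(z - zc)/span)))

    for |z - zc| <= span/2.  The profile is continuous with continuous slope
    at the span boundaries.
    """
    R = spec.radius
    zc = spec.stenosis_center
    span = spec.stenosis_span
    dos = spec.dos

    def profile(z):
        z = np.asarray(z, dtype=float)
        r = np.full_like(z, R)
        if dos > 0:
            inside = np.abs(z - zc) <= 0.5 * span
            r = np.where(
                inside,
                R * (1.0 - 0.5 * dos * (1.0 + np.cos(2.0 * np.pi * (z - zc) / span))),
                r,
            )
        return r

    return profile


def _classify_caps_and_walls(node_class: np.ndarray) -> None:
    """Mark the axial end planes of a fluid mask as inlet (x=0) / outlet (x=-1)."""
    first = node_class[0]
    last = node_class[-1]
    first[first == FLUID] = INLET
    last[last == FLUID] = OUTLET


def _wall_adjacent(node_class: np.ndarray):
    """Fluid nodes with at least one solid face/edge neighbor (D3Q19 links)."""
    from .lbm_core import D3Q19_C

    solid = node_class == SOLID
    fluid = node_class == FLUID
    adjacent = np.zeros_like(fluid)
    for c in D3Q19_C[1:]:
        shifted = np.roll(solid, shift=tuple(-c), axis=(0, 1, 2))
        # roll wraps around; mask out wrapped planes
        for ax, s in enumerate(c):
            if s == 1:
                idx = [slice(None)] * 3
                idx[ax] = -1
                shifted[tuple(idx)] = False
            elif s == -1:
                idx = [slice(None)] * 3
                idx[ax] = 0
                shifted[tuple(idx)] = False
        adjacent |= fluid & shifted
    return np.argwhere(adjacent)


def voxelize(
    profile: Callable[[np.ndarray], np.ndarray],
    dx: float,
    length: float,
    radius_max: float,
    spec: VesselSpec | None = None,
    n_outlets: int = 1,
) -> VoxelGrid:
    """Voxelize an axisymmetric radius profile onto a Cartesian lattice.

    The vessel axis runs along x.  A node at center (i*dx, y, z) is fluid if
    its radial distance from the axis is below r(x); with halfway bounce-back
    the no-slip wall is realized half a spacing beyond the outermost fluid
    nodes.  The two axial end planes are classified inlet (x = 0) and outlet.

    ``n_outlets`` splits the outlet cap into sectors about the axis (equal
    angular wedges), producing the single-inlet/N-outlet manifolds used for
    resistance-calibration studies.
    """
    if dx <= 0:
        raise InvalidSpecError("dx must be positive")
    if length <= 0 or radius_max <= 0:
        raise InvalidSpecError("degenerate vessel: non-positive length or radius")

    if spec is not None:
        throat_lu = spec.throat_diameter / dx
        if throat_lu < MIN_THROAT_LU:
            dx_max = spec.throat_diameter / MIN_THROAT_LU
            raise ResolutionError(
                f"throat resolved by {throat_lu:.1f} lattice units "
                f"(< {MIN_THROAT_LU}); use dx <= {dx_max:.3e} m"
            )

    nx = int(round(length / dx)) + 1
    # transverse extent: radius plus one solid shell layer each side
    nr = int(np.ceil(radius_max / dx)) + 2
    ny = nz = 2 * nr + 1
    yc = zc = nr  # axis passes through node centers

    x = np.arange(nx) * dx
    y = (np.arange(ny) - yc) * dx
    z = (np.arange(nz) - zc) * dx
    r_of_x = np.asarray(profile(x), dtype=float)
    rr = np.sqrt(y[:, None] ** 2 + z[None, :] ** 2)
    fluid = rr[None, :, :] < r_of_x[:, None, None]

    node_class = np.where(fluid, FLUID, SOLID).astype(np.uint8)
    _classify_caps_and_walls(node_class)

    grid = VoxelGrid(
        dx=dx,
        node_class=node_class,
        meta={
            "kind": "tube",
            "axis": "x",
            "axis_yz": (yc, zc),
            "length": length,
            "radius": radius_max,
        },
    )
    if spec is not None:
        grid.meta.update(
            dos=spec.dos,
            inlet_diameter=spec.inlet_diameter,
            stenosis_center=spec.stenosis_center,
            stenosis_span=spec.stenosis_span,
        )

    _assign_outlets(grid, n_outlets)
    _compute_wall_normals_tube(grid)
    return grid


def voxelize_spec(spec: VesselSpec, dx: float, n_outlets: int = 1) -> VoxelGrid:
    """Convenience wrapper: profile from :func:`make_stenosed_tube` then voxelize."""
    profile = make_stenosed_tube(spec)
    return voxelize(profile, dx, spec.length, spec.radius, spec=spec, n_outlets=n_outlets)


def _assign_outlets(grid: VoxelGrid, n_outlets: int) -> None:
    idx = np.argwhere(grid.node_class == OUTLET)
    if idx.size == 0:
        raise InvalidSpecError("voxelization produced no outlet nodes")
    if n_outlets <= 1:
        grid.outlet_ids = {0: idx}
        return
    yc, zc = grid.meta.get("axis_yz", (0, 0))
    ang = np.arctan2(idx[:, 2] - zc, idx[:, 1] - yc)  # (-pi, pi]
    edges = np.linspace(-np.pi, np.pi, n_outlets + 1)
    which = np.clip(np.digitize(ang, edges) - 1, 0, n_outlets - 1)
    # node rows that fall exactly on a sector edge are alternated between
    # the two adjacent sectors so the discrete split stays balanced
    for e_i, e in enumerate(edges[:-1]):
        on_edge = np.flatnonzero(
            (np.abs(ang - e) < 1e-9) | (np.abs(np.abs(ang) - np.pi) < 1e-9)
            if e_i == 0
            else np.abs(ang - e) < 1e-9
        )
        left = (e_i - 1) % n_outlets
        for m, node in enumerate(on_edge):
            which[node] = e_i if m % 2 == 0 else left
    grid.outlet_ids = {i: idx[which == i] for i in range(n_outlets)}
    for i, nodes in grid.outlet_ids.items():
        if len(nodes) == 0:
            raise InvalidSpecError(f"outlet sector {i} received no nodes")


def _compute_wall_normals_tube(grid: VoxelGrid) -> None:
    """Radial outward normals for axisymmetric tube grids."""
    wall_nodes = _wall_adjacent(grid.node_class)
    yc, zc = grid.meta.get("axis_yz", (0, 0))
    vy = wall_nodes[:, 1] - yc
    vz = wall_nodes[:, 2] - zc
    mag = np.sqrt(vy**2 + vz**2)
    mag[mag == 0] = 1.0
    normals = np.zeros((len(wall_nodes), 3))
    normals[:, 1] = vy / mag
    normals[:, 2] = vz / mag
    grid.wall_nodes = wall_nodes
    grid.wall_normals = normals


def load_stl(path):
    """Load a closed-manifold STL surface (binary or ASCII) via trimesh."""
    import trimesh

    try:
        mesh = trimesh.load_mesh(path, file_type="stl")
    except Exception as exc:  # truncated / malformed file
        raise STLImportError(f"could not parse STL {path!r}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise STLImportError(f"no triangles found in {path!r}")
    if not mesh.is_watertight:
        report = {
            "faces": int(len(mesh.faces)),
            "euler_number": int(mesh.euler_number),
            "open_edges": int((mesh.edges_sorted.shape[0] - mesh.edges_unique.shape[0])),
        }
        raise STLImportError(f"surface is not a closed manifold: {report}")
    return mesh


def _xray_inside(mesh, xs, ys, zs) -> np.ndarray:
    """Inside/outside classification of grid nodes by x-ray parity counting.

    For every (y, z) lattice column, the crossings of the closed surface
    along +x are located by plane intersection of the triangles whose (y, z)
    projection covers the column; a node is inside iff an odd number of
    crossings lies below it.  A sub-lattice jitter on the column coordinates
    avoids edge-grazing degeneracies.
    """
    tri = mesh.triangles  # (T, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    normals = np.cross(v1 - v0, v2 - v0)
    ok = np.abs(normals[:, 0]) > 1e-14  # triangles not parallel to the ray
    v0, v1, v2, normals = v0[ok], v1[ok], v2[ok], normals[ok]

    jitter = 0.5e-6 * (xs[1] - xs[0] if len(xs) > 1 else 1.0)
    Y, Z = np.meshgrid(ys + jitter, zs + 2 * jitter, indexing="ij")
    cols = np.stack([Y.ravel(), Z.ravel()], axis=-1)  # (M, 2)

    def side(a, b):
        # 2D cross product sign of edge a->b vs the column point, (T, M)
        dy = (b[:, 1] - a[:, 1])[:, None]
        dz = (b[:, 2] - a[:, 2])[:, None]
        return dy * (cols[None, :, 1] - a[:, None, 2]) - dz * (
            cols[None, :, 0] - a[:, None, 1]
        )

    d0, d1, d2 = side(v0, v1), side(v1, v2), side(v2, v0)
    covers = ((d0 >= 0) & (d1 >= 0) & (d2 >= 0)) | ((d0 <= 0) & (d1 <= 0) & (d2 <= 0))

    # crossing x from the triangle plane equation
    x_cross = v0[:, 0][:, None] - (
        normals[:, 1][:, None] * (cols[None, :, 0] - v0[:, 1][:, None])
        + normals[:, 2][:, None] * (cols[None, :, 1] - v0[:, 2][:, None])
    ) / normals[:, 0][:, None]

    inside = np.zeros((len(xs), len(cols)), dtype=bool)
    for i, x in enumerate(xs):
        below = covers & (x_cross <= x)
        inside[i] = (below.sum(axis=0) % 2) == 1
    return inside.reshape(len(xs), len(ys), len(zs))


def voxelize_mesh(mesh, dx: float, cap_axis: int = 0) -> VoxelGrid:
    """Voxelize a closed surface mesh; cap the two extreme planes as inlet/outlet.

    Nodes whose centers lie inside the surface are fluid.  The first and last
    planes along ``cap_axis`` that contain fluid are classified inlet and
    outlet respectively, mirroring the analytic tube convention.
    """
    if dx <= 0:
        raise InvalidSpecError("dx must be positive")
    lo, hi = mesh.bounds
    # one solid shell layer around the bounding box
    origin = lo - dx
    shape = np.ceil((hi - lo) / dx).astype(int) + 3
    axes = [origin[d] + np.arange(shape[d]) * dx for d in range(3)]
    inside = _xray_inside(mesh, *axes)

    node_class = np.where(inside, FLUID, SOLID).astype(np.uint8)
    if cap_axis != 0:
        node_class = np.moveaxis(node_class, cap_axis, 0)
    # trim empty leading/trailing axial planes so caps sit on boundary planes
    has_fluid = node_class.max(axis=(1, 2)) == FLUID
    if not has_fluid.any():
        raise InvalidSpecError("mesh voxelization produced no fluid nodes")
    i0, i1 = np.argmax(has_fluid), len(has_fluid) - np.argmax(has_fluid[::-1]) - 1
    node_class = node_class[i0 : i1 + 1]
    _classify_caps_and_walls(node_class)

    center = 0.5 * (lo + hi)
    yc = (center[1] - origin[1]) / dx
    zc = (center[2] - origin[2]) / dx
    grid = VoxelGrid(
        dx=dx,
        node_class=node_class,
        meta={"kind": "mesh", "axis": "x", "axis_yz": (yc, zc)},
    )
    _assign_outlets(grid, 1)
    _compute_wall_normals_tube(grid)
    return grid


def write_vtk(grid: VoxelGrid, path, fields: dict | None = None) -> None:
    """Export node classes (and optional per-node scalar fields) as legacy
    ASCII VTK structured points, viewable in ParaView."""
    nx, ny, nz = grid.shape
    fields = fields or {}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoarct voxel grid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {grid.dx} {grid.dx} {grid.dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS node_class int 1\nLOOKUP_TABLE default\n")
        grid.node_class.T.ravel().tofile(fh, sep="\n", format="%d")
        fh.write("\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.asarray(arr, dtype=float).T.ravel().tofile(fh, sep="\n", format="%.8g")
            fh.write("\n")
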