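"""Numba-compiled hot loops for the D3Q19 BGK solver.

The collide-and-stream kernel is fused (push scheme): each active node
computes its moments and post-collision distributions, then propagates them
to neighbors.  Links into solid nodes are reflected back in place (halfway
bounce-back), so the no-slip wall sits midway between the fluid node and the
solid node.  Links leaving the domain only occur at inlet/outlet cap nodes,
whose distributions are overwritten by the boundary closures afterwards.
"""

import numpy as np
from numba import njit

# D3Q19 stencil: rest, 6 axis, 12 diagonal velocities
_c = [[0, 0, 0]]
_c += [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
_c += [
    [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
    [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
    [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
]
C = np.array(_c, dtype=np.int64)
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)
OPP = np.array(
    [int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C], dtype=np.int64
)


@njit(cache=True)
def equilibrium_node(rho, ux, uy, uz, out):
    usq = ux * ux + uy * uy + uz * uz
    for i in range(19):
        cu = C[i, 0] * ux + C[i, 1] * uy + C[i, 2] * uz
        out[i] = W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=True)
def collide_stream(f, fnew, node_class, tau):
    """One BGK collide + stream step.  node_class: 0 solid, >0 active."""
    nx, ny, nz = node_class.shape
    omega = 1.0 / tau
    feq = np.empty(19)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if node_class[x, y, z] == 0:
                    continue
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(19):
                    fi = f[x, y, z, i]
                    rho += fi
                    mx += C[i, 0] * fi
                    my += C[i, 1] * fi
                    mz += C[i, 2] * fi
                ux = mx / rho
                uy = my / rho
                uz = mz / rho
                equilibrium_node(rho, ux, uy, uz, feq)
                for i in range(19):
                    fpost = f[x, y, z, i] - omega * (f[x, y, z, i] - feq[i])
                    xn = x + C[i, 0]
                    yn = y + C[i, 1]
                    zn = z + C[i, 2]
                    if 0 <= xn < nx and 0 <= yn < ny and 0 <= zn < nz:
                        if node_class[xn, yn, zn] == 0:
                            fnew[x, y, z, OPP[i]] = fpost
                        else:
                            fnew[xn, yn, zn, i] = fpost
                    # else: leaves the domain through a cap node; the cap's
                    # distributions are rebuilt by the boundary closure


@njit(cache=True)
def moments(f, node_class, rho, u):
    nx, ny, nz = node_class.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if node_class[x, y, z] == 0:
                    rho[x, y, z] = 1.0
                    u[x, y, z, 0] = 0.0
                    u[x, y, z, 1] = 0.0
                    u[x, y, z, 2] = 0.0
                    continue
                r = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(19):
                    fi = f[x, y, z, i]
                    r += fi
                    mx += C[i, 0] * fi
                    my += C[i, 1] * fi
                    mz += C[i, 2] * fi
                rho[x, y, z] = r
                u[x, y, z, 0] = mx / r
                u[x, y, z, 1] = my / r
                u[x, y, z, 2] = mz / r
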