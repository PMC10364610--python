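"""Independent numerical validation of the analytic electrogram model.

Two brute-force oracles, deliberately sharing no code with the mirror
series:

* a 2D (XZ) finite-volume solver for the heterogeneous anisotropic Poisson
  problem ``-div(G grad Phi) = rho`` with the travelling front represented
  as a discrete dipole sheet spanning the wall, zero-flux outer boundaries
  and one pinned reference node;
* a numerical solid-angle integrator for the rectangular front strip, used
  to certify that the 3D solid angle equals twice the planar angle of the
  analytic solution.

The problem is Y-invariant, so the 2D solution is per unit length in Y and
matches the line-stacked analytic forms directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import quad
from scipy.sparse.linalg import spsolve

from .exceptions import GridError
from .tissue_model import DEFAULT_MEMBRANE, MembraneStep, SlabModel

__all__ = ["GridSpec", "PoissonSolution", "solve_poisson_slab", "solid_angle_numeric"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform XZ grid aligned with the layer interfaces z = 0 and z = -L.

    ``dx``/``dz`` are spacings (mm); ``x_half_width`` the lateral extent on
    either side of the front; ``pad_top``/``pad_bottom`` the blood- and
    torso-side extents beyond the wall.  The front is placed midway between
    two node columns so the discrete dipole is symmetric.
    """

    dx: float = 0.5
    dz: float = 0.5
    x_half_width: float = 60.0
    pad_top: float = 50.0
    pad_bottom: float = 50.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dz > 0):
            raise GridError("dx and dz must be > 0")

    def validate(self, L: float) -> None:
        for name, extent, step in (
            ("L", L, self.dz),
            ("pad_top", self.pad_top, self.dz),
            ("pad_bottom", self.pad_bottom, self.dz),
        ):
            n = extent / step
            if abs(n - round(n)) > 1e-9:
                raise GridError(
                    f"{name}={extent} is not an integer multiple of dz={step}; "
                    "grid nodes must align with the interfaces"
                )


@dataclass
class PoissonSolution:
    """Finite-volume solution field with bilinear probing."""

    x: np.ndarray  # node x positions relative to the front (mm)
    z: np.ndarray  # node z positions (mm)
    phi: np.ndarray  # (nz, nx) potential (mV per unit Y-length)
    residual_inf: float  # max |A phi - b| after solving (conservation check)

    def probe(self, x_rel, z):
        """Bilinearly interpolated potential at (x - front_x, z)."""
        x_rel = np.atleast_1d(np.asarray(x_rel, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.empty(np.broadcast(x_rel, z).shape)
        xb, zb = np.broadcast_arrays(x_rel, z)
        for k, (xv, zv) in enumerate(zip(xb.ravel(), zb.ravel())):
            i = np.clip(np.searchsorted(self.x, xv) - 1, 0, len(self.x) - 2)
            j = np.clip(np.searchsorted(self.z, zv) - 1, 0, len(self.z) - 2)
            tx = (xv - self.x[i]) / (self.x[i + 1] - self.x[i])
            tz = (zv - self.z[j]) / (self.z[j + 1] - self.z[j])
            out.ravel()[k] = (
                self.phi[j, i] * (1 - tx) * (1 - tz)
                + self.phi[j, i + 1] * tx * (1 - tz)
                + self.phi[j + 1, i] * (1 - tx) * tz
                + self.phi[j + 1, i + 1] * tx * tz
            )
        return out[0] if out.size == 1 else out


def solve_poisson_slab(
    grid: GridSpec,
    slab: SlabModel,
    mem: MembraneStep = DEFAULT_MEMBRANE,
    front_x: float = 0.0,
) -> PoissonSolution:
    """Solve the three-layer anisotropic Poisson problem for a front at x=0.

    Conductivity is ``g_B`` above the wall, ``diag(g_M, g_zz)`` inside and
    ``g_T`` below.  The dipole sheet is discretized as two charged node
    columns of strength ``+-(phi_max - phi_rest) g_i,xx / dx`` adjacent to
    the front (positive ahead of it), spanning ``z in [-L, 0]`` with
    half-weight end nodes.  Outer boundaries are zero-flux; the gauge is
    fixed by pinning one corner node and removing the mean afterwards, which
    leaves the odd-in-x solution on the front-symmetric grid.

    ``front_x`` only shifts the reported x coordinates; the grid is always
    built symmetric about the front.
    """
    grid.validate(slab.L)
    dx, dz = grid.dx, grid.dz
    nx = 2 * int(round(grid.x_half_width / dx))
    x = (np.arange(nx) - nx / 2 + 0.5) * dx  # front between nx//2-1 and nx//2
    z_bot = -slab.L - grid.pad_bottom
    nz = int(round((grid.pad_top - z_bot) / dz)) + 1
    z = z_bot + np.arange(nz) * dz

    cs = slab.conductivities
    z_mid = 0.5 * (z[:-1] + z[1:])
    in_wall = (z_mid > -slab.L) & (z_mid < 0)
    in_blood = z_mid > 0
    gxx_int = np.where(in_blood, cs.g_B, np.where(in_wall, slab.g_M, cs.g_T))
    gzz_int = np.where(in_blood, cs.g_B, np.where(in_wall, slab.g_zz, cs.g_T))

    # node-row x-conductivity: mean of the adjacent intervals (interface rows
    # carry half blood / half tissue control volumes)
    gxx_row = np.empty(nz)
    gxx_row[0], gxx_row[-1] = gxx_int[0], gxx_int[-1]
    gxx_row[1:-1] = 0.5 * (gxx_int[:-1] + gxx_int[1:])
    dzcv = np.full(nz, dz)
    dzcv[[0, -1]] = dz / 2
    dxcv = np.full(nx, dx)
    dxcv[[0, -1]] = dx / 2

    rows, cols, data = [], [], []

    def add_edges(m, n, c):
        rows.extend((m, n, m, n))
        cols.extend((m, n, n, m))
        data.extend((c, c, -c, -c))

    jj, ii = np.meshgrid(np.arange(nz), np.arange(nx - 1), indexing="ij")
    m = (jj * nx + ii).ravel()
    c = (gxx_row[:, None] * dzcv[:, None] / dx * np.ones((1, nx - 1))).ravel()
    add_edges(m, m + 1, c)

    jj, ii = np.meshgrid(np.arange(nz - 1), np.arange(nx), indexing="ij")
    m = (jj * nx + ii).ravel()
    c = (gzz_int[:, None] * dxcv[None, :] / dz).ravel()
    add_edges(m, m + nx, c)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    A = sp.coo_matrix((data, (rows, cols)), shape=(nx * nz, nx * nz)).tocsr()

    b = np.zeros(nx * nz)
    q = mem.delta * slab.g_i_xx / dx  # line-charge density per unit z (mV*S/m/mm)
    on_sheet = (z >= -slab.L - 1e-12) & (z <= 1e-12)
    w = np.where(
        np.isclose(z, 0.0) | np.isclose(z, -slab.L), 0.5, 1.0
    ) * on_sheet
    i_left, i_right = nx // 2 - 1, nx // 2
    b[np.arange(nz) * nx + i_right] += q * w * dz
    b[np.arange(nz) * nx + i_left] -= q * w * dz

    # pin the gauge at one corner
    pin = 0
    A = A.tolil()
    A.rows[pin] = [pin]
    A.data[pin] = [1.0]
    A = A.tocsr()
    b[pin] = 0.0

    phi = spsolve(A, b)
    resid = A @ phi - b
    resid[pin] = 0.0
    phi = phi - phi.mean()  # recover the odd-in-x gauge
    return PoissonSolution(
        x=x + front_x,
        z=z,
        phi=phi.reshape(nz, nx),
        residual_inf=float(np.max(np.abs(resid))),
    )


def solid_angle_numeric(
    x: float, z: float, L: float, y_half_width: float
) -> float:
    """Solid angle (sr) subtended by the front rectangle at a blood-pool point.

    The rectangle is {x' = 0, z' in [-L, 0], y in [-W, W]} and the
    observation point (x, 0, z) with x the lateral offset from the front.
    The y-integral is done in closed form; the remaining depth integral is
    evaluated by adaptive quadrature.
    """
    if z <= 0:
        raise ValueError("observation point must lie in the blood pool (z > 0)")
    if y_half_width < 100.0 * (z + L):
        warnings.warn(
            "y_half_width below 100*(z+L); strip truncation may exceed tolerance",
            stacklevel=2,
        )
    W = y_half_width

    def integrand(z0: float) -> float:
        Z = z - z0
        r2 = x * x + Z * Z
        return 2.0 * x * W / (r2 * math.sqrt(r2 + W * W))

    val, _ = quad(integrand, -L, 0.0, epsabs=1e-12, epsrel=1e-10, limit=200)
    return val
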