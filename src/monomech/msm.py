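"""Monolayer stress microscopy (MSM).

Recovers the in-plane intercellular stress tensor of a cell sheet from the
traction field it exerts on its substrate.  Newton's laws applied to the
sheet give the force balance

    d(sxx)/dx + d(sxy)/dy = Tx
    d(sxy)/dx + d(syy)/dy = Ty

inside the island domain, with a stress-free boundary (sigma . n = 0 on the
island edge).  The balance alone is underdetermined in 2D; closure follows
the standard MSM recipe: the sheet is modelled as a linear plane-stress
elastic medium with unit fictitious modulus and Poisson ratio ``nu_m``,
loaded by the body force ``-T`` with a free boundary.  The
recovered stress is exactly independent of the fictitious modulus (it
scales out of the linear solve) and only weakly dependent on ``nu_m``.

Stress carries line-stress units (nN/um = mN/m) because monolayer height is
not part of the measurement; tractions in Pa are converted internally via
1 Pa = 1e-3 nN/um^2.

Discretization: bilinear quadrilateral finite elements on the traction
grid; rigid-body modes are removed by zero-mean translation/rotation
constraints (admissible because the net force and torque of the corrected
traction vanish).  Nodal stresses are obtained by local linear
least-squares fits to element-centre stresses (patch recovery), which keeps
the recovered boundary stress consistent with the free-boundary condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import DomainMask, ScalarField2D, VectorField2D, require_units

__all__ = [
    "StressField",
    "recover_stress",
    "tension_map",
    "median_tension",
    "equilibrium_residual",
    "boundary_residual",
]

PA_TO_NN_PER_UM2 = 1.0e-3  # 1 Pa = 1e-3 nN/um^2


@dataclass
class StressField:
    """Symmetric in-plane stress tensor per grid node (line stress, nN/um).

    Values are NaN outside the solved domain.
    """

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    mask: DomainMask
    grid_spacing: float
    nu_m: float

    def __post_init__(self) -> None:
        for a in (self.sxx, self.syy, self.sxy):
            if a.shape != self.mask.shape:
                raise ValueError("stress components must be congruent with mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sxx.shape

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Principal stresses (s1 >= s2) nodewise."""
        mean = 0.5 * (self.sxx + self.syy)
        rad = np.sqrt((0.5 * (self.sxx - self.syy)) ** 2 + self.sxy**2)
        return mean + rad, mean - rad


def _element_matrices(spacing: float, nu_m: float):
    """Stiffness matrix (8x8) of one square bilinear plane-stress element
    with unit fictitious modulus, and the constitutive matrix."""
    C = np.array(
        [[1.0, nu_m, 0.0], [nu_m, 1.0, 0.0], [0.0, 0.0, (1.0 - nu_m) / 2.0]]
    ) / (1.0 - nu_m**2)
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    Ke = np.zeros((8, 8))
    # local node order, counterclockwise: (0,0), (dx,0), (dx,dy), (0,dy)
    for xi in gp:
        for eta in gp:
            dN_dxi = 0.25 * np.array(
                [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]
            )
            dN_deta = 0.25 * np.array(
                [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]
            )
            dN_dx = dN_dxi * 2.0 / spacing
            dN_dy = dN_deta * 2.0 / spacing
            B = np.zeros((3, 8))
            B[0, 0::2] = dN_dx
            B[1, 1::2] = dN_dy
            B[2, 0::2] = dN_dy
            B[2, 1::2] = dN_dx
            Ke += B.T @ C @ B * (spacing / 2.0) ** 2
    return Ke, C


def _center_B(spacing: float) -> np.ndarray:
    dN_dx = np.array([-1.0, 1.0, 1.0, -1.0]) / (2.0 * spacing)
    dN_dy = np.array([-1.0, -1.0, 1.0, 1.0]) / (2.0 * spacing)
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def _consistent_load(spacing: float) -> np.ndarray:
    return (
        spacing**2
        / 36.0
        * np.array([[4, 2, 1, 2], [2, 4, 2, 1], [1, 2, 4, 2], [2, 1, 2, 4]], float)
    )


def remove_rigid_traction(
    tx: np.ndarray, ty: np.ndarray, mask: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Subtract the best-fit uniform + rigid-rotation traction component over
    the mask.  Returns corrected components and the relative magnitude of the
    correction (L2 of removed part / L2 of input)."""
    ii, jj = np.nonzero(mask)
    x = jj * spacing
    y = ii * spacing
    xc, yc = x.mean(), y.mean()
    # basis: (1,0), (0,1), (-(y-yc), (x-xc))
    n = x.size
    A = np.zeros((2 * n, 3))
    A[0::2, 0] = 1.0
    A[1::2, 1] = 1.0
    A[0::2, 2] = -(y - yc)
    A[1::2, 2] = x - xc
    b = np.empty(2 * n)
    b[0::2] = tx[mask]
    b[1::2] = ty[mask]
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    fit = A @ coef
    norm_in = np.linalg.norm(b)
    rel = float(np.linalg.norm(fit) / norm_in) if norm_in > 0 else 0.0
    txc = tx.copy()
    tyc = ty.copy()
    txc[mask] = tx[mask] - fit[0::2]
    tyc[mask] = ty[mask] - fit[1::2]
    return txc, tyc, rel


def recover_stress(
    traction: VectorField2D,
    omega: DomainMask,
    nu_m: float = 0.9,
    max_imbalance: float = 0.05,
) -> StressField:
    """Recover the monolayer stress tensor from a traction field.

    Parameters
    ----------
    traction : VectorField2D
        Traction the cells exert on the substrate, in Pa, on a regular grid.
    omega : DomainMask
        Island domain (simply connected).
    nu_m : float
        Poisson ratio of the fictitious closure sheet.  The default 0.9
        sits near the 2D-incompressible limit (nu -> 1 for a plane-stress
        sheet; exactly 1 is singular), where the closure reproduces the
        statically expected tension of radially loaded islands; the median
        tension is insensitive to the choice.
    max_imbalance : float
        Refuse if the rigid (net force + torque) component of the traction
        exceeds this fraction of its total magnitude; smaller imbalances are
        projected out and the correction logged on the result.
    """
    require_units(traction.units, "Pa")
    omega.check_congruent(traction)
    spacing = traction.grid_spacing
    mask = omega.mask

    tx = traction.vx * PA_TO_NN_PER_UM2
    ty = traction.vy * PA_TO_NN_PER_UM2
    tx = np.where(mask, tx, 0.0)
    ty = np.where(mask, ty, 0.0)

    total = float(np.hypot(tx[mask], ty[mask]).sum())
    if total > 0:
        txc, tyc, rel = remove_rigid_traction(tx, ty, mask, spacing)
        if rel > max_imbalance:
            raise ValueError(
                f"net force/torque component is {rel:.1%} of traction magnitude "
                f"(> {max_imbalance:.0%}); refusing to solve"
            )
        tx, ty = txc, tyc
    else:
        rel = 0.0

    # elements fully inside the mask
    el = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, 1:] & mask[1:, :-1]
    ei, ej = np.nonzero(el)
    if ei.size == 0:
        raise ValueError("mask contains no complete grid cell")

    ny, nx = mask.shape
    # nodes participating in at least one element
    node_used = np.zeros((ny, nx), dtype=bool)
    for di, dj in ((0, 0), (0, 1), (1, 1), (1, 0)):
        node_used[ei + di, ej + dj] = True
    node_ids = -np.ones((ny, nx), dtype=int)
    ui, uj = np.nonzero(node_used)
    node_ids[ui, uj] = np.arange(ui.size)
    n_nodes = ui.size

    # connectivity (counterclockwise in x-y): (i,j), (i,j+1), (i+1,j+1), (i+1,j)
    conn = np.stack(
        [
            node_ids[ei, ej],
            node_ids[ei, ej + 1],
            node_ids[ei + 1, ej + 1],
            node_ids[ei + 1, ej],
        ],
        axis=1,
    )

    Ke, _C = _element_matrices(spacing, nu_m)
    Me = _consistent_load(spacing)

    # assemble stiffness
    dof = np.empty((conn.shape[0], 8), dtype=int)
    dof[:, 0::2] = 2 * conn
    dof[:, 1::2] = 2 * conn + 1
    rows = np.repeat(dof, 8, axis=1).ravel()
    cols = np.tile(dof, (1, 8)).ravel()
    vals = np.tile(Ke.ravel(), conn.shape[0])
    K = sp.coo_matrix((vals, (rows, cols)), shape=(2 * n_nodes, 2 * n_nodes)).tocsr()

    # consistent body-force load, f = -T
    fx_n = -tx[ui, uj]
    fy_n = -ty[ui, uj]
    F = np.zeros(2 * n_nodes)
    fe_x = fx_n[conn] @ Me.T
    fe_y = fy_n[conn] @ Me.T
    np.add.at(F, 2 * conn.ravel(), fe_x.ravel())
    np.add.at(F, 2 * conn.ravel() + 1, fe_y.ravel())

    # rigid-body constraints: zero mean translation and rotation
    x = uj * spacing
    y = ui * spacing
    xc, yc = x.mean(), y.mean()
    Crows = np.zeros((3, 2 * n_nodes))
    Crows[0, 0::2] = 1.0
    Crows[1, 1::2] = 1.0
    Crows[2, 0::2] = -(y - yc)
    Crows[2, 1::2] = x - xc
    Crows /= np.linalg.norm(Crows, axis=1, keepdims=True)
    Csp = sp.csr_matrix(Crows)

    KKT = sp.bmat([[K, Csp.T], [Csp, None]], format="csc")
    rhs = np.concatenate([F, np.zeros(3)])
    sol = spla.spsolve(KKT, rhs)
    u = sol[: 2 * n_nodes]

    # element-centre stresses
    Bc = _center_B(spacing)
    C = np.array(
        [[1.0, nu_m, 0.0], [nu_m, 1.0, 0.0], [0.0, 0.0, (1.0 - nu_m) / 2.0]]
    ) / (1.0 - nu_m**2)
    ue = u[dof]  # (n_el, 8)
    sig_el = ue @ (C @ Bc).T  # (n_el, 3): sxx, syy, sxy at centres
    cx = (ej + 0.5) * spacing
    cy = (ei + 0.5) * spacing

    sxx, syy, sxy = _patch_recover(
        sig_el, cx, cy, ei, ej, ui, uj, spacing, (ny, nx)
    )

    out = StressField(sxx, syy, sxy, omega, spacing, nu_m)
    out.rigid_correction = rel  # type: ignore[attr-defined]
    return out


def _patch_recover(sig_el, cx, cy, ei, ej, ui, uj, spacing, shape):
    """Nodal stress by per-node linear least squares over adjacent element
    centres (superconvergent patch recovery); falls back to the patch mean
    where fewer than 3 elements are available."""
    ny, nx = shape
    el_index = -np.ones((ny - 1, nx - 1), dtype=int)
    el_index[ei, ej] = np.arange(ei.size)
    has_el = el_index >= 0
    comp_grids = [np.zeros((ny - 1, nx - 1)) for _ in range(3)]
    for c in range(3):
        comp_grids[c][ei, ej] = sig_el[:, c]

    # interior nodes: the 4 adjacent element centres form a symmetric patch,
    # so the linear fit reduces to their plain average (vectorized)
    counts = np.zeros((ny, nx))
    sums = [np.zeros((ny, nx)) for _ in range(3)]
    for di, dj in ((0, 0), (0, 1), (1, 0), (1, 1)):
        sl = (slice(di, ny - 1 + di), slice(dj, nx - 1 + dj))
        counts[sl] += has_el
        for c in range(3):
            sums[c][sl] += comp_grids[c]
    sxx = np.full((ny, nx), np.nan)
    syy = np.full((ny, nx), np.nan)
    sxy = np.full((ny, nx), np.nan)
    full = counts == 4
    for c, out in zip(range(3), (sxx, syy, sxy)):
        out[full] = sums[c][full] / 4.0

    # boundary nodes: linear least squares over elements within 2 cells
    part = ~full[ui, uj]
    for i0, j0 in zip(ui[part], uj[part]):
        lo_i, hi_i = max(i0 - 2, 0), min(i0 + 2, ny - 1)
        lo_j, hi_j = max(j0 - 2, 0), min(j0 + 2, nx - 1)
        patch = el_index[lo_i:hi_i, lo_j:hi_j]
        e = patch[patch >= 0]
        xs = cx[e] - j0 * spacing
        ys = cy[e] - i0 * spacing
        S = sig_el[e]
        if e.size >= 3:
            A = np.column_stack([np.ones(e.size), xs, ys])
            coef, *_ = np.linalg.lstsq(A, S, rcond=None)
            val = coef[0]
        elif e.size > 0:
            val = S.mean(axis=0)
        else:
            continue
        sxx[i0, j0], syy[i0, j0], sxy[i0, j0] = val
    return sxx, syy, sxy


def tension_map(stress: StressField) -> ScalarField2D:
    """Monolayer tension: average principal stress (s1+s2)/2 = (sxx+syy)/2."""
    return ScalarField2D(
        0.5 * (stress.sxx + stress.syy), stress.grid_spacing, "nN/um"
    )


def median_tension(tension: ScalarField2D, omega: DomainMask) -> float:
    """Median tension over the island nodes, in nN/um."""
    require_units(tension.units, "nN/um")
    omega.check_congruent(tension)
    vals = tension.values[omega.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite tension values inside the mask")
    return float(np.median(vals))


def equilibrium_residual(
    stress: StressField, traction: VectorField2D, collar: int = 3
) -> float:
    """Relative L2 residual of the discrete force balance div(sigma) = T
    (centred differences; traction converted to nN/um^2).

    The residual is evaluated on nodes at least ``collar`` cells inside the
    domain boundary: the outermost cells carry the traction discontinuity
    of the stress-free edge and one-sided stress recovery, where a centred
    finite-difference check of a weak-form solution is not consistent.
    """
    require_units(traction.units, "Pa")
    mask = stress.mask.mask & np.isfinite(stress.sxx)
    h = stress.grid_spacing
    interior = ndimage_erosion(mask, collar)
    if not interior.any():
        raise ValueError("mask too small for the requested collar")

    def ddx(a):
        return (np.roll(a, -1, 1) - np.roll(a, 1, 1)) / (2 * h)

    def ddy(a):
        return (np.roll(a, -1, 0) - np.roll(a, 1, 0)) / (2 * h)

    rx = ddx(stress.sxx) + ddy(stress.sxy) - traction.vx * PA_TO_NN_PER_UM2
    ry = ddx(stress.sxy) + ddy(stress.syy) - traction.vy * PA_TO_NN_PER_UM2
    num = np.sqrt(np.nansum(rx[interior] ** 2 + ry[interior] ** 2))
    den = np.sqrt(
        np.sum(
            (traction.vx[interior] * PA_TO_NN_PER_UM2) ** 2
            + (traction.vy[interior] * PA_TO_NN_PER_UM2) ** 2
        )
    )
    if den == 0:
        return 0.0
    return float(num / den)


def ndimage_erosion(mask: np.ndarray, iterations: int) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    out = binary_erosion(mask, iterations=iterations)
    out[0, :] = out[-1, :] = False
    out[:, 0] = out[:, -1] = False
    return out


def boundary_residual(stress: StressField) -> float:
    """RMS of |sigma . n| over boundary nodes, relative to the median
    interior tension: the free-boundary diagnostic.  Outward normals are
    estimated from a Gaussian-smoothed mask (sigma = 2 cells) to average
    out the staircase of the discrete boundary."""
    from scipy.ndimage import gaussian_filter

    mask = stress.mask.mask
    solved = np.isfinite(stress.sxx)
    interior = ndimage_erosion(mask, 1)
    boundary = mask & ~interior & solved

    sm = gaussian_filter(mask.astype(float), 2.0)
    gy, gx = np.gradient(sm)
    nxc = -gx[boundary]
    nyc = -gy[boundary]
    norm = np.hypot(nxc, nyc)
    norm[norm == 0] = 1.0
    nxc /= norm
    nyc /= norm

    tx = stress.sxx[boundary] * nxc + stress.sxy[boundary] * nyc
    ty = stress.sxy[boundary] * nxc + stress.syy[boundary] * nyc
    rms = float(np.sqrt(np.nanmean(tx**2 + ty**2)))

    ten = 0.5 * (stress.sxx + stress.syy)
    ref = float(np.nanmedian(np.abs(ten[ndimage_erosion(mask, 2) & solved])))
    if ref == 0:
        return rms
    return rms / ref
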