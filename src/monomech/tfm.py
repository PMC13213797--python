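"""Traction force microscopy.

Two stages: (1) substrate displacement estimation by windowed digital image
correlation (DIC) between a bead image under load and the trypsin-released
reference, with subpixel peak localization; (2) traction recovery by
unconstrained Fourier-transform traction cytometry (FTTC) on a gel of finite
thickness bonded to rigid glass.

Elastic kernel
--------------
In Fourier space the surface displacement responds to surface traction via a
2x2 tensor ``u_hat(k) = G_hat(k) . T_hat(k)``.  Decomposed along the unit
wavevector ``k_hat`` (longitudinal) and its perpendicular (transverse),

    G_hat(k) = 2(1+nu)/(E k) * [ c_T(kh) (I - k_hat k_hat^T)
                                 + (1-nu) c_L(kh, nu) k_hat k_hat^T ]

where ``h`` is gel thickness.  ``c_T(kh) = tanh(kh)`` is the exact antiplane
(shear) factor for a layer clamped at its base, and

    c_L(kh, nu) = [2kh + (3-4nu) sinh(2kh)]
                  / [(3-4nu) cosh(2kh) + 2(kh)^2 + 8nu^2 - 12nu + 5]

is the exact plane-strain factor for tangential surface load with zero
normal surface traction and a rigidly bonded base (derived from the
biharmonic layer solution).  Both factors go to 1 as ``kh -> inf``,
recovering the Boussinesq half-space tensor, and to the thin-layer shear-lag
limit ``u = 2(1+nu) h T / E`` as ``kh -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .core import (
    DomainMask,
    ImageFrame,
    ScalarField2D,
    SubstrateSpec,
    UnitsError,
    VectorField2D,
    require_units,
)

__all__ = [
    "DisplacementField",
    "dic_displacements",
    "greens_kernel",
    "forward_displacement",
    "fttc_inverse",
    "drift_correct",
    "median_traction",
]


@dataclass
class DisplacementField:
    """Substrate surface displacement (um) with a per-window quality map."""

    field: VectorField2D
    quality: np.ndarray  # in [0, 1], congruent with field

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=float)
        if self.quality.shape != self.field.shape:
            raise ValueError("quality map must be congruent with the field")


# ----------------------------------------------------------------------------
# Digital image correlation
# ----------------------------------------------------------------------------

def _inpaint_invalid(vx: np.ndarray, vy: np.ndarray, valid: np.ndarray) -> None:
    """Replace invalid nodes by the median of their valid 8-neighbours,
    iterating until every node is filled (in place)."""
    ny, nx = vx.shape
    while not valid.all():
        filled_any = False
        bad = np.argwhere(~valid)
        for i, j in bad:
            i0, i1 = max(i - 1, 0), min(i + 2, ny)
            j0, j1 = max(j - 1, 0), min(j + 2, nx)
            sel = valid[i0:i1, j0:j1]
            if sel.any():
                vx[i, j] = np.median(vx[i0:i1, j0:j1][sel])
                vy[i, j] = np.median(vy[i0:i1, j0:j1][sel])
                valid[i, j] = True
                filled_any = True
        if not filled_any:  # completely invalid field
            raise ValueError("no valid correlation windows anywhere")


def dic_displacements(
    ref: ImageFrame,
    deformed: ImageFrame,
    window: int = 32,
    step: int = 16,
    q_min: float = 0.2,
    upsample_factor: int = 100,
) -> DisplacementField:
    """Windowed cross-correlation displacement field, deformed vs reference.

    The displacement convention is material displacement: the deformed image
    satisfies ``deformed(x) = ref(x - u(x))``.  Subpixel localization uses
    upsampled-DFT phase correlation per window; windows whose registration
    quality falls below ``q_min`` (or that are textureless) are marked
    invalid and inpainted by the median of valid neighbours.

    Returns displacements in micrometres on a grid with spacing
    ``step * pixel_size``.
    """
    if ref.shape != deformed.shape:
        raise ValueError("reference and deformed frames must be congruent")
    if window < 16:
        raise ValueError("window must be >= 16 px")
    H, W = ref.shape
    if window > min(H, W):
        raise ValueError("window larger than image")
    a = np.asarray(ref.image, dtype=float)
    b = np.asarray(deformed.image, dtype=float)

    half = window // 2
    rows = np.arange(half, H - half + 1, step)
    cols = np.arange(half, W - half + 1, step)
    ux = np.zeros((rows.size, cols.size))
    uy = np.zeros_like(ux)
    quality = np.zeros_like(ux)
    valid = np.zeros(ux.shape, dtype=bool)
    # zero-mean + Hann apodization suppresses the circular-correlation edge
    # leakage that otherwise biases subpixel peaks by ~0.1 px
    hann = np.outer(np.hanning(window), np.hanning(window))

    for ii, r in enumerate(rows):
        for jj, c in enumerate(cols):
            wa = a[r - half : r + half, c - half : c + half]
            wb = b[r - half : r + half, c - half : c + half]
            if wa.std() < 1e-12 or wb.std() < 1e-12:
                continue
            shift, error, _ = phase_cross_correlation(
                (wa - wa.mean()) * hann,
                (wb - wb.mean()) * hann,
                upsample_factor=upsample_factor,
                normalization=None,
            )
            q = float(np.clip(1.0 - error, 0.0, 1.0))
            # shift registers deformed onto reference, i.e. equals -u
            uy[ii, jj] = -shift[0]
            ux[ii, jj] = -shift[1]
            quality[ii, jj] = q
            valid[ii, jj] = q >= q_min and np.hypot(*shift) < half

    if not valid.any():
        raise ValueError("textureless or uncorrelated input: no valid windows")
    _inpaint_invalid(ux, uy, valid)

    px = ref.pixel_size
    fld = VectorField2D(
        ux * px,
        uy * px,
        grid_spacing=step * px,
        units="um",
        origin=(cols[0] * px, rows[0] * px),
    )
    return DisplacementField(fld, quality)


# ----------------------------------------------------------------------------
# Elastic kernel
# ----------------------------------------------------------------------------

def _finite_thickness_factors(kh: np.ndarray, nu: float) -> tuple[np.ndarray, np.ndarray]:
    """(c_T, c_L) compliance factors for a layer bonded to a rigid base."""
    kh = np.asarray(kh, dtype=float)
    c_t = np.tanh(kh)
    # guard the exponentials; for kh > 20 both factors are 1 to < 1e-16
    khc = np.minimum(kh, 20.0)
    m = 3.0 - 4.0 * nu
    num = 2.0 * khc + m * np.sinh(2.0 * khc)
    den = m * np.cosh(2.0 * khc) + 2.0 * khc**2 + 8.0 * nu**2 - 12.0 * nu + 5.0
    c_l = np.where(kh >= 20.0, 1.0, num / den)
    return c_t, c_l


def greens_kernel(
    kx: np.ndarray, ky: np.ndarray, substrate: SubstrateSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier-space surface response tensor ``G_hat(k)`` in um/Pa.

    Parameters are angular wavevector components (rad/um).  Returns the
    three independent entries ``(G11, G12, G22)`` broadcast over the input
    arrays.  Entries at ``k = 0`` are returned as 0 (the DC mode carries no
    information in unconstrained FTTC and is handled by the DC policy of the
    forward/inverse operators).
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    E = substrate.youngs_modulus_pa
    nu = substrate.poisson_ratio
    ksafe = np.where(k == 0, 1.0, k)
    khx = kx / ksafe
    khy = ky / ksafe

    if substrate.is_half_space:
        c_t = np.ones_like(ksafe)
        c_l = np.ones_like(ksafe)
    else:
        c_t, c_l = _finite_thickness_factors(k * substrate.thickness_um, nu)

    pref = 2.0 * (1.0 + nu) / (E * ksafe)
    lon = (1.0 - nu) * c_l
    g11 = pref * (c_t * (1.0 - khx**2) + lon * khx**2)
    g22 = pref * (c_t * (1.0 - khy**2) + lon * khy**2)
    g12 = pref * (lon - c_t) * khx * khy
    zero = k == 0
    for g in (g11, g12, g22):
        g[zero] = 0.0
    return g11, g12, g22


def _fft_wavevectors(shape: tuple[int, int], spacing: float):
    ky = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=spacing)
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=spacing)
    return np.meshgrid(kx, ky)


def _padded_shape(shape: tuple[int, int], pad_factor: float) -> tuple[int, int]:
    return tuple(int(np.ceil(n * pad_factor / 2) * 2) for n in shape)


def forward_displacement(
    traction: VectorField2D,
    substrate: SubstrateSpec,
    pad_factor: float = 2.0,
) -> VectorField2D:
    """Surface displacement generated by a traction field (exact linear
    forward model; the adjoint-consistent oracle of :func:`fttc_inverse`).

    The traction field is zero-padded by ``pad_factor`` before the FFT; the
    DC term of the displacement is set to zero.
    """
    require_units(traction.units, "Pa")
    ny, nx = traction.shape
    pshape = _padded_shape((ny, nx), pad_factor)
    tx = np.zeros(pshape)
    ty = np.zeros(pshape)
    tx[:ny, :nx] = traction.vx
    ty[:ny, :nx] = traction.vy
    kxg, kyg = _fft_wavevectors(pshape, traction.grid_spacing)
    g11, g12, g22 = greens_kernel(kxg, kyg, substrate)
    txh = np.fft.fft2(tx)
    tyh = np.fft.fft2(ty)
    uxh = g11 * txh + g12 * tyh
    uyh = g12 * txh + g22 * tyh
    uxh[0, 0] = 0.0
    uyh[0, 0] = 0.0
    ux = np.fft.ifft2(uxh).real[:ny, :nx]
    uy = np.fft.ifft2(uyh).real[:ny, :nx]
    return traction.with_values(ux, uy, units="um")


def fttc_inverse(
    displacement: VectorField2D,
    substrate: SubstrateSpec,
    pad_factor: float = 2.0,
    cutoff_wavelength: float | None = None,
    taper_fraction: float = 0.0,
) -> VectorField2D:
    """Unconstrained FTTC: per-wavevector inversion of the elastic kernel.

    No regularization penalty is applied; optional noise control is a hard
    spectral cutoff removing wavelengths shorter than ``cutoff_wavelength``
    (um) and an optional cosine taper at the field border
    (``taper_fraction`` of each dimension) to suppress periodicity
    artifacts.  The DC traction is set to zero (zero net force).  With no
    cutoff and no taper, ``fttc_inverse(forward_displacement(T)) == T`` to
    numerical precision on the same grid.
    """
    require_units(displacement.units, "um")
    ny, nx = displacement.shape
    ux = displacement.vx.copy()
    uy = displacement.vy.copy()
    if taper_fraction > 0:
        wy = np.ones(ny)
        wx = np.ones(nx)
        my = max(int(round(taper_fraction * ny)), 1)
        mx = max(int(round(taper_fraction * nx)), 1)
        ramp_y = 0.5 * (1 - np.cos(np.pi * np.arange(my) / my))
        ramp_x = 0.5 * (1 - np.cos(np.pi * np.arange(mx) / mx))
        wy[:my] = ramp_y
        wy[-my:] = ramp_y[::-1]
        wx[:mx] = ramp_x
        wx[-mx:] = ramp_x[::-1]
        win = np.outer(wy, wx)
        ux *= win
        uy *= win
    pshape = _padded_shape((ny, nx), pad_factor)
    pux = np.zeros(pshape)
    puy = np.zeros(pshape)
    pux[:ny, :nx] = ux
    puy[:ny, :nx] = uy
    kxg, kyg = _fft_wavevectors(pshape, displacement.grid_spacing)
    g11, g12, g22 = greens_kernel(kxg, kyg, substrate)
    det = g11 * g22 - g12**2
    det[0, 0] = 1.0
    uxh = np.fft.fft2(pux)
    uyh = np.fft.fft2(puy)
    txh = (g22 * uxh - g12 * uyh) / det
    tyh = (-g12 * uxh + g11 * uyh) / det
    txh[0, 0] = 0.0
    tyh[0, 0] = 0.0
    if cutoff_wavelength is not None:
        k = np.hypot(kxg, kyg)
        keep = k <= 2.0 * np.pi / cutoff_wavelength
        txh *= keep
        tyh *= keep
    tx = np.fft.ifft2(txh).real[:ny, :nx]
    ty = np.fft.ifft2(tyh).real[:ny, :nx]
    return displacement.with_values(tx, ty, units="Pa")


# ----------------------------------------------------------------------------
# Post-processing
# ----------------------------------------------------------------------------

def drift_correct(
    displacement: VectorField2D, far_field: np.ndarray
) -> VectorField2D:
    """Subtract the median displacement over cell-free nodes (``far_field``
    boolean array congruent with the field) to remove stage drift."""
    require_units(displacement.units, "um")
    far_field = np.asarray(far_field, dtype=bool)
    if far_field.shape != displacement.shape:
        raise ValueError("far_field mask must be congruent with the field")
    if not far_field.any():
        raise ValueError("far_field mask is empty")
    dx = float(np.median(displacement.vx[far_field]))
    dy = float(np.median(displacement.vy[far_field]))
    return displacement.with_values(displacement.vx - dx, displacement.vy - dy)


def median_traction(traction: VectorField2D, mask: DomainMask) -> float:
    """Median of the traction magnitude |T| over the island mask, in Pa."""
    require_units(traction.units, "Pa")
    mask.check_congruent(traction)
    mag = np.hypot(traction.vx, traction.vy)
    return float(np.median(mag[mask.mask]))


def net_force_residual(traction: VectorField2D, mask: DomainMask) -> float:
    """|net force| / sum |T| over the mask (dimensionless diagnostic)."""
    require_units(traction.units, "Pa")
    mask.check_congruent(traction)
    m = mask.mask
    fx = float(traction.vx[m].sum())
    fy = float(traction.vy[m].sum())
    total = float(np.hypot(traction.vx[m], traction.vy[m]).sum())
    if total == 0:
        return 0.0
    return float(np.hypot(fx, fy) / total)
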