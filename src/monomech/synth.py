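"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage has a generator here producing inputs whose true
answer is known in closed form or by construction: speckle (bead) images
with subpixel Gaussian spots, image warps by prescribed displacement
fields, spatially correlated Gaussian random fields with exponential
autocovariance, anisotropic Voronoi label masks, contractile-island
traction fields with an exact monolayer-stress solution, and textured
monolayer timelapses following a prescribed speed schedule.

All generators are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import (
    AcquisitionSpec,
    DomainMask,
    ImageFrame,
    ImageStack,
    VectorField2D,
    bilinear_sample,
    require_units,
)
from .msm import StressField

__all__ = [
    "FlowSchedule",
    "IslandRecipe",
    "gen_speckle_image",
    "warp_image",
    "gen_correlated_field",
    "gen_island_traction",
    "gen_label_mask",
    "gen_jamming_timelapse",
]


@dataclass(frozen=True)
class FlowSchedule:
    """Per-interval mean speed targets and a direction-field recipe.

    ``speeds_um_per_h`` has one entry per frame interval; the generated
    timelapse has ``len(speeds) + 1`` frames.  Recipes: ``uniform`` (one
    random direction for the whole movie), ``swirl`` (rigid rotation about
    the image centre), ``correlated`` (a frozen random direction field with
    correlation length ``xi_um``).
    """

    speeds_um_per_h: tuple[float, ...]
    direction: str = "uniform"
    xi_um: float = 100.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.speeds_um_per_h):
            raise ValueError("speeds must be >= 0")
        if self.direction not in ("uniform", "swirl", "correlated"):
            raise ValueError(f"unknown direction recipe {self.direction!r}")


@dataclass(frozen=True)
class IslandRecipe:
    """Contractile micropatterned island with a closed-form stress state.

    The ``parabolic-tension`` profile has isotropic line tension
    ``sigma(r) = sigma0 (1 - r^2/R^2)`` inside radius R and zero outside;
    force balance then fixes the traction to ``T_r(r) = -2 sigma0 r / R^2``
    (radially inward, i.e. contractile).  Net force and torque vanish by
    symmetry.
    """

    radius_um: float = 500.0
    sigma0_nn_per_um: float = 1.0
    profile: str = "parabolic-tension"
    bead_density_per_um2: float = 0.02
    seed: int = 0
    grid_shape: tuple[int, int] = (256, 256)
    grid_spacing_um: float | None = None  # default: grid spans 2x island extent

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.sigma0_nn_per_um < 0:
            raise ValueError("sigma0 must be >= 0")

    @property
    def spacing(self) -> float:
        if self.grid_spacing_um is not None:
            return self.grid_spacing_um
        # grid span = 4R: the island (diameter 2R) sits in a field twice its
        # extent, the stated precondition of the Fourier forward model
        return 4.0 * self.radius_um / self.grid_shape[1]


# ----------------------------------------------------------------------------
# Speckle / bead images
# ----------------------------------------------------------------------------

def gen_speckle_image(
    shape_px: tuple[int, int],
    density_per_um2: float,
    pixel_size: float,
    seed: int,
    psf_sigma_px: float = 1.0,
    background: float = 100.0,
    amplitude: float = 1000.0,
) -> ImageFrame:
    """Render sub-resolution fluorescent beads as Gaussian spots with
    subpixel centres.  The spot count is Poisson with mean
    ``density * imaged area``; density 0 gives a uniform background."""
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape_px
    area_um2 = H * W * pixel_size**2
    n = int(rng.poisson(density_per_um2 * area_um2))
    window_um2 = (32 * pixel_size) ** 2
    if 0 < density_per_um2 * window_um2 < 5:
        warnings.warn(
            "bead density yields < 5 particles per 32 px correlation window; "
            "DIC windows may be textureless",
            stacklevel=2,
        )
    img = np.full((H, W), background, dtype=float)
    if n > 0:
        ys = rng.uniform(0, H, n)
        xs = rng.uniform(0, W, n)
        amps = amplitude * rng.uniform(0.6, 1.0, n)
        r = int(np.ceil(4 * psf_sigma_px))
        for y0, x0, a in zip(ys, xs, amps):
            iy0, ix0 = int(np.floor(y0)), int(np.floor(x0))
            sl_y = slice(max(iy0 - r, 0), min(iy0 + r + 2, H))
            sl_x = slice(max(ix0 - r, 0), min(ix0 + r + 2, W))
            yy = np.arange(sl_y.start, sl_y.stop)
            xx = np.arange(sl_x.start, sl_x.stop)
            gy = np.exp(-((yy - y0) ** 2) / (2 * psf_sigma_px**2))
            gx = np.exp(-((xx - x0) ** 2) / (2 * psf_sigma_px**2))
            img[sl_y, sl_x] += a * np.outer(gy, gx)
    return ImageFrame(img, pixel_size)


def warp_image(frame: ImageFrame, u: VectorField2D) -> ImageFrame:
    """Resample intensities at ``x - u(x)``: material that was at ``x - u``
    appears at ``x``.  ``u`` must carry micrometre units; it may live on a
    coarser grid than the image (bilinear interpolation to pixel centres).
    Pure integer-pixel translations are reproduced exactly in the interior
    (interpolating cubic spline)."""
    require_units(u.units, "um")
    H, W = frame.shape
    px = frame.pixel_size
    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    x_um = jj * px
    y_um = ii * px
    ux_px = bilinear_sample(u.vx, x_um, y_um, u.grid_spacing, u.origin) / px
    uy_px = bilinear_sample(u.vy, x_um, y_um, u.grid_spacing, u.origin) / px
    warped = ndi.map_coordinates(
        np.asarray(frame.image, dtype=float),
        [ii - uy_px, jj - ux_px],
        order=3,
        mode="reflect",
    )
    return ImageFrame(warped, px)


# ----------------------------------------------------------------------------
# Correlated random fields
# ----------------------------------------------------------------------------

def _correlated_scalar(
    xi_um: float, shape: tuple[int, int], spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """One periodic stationary Gaussian field whose target autocovariance is
    exp(-r/xi), synthesized spectrally from the 2D exponential-covariance
    power spectrum S(k) ~ (1 + (k xi)^2)^(-3/2); normalized to unit sample
    variance."""
    ky = 2 * np.pi * np.fft.fftfreq(shape[0], d=spacing)
    kx = 2 * np.pi * np.fft.fftfreq(shape[1], d=spacing)
    kxg, kyg = np.meshgrid(kx, ky)
    k2 = kxg**2 + kyg**2
    spec = (1.0 + k2 * xi_um**2) ** (-0.75)
    noise = rng.standard_normal(shape)
    f = np.fft.ifft2(np.fft.fft2(noise) * spec).real
    f -= f.mean()
    return f / f.std()


def gen_correlated_field(
    xi_um: float,
    rms: float,
    shape: tuple[int, int],
    grid_spacing: float,
    seed: int,
    units: str = "um/h",
) -> VectorField2D:
    """Stationary Gaussian vector field with per-component autocovariance
    exp(-r/xi) (periodic synthesis; analyze the central half-window to avoid
    wrap-around).  Each component is normalized to sample RMS ``rms``."""
    if xi_um < 2 * grid_spacing:
        raise ValueError(
            f"xi = {xi_um} um is under-resolved by grid spacing {grid_spacing} um"
        )
    rng = np.random.default_rng(seed)
    vx = _correlated_scalar(xi_um, shape, grid_spacing, rng) * rms
    vy = _correlated_scalar(xi_um, shape, grid_spacing, rng) * rms
    return VectorField2D(vx, vy, grid_spacing, units)


# ----------------------------------------------------------------------------
# Contractile island
# ----------------------------------------------------------------------------

def gen_island_traction(
    recipe: IslandRecipe,
) -> tuple[VectorField2D, StressField, DomainMask]:
    """Traction field (Pa) of a contractile disk island together with the
    exact monolayer-stress oracle and the island mask.

    Line-stress/traction unit bookkeeping: sigma0 in nN/um and R in um give
    traction 2 sigma0 r / R^2 in nN/um^2 = kPa, converted to Pa.
    """
    if recipe.profile != "parabolic-tension":
        raise ValueError(f"unknown island profile {recipe.profile!r}")
    ny, nx = recipe.grid_shape
    h = recipe.spacing
    R = recipe.radius_um
    s0 = recipe.sigma0_nn_per_um
    cx = (nx - 1) / 2.0 * h
    cy = (ny - 1) / 2.0 * h
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    x = jj * h - cx
    y = ii * h - cy
    r = np.hypot(x, y)
    inside = r < R

    # T = -2 sigma0 r / R^2 * r_hat   [nN/um^2]; 1 nN/um^2 = 1000 Pa
    with np.errstate(invalid="ignore", divide="ignore"):
        tmag = np.where(inside, 2.0 * s0 * r / R**2, 0.0)
        rhatx = np.where(r > 0, x / np.where(r > 0, r, 1.0), 0.0)
        rhaty = np.where(r > 0, y / np.where(r > 0, r, 1.0), 0.0)
    tx = -tmag * rhatx * 1000.0
    ty = -tmag * rhaty * 1000.0
    traction = VectorField2D(tx, ty, h, "Pa")

    mask = DomainMask(inside, h)
    ten = np.where(inside, s0 * (1.0 - r**2 / R**2), np.nan)
    zeros = np.where(inside, 0.0, np.nan)
    oracle = StressField(ten.copy(), ten.copy(), zeros, mask, h, nu_m=0.5)
    return traction, oracle, mask


# ----------------------------------------------------------------------------
# Label masks
# ----------------------------------------------------------------------------

def gen_label_mask(
    n_cells: int,
    anisotropy: float,
    seed: int,
    shape_px: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    jitter: float = 0.35,
) -> np.ndarray:
    """Anisotropic Voronoi tessellation of a jittered lattice.

    Cells are Voronoi regions of lattice sites jittered in a virtual
    isotropic domain and then stretched by ``anisotropy`` along x, so the
    mean cell aspect ratio grows monotonically with ``anisotropy``.
    Returns an integer label image with labels 1..n_cells covering the
    frame (no background).
    """
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4")
    if anisotropy < 1:
        raise ValueError("anisotropy must be >= 1")
    rng = np.random.default_rng(seed)
    H, W = shape_px
    wv = W / anisotropy  # virtual (isotropic) domain width
    s = np.sqrt(wv * H / n_cells)
    nc = max(2, int(round(wv / s)))
    nr = int(np.ceil(n_cells / nc))
    xs = (np.arange(nc) + 0.5) * wv / nc
    ys = (np.arange(nr) + 0.5) * H / nr
    sx, sy = np.meshgrid(xs, ys)
    sites = np.column_stack([sx.ravel(), sy.ravel()])
    sites[:, 0] += rng.uniform(-jitter, jitter, sites.shape[0]) * wv / nc
    sites[:, 1] += rng.uniform(-jitter, jitter, sites.shape[0]) * H / nr
    rng.shuffle(sites, axis=0)
    sites = sites[:n_cells]

    jjpix, iipix = np.meshgrid(np.arange(W), np.arange(H))
    query = np.column_stack(
        [jjpix.ravel() / anisotropy, iipix.ravel().astype(float)]
    )
    _, idx = cKDTree(sites).query(query)
    return (idx.reshape(H, W) + 1).astype(np.int32)


# ----------------------------------------------------------------------------
# Jamming timelapse
# ----------------------------------------------------------------------------

def _direction_field(
    schedule: FlowSchedule,
    shape_px: tuple[int, int],
    pixel_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-mean-magnitude direction field (dx, dy) on the pixel grid."""
    H, W = shape_px
    if schedule.direction == "uniform":
        theta = rng.uniform(0, 2 * np.pi)
        return (
            np.full((H, W), np.cos(theta)),
            np.full((H, W), np.sin(theta)),
        )
    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    if schedule.direction == "swirl":
        x = (jj - (W - 1) / 2.0) * pixel_size
        y = (ii - (H - 1) / 2.0) * pixel_size
        dx, dy = -y, x
    else:  # correlated
        f = gen_correlated_field(
            schedule.xi_um, 1.0, (H, W), pixel_size, int(rng.integers(2**31)),
            units="um",
        )
        dx, dy = f.vx, f.vy
    mean_mag = np.hypot(dx, dy).mean()
    return dx / mean_mag, dy / mean_mag


def gen_jamming_timelapse(
    schedule: FlowSchedule,
    seed: int,
    shape_px: tuple[int, int] = (256, 256),
    pixel_size: float = 0.65,
    frame_interval_min: float = 6.0,
    texture_density_per_um2: float = 0.05,
) -> tuple[ImageStack, np.ndarray]:
    """Timelapse of a persistent texture advected by a prescribed speed
    schedule; returns the stack and the imposed per-interval mean speeds
    (um/h).  Successive frames are warps of the same texture by the
    cumulative displacement, so the spatial-mean interval speed matches the
    schedule by construction."""
    rng = np.random.default_rng(seed)
    speeds = np.asarray(schedule.speeds_um_per_h, dtype=float)
    n_frames = speeds.size + 1
    dt_h = frame_interval_min / 60.0

    disp_px = speeds * dt_h / pixel_size
    if np.any((disp_px > 0) & (disp_px < 0.05)):
        warnings.warn(
            "schedule contains sub-resolution (< 0.05 px) displacements",
            stacklevel=2,
        )

    texture = gen_speckle_image(
        shape_px, texture_density_per_um2, pixel_size,
        seed=int(rng.integers(2**31)),
    )
    dx, dy = _direction_field(schedule, shape_px, pixel_size, rng)

    frames = [np.asarray(texture.image, dtype=np.float32)]
    cum_x = np.zeros(shape_px)
    cum_y = np.zeros(shape_px)
    for s in speeds:
        step_um = s * dt_h
        cum_x += step_um * dx
        cum_y += step_um * dy
        u = VectorField2D(cum_x, cum_y, pixel_size, "um")
        frames.append(np.asarray(warp_image(texture, u).image, dtype=np.float32))

    spec = AcquisitionSpec(pixel_size, frame_interval_min, n_frames)
    return ImageStack(np.stack(frames), spec), speeds
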