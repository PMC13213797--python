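"""Shared physical-field data model, grid conventions, units, and file I/O.

Grid convention used throughout the package: arrays are indexed ``[row, col]``
(0-based); the physical coordinate of node ``(i, j)`` is
``origin + (j * grid_spacing, i * grid_spacing)``, i.e. x increases with the
column index and y with the row index.  All fields carry an explicit units
tag which every derived operation propagates or rejects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "UnitsError",
    "AcquisitionSpec",
    "SubstrateSpec",
    "VectorField2D",
    "ScalarField2D",
    "DomainMask",
    "ImageFrame",
    "ImageStack",
    "read_stack",
    "write_field",
    "read_field",
]

#: Units tags understood by the pipeline.  Velocity fields are "um/h",
#: displacement fields "um", traction fields "Pa", line stress "nN/um".
KNOWN_UNITS = ("um/h", "um", "Pa", "nN/um", "dimensionless")


class UnitsError(ValueError):
    """Raised when incompatible or missing units tags are combined."""


def require_units(tag: str, expected: str) -> None:
    if tag != expected:
        raise UnitsError(f"expected units {expected!r}, got {tag!r}")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging geometry and cadence of a timelapse.

    Parameters
    ----------
    pixel_size : float
        Physical size of one pixel, in micrometres.
    frame_interval_min : float
        Time between consecutive frames, in minutes.
    n_frames : int
        Number of frames in the sequence.
    """

    pixel_size: float
    frame_interval_min: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def total_duration_h(self) -> float:
        """Elapsed time between the first and last frame, in hours."""
        return self.frame_interval_h * (self.n_frames - 1)


@dataclass(frozen=True)
class SubstrateSpec:
    """Linear-elastic gel substrate for traction microscopy.

    ``thickness_um=None`` (or ``inf``) selects the elastic half-space.
    A Poisson ratio of exactly 0.5 is rejected: the in-plane Fourier kernel
    degenerates there, and polyacrylamide is near- but not exactly
    incompressible (default 0.49).
    """

    youngs_modulus_pa: float = 4800.0
    poisson_ratio: float = 0.49
    thickness_um: float | None = 100.0

    def __post_init__(self) -> None:
        if self.youngs_modulus_pa <= 0:
            raise ValueError("youngs_modulus_pa must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must satisfy 0 <= nu < 0.5")
        if self.thickness_um is not None and not (
            self.thickness_um > 0 or math.isinf(self.thickness_um)
        ):
            raise ValueError("thickness_um must be > 0, inf, or None")

    @property
    def is_half_space(self) -> bool:
        return self.thickness_um is None or math.isinf(self.thickness_um)


@dataclass
class VectorField2D:
    """A 2D vector field sampled on a regular grid.

    ``vx``/``vy`` share one shape; node (i, j) sits at physical position
    ``origin + (j, i) * grid_spacing``.
    """

    vx: np.ndarray
    vy: np.ndarray
    grid_spacing: float
    units: str
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy must share one shape")
        if self.vx.ndim != 2:
            raise ValueError("components must be 2D")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.units not in KNOWN_UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    def magnitude(self) -> "ScalarField2D":
        return ScalarField2D(
            np.hypot(self.vx, self.vy), self.grid_spacing, self.units, self.origin
        )

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of every node, as 2D arrays."""
        ny, nx = self.shape
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        return (
            self.origin[0] + jj * self.grid_spacing,
            self.origin[1] + ii * self.grid_spacing,
        )

    def with_values(self, vx: np.ndarray, vy: np.ndarray, units: str | None = None):
        return replace(self, vx=vx, vy=vy, units=units or self.units)


@dataclass
class ScalarField2D:
    """A scalar lattice with physical grid spacing and a units tag."""

    values: np.ndarray
    grid_spacing: float
    units: str
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.units not in KNOWN_UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DomainMask:
    """Boolean lattice marking the analysis domain of a congruent field."""

    mask: np.ndarray
    grid_spacing: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one true node")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.grid_spacing**2

    def check_congruent(self, fld: VectorField2D | ScalarField2D) -> None:
        if self.shape != fld.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match field shape {fld.shape}"
            )


@dataclass
class ImageFrame:
    """A single 2D intensity image with its pixel size (micrometres)."""

    image: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D grayscale")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class ImageStack:
    """A timelapse: frames in acquisition order, all congruent."""

    frames: np.ndarray  # (n_frames, H, W)
    spec: AcquisitionSpec

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.frames.shape[0] != self.spec.n_frames:
            raise ValueError(
                f"stack has {self.frames.shape[0]} frames but spec says "
                f"{self.spec.n_frames}"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame(self, t: int) -> ImageFrame:
        return ImageFrame(self.frames[t], self.spec.pixel_size)


# ----------------------------------------------------------------------------
# File I/O
# ----------------------------------------------------------------------------

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32, np.float64)


def read_stack(path: str | Path, spec: AcquisitionSpec) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Intensities are passed through unchanged.  The number of pages must match
    ``spec.n_frames`` and all pages must share one shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise ValueError(f"{path} contains no image pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: pages have mixed shapes {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise ValueError(f"{path}: pages are not 2D grayscale")
    if pages[0].dtype not in [np.dtype(d) for d in _SUPPORTED_DTYPES]:
        raise ValueError(f"{path}: unsupported bit depth {pages[0].dtype}")
    if len(pages) != spec.n_frames:
        raise ValueError(
            f"{path} has {len(pages)} pages but spec.n_frames={spec.n_frames}"
        )
    return ImageStack(np.stack(pages), spec)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(Path(path), stack.frames)


def _meta_frame(fld: VectorField2D | ScalarField2D, kind: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "key": ["kind", "grid_spacing", "origin_x", "origin_y", "units"],
            "value": [kind, repr(fld.grid_spacing), repr(fld.origin[0]),
                      repr(fld.origin[1]), fld.units],
        }
    )


def write_field(fld: VectorField2D | ScalarField2D, stem: str | Path) -> None:
    """Write a field as 32-bit float TIFF component(s) plus a CSV sidecar.

    ``stem`` is a path without extension; a vector field produces
    ``<stem>_x.tif``, ``<stem>_y.tif``; a scalar field ``<stem>.tif``;
    both produce ``<stem>_meta.csv``.  Values survive the round trip
    bit-exactly (in 32-bit precision); metadata exactly.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(fld, VectorField2D):
        tifffile.imwrite(stem.with_name(stem.name + "_x.tif"),
                         fld.vx.astype(np.float32))
        tifffile.imwrite(stem.with_name(stem.name + "_y.tif"),
                         fld.vy.astype(np.float32))
        meta = _meta_frame(fld, "vector")
    else:
        tifffile.imwrite(stem.with_suffix(".tif"), fld.values.astype(np.float32))
        meta = _meta_frame(fld, "scalar")
    meta.to_csv(stem.with_name(stem.name + "_meta.csv"), index=False)


def read_field(stem: str | Path) -> VectorField2D | ScalarField2D:
    """Inverse of :func:`write_field`."""
    stem = Path(stem)
    meta = pd.read_csv(stem.with_name(stem.name + "_meta.csv"), dtype=str)
    kv = dict(zip(meta["key"], meta["value"]))
    spacing = float(kv["grid_spacing"])
    origin = (float(kv["origin_x"]), float(kv["origin_y"]))
    units = kv["units"]
    if kv["kind"] == "vector":
        vx = tifffile.imread(stem.with_name(stem.name + "_x.tif"))
        vy = tifffile.imread(stem.with_name(stem.name + "_y.tif"))
        return VectorField2D(vx, vy, spacing, units, origin)
    values = tifffile.imread(stem.with_suffix(".tif"))
    return ScalarField2D(values, spacing, units, origin)


def bilinear_sample(
    comp: np.ndarray, x: np.ndarray, y: np.ndarray, grid_spacing: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Sample a gridded component at physical positions by bilinear
    interpolation, clamping positions to the grid hull."""
    j = (np.asarray(x) - origin[0]) / grid_spacing
    i = (np.asarray(y) - origin[1]) / grid_spacing
    ny, nx = comp.shape
    j = np.clip(j, 0.0, nx - 1.0)
    i = np.clip(i, 0.0, ny - 1.0)
    j0 = np.clip(np.floor(j).astype(int), 0, nx - 2) if nx > 1 else np.zeros_like(j, int)
    i0 = np.clip(np.floor(i).astype(int), 0, ny - 2) if ny > 1 else np.zeros_like(i, int)
    fj = j - j0
    fi = i - i0
    j1 = np.minimum(j0 + 1, nx - 1)
    i1 = np.minimum(i0 + 1, ny - 1)
    return (
        comp[i0, j0] * (1 - fi) * (1 - fj)
        + comp[i0, j1] * (1 - fi) * fj
        + comp[i1, j0] * fi * (1 - fj)
        + comp[i1, j1] * fi * fj
    )
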