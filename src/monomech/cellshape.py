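"""Per-cell shape measurement from integer label masks.

The aspect ratio (AR) of each cell is the axis ratio of its
moment-equivalent ellipse: the square root of the eigenvalue ratio of the
pixel-coordinate covariance matrix, with the standard uniform-pixel
correction (+1/12 per diagonal entry) so that, e.g., an axis-aligned
W x H rectangle of pixels has AR exactly W/H.  This matches the
"fit ellipse" convention of the common ROI measurement tools and is
invariant under image rotation and uniform rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .stats import StatResult, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "CellShapeRecord",
    "measure_cells",
    "records_to_frame",
    "fov_shape_summary",
    "shape_speed_coupling",
]


@dataclass
class LabelMask:
    """Integer label image (0 = background, k > 0 = cell k) with pixel size."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D integer image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class CellShapeRecord:
    """Moment-ellipse geometry of one cell."""

    label: int
    area_um2: float
    centroid_x_um: float
    centroid_y_um: float
    major_um: float
    minor_um: float
    aspect_ratio: float
    border_touching: bool


def measure_cells(
    mask: LabelMask, min_area_px: int = 20
) -> tuple[list[CellShapeRecord], int]:
    """Measure every label of a mask; returns (records, n_skipped).

    Labels smaller than ``min_area_px`` or split into multiple connected
    components are skipped with a log entry.  ``border_touching`` is set
    for labels whose bounding box touches the image edge.
    """
    lab = mask.labels
    if lab.max() == 0:
        raise ValueError("mask contains no labels")
    px = mask.pixel_size
    H, W = lab.shape
    records: list[CellShapeRecord] = []
    skipped = 0
    for region in regionprops(lab):
        if region.area < min_area_px:
            logger.info("label %d skipped: area %d px < %d", region.label,
                        region.area, min_area_px)
            skipped += 1
            continue
        _, n_comp = ndi.label(region.image)
        if n_comp != 1:
            logger.info("label %d skipped: %d connected components",
                        region.label, n_comp)
            skipped += 1
            continue
        coords = region.coords  # (n, 2) as (row, col)
        x = coords[:, 1].astype(float)
        y = coords[:, 0].astype(float)
        cov = np.cov(np.stack([x, y]), bias=True) + np.eye(2) / 12.0
        lam = np.linalg.eigvalsh(cov)  # ascending
        lam = np.clip(lam, 1e-12, None)
        ar = float(np.sqrt(lam[1] / lam[0]))
        minr, minc, maxr, maxc = region.bbox
        border = minr == 0 or minc == 0 or maxr == H or maxc == W
        records.append(
            CellShapeRecord(
                label=int(region.label),
                area_um2=float(region.area) * px**2,
                centroid_x_um=float(x.mean()) * px,
                centroid_y_um=float(y.mean()) * px,
                major_um=4.0 * float(np.sqrt(lam[1])) * px,
                minor_um=4.0 * float(np.sqrt(lam[0])) * px,
                aspect_ratio=ar,
                border_touching=bool(border),
            )
        )
    return records, skipped


def records_to_frame(records: list[CellShapeRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def fov_shape_summary(
    records: list[CellShapeRecord],
    drop_border: bool = True,
    min_area_um2: float | None = None,
    max_area_percentile: float = 99.5,
) -> dict:
    """Unweighted mean aspect ratio over retained cells of one field of view.

    Default filters: drop border-touching cells and cells above the 99.5th
    area percentile (segmentation-artifact suppression).
    """
    cells = [r for r in records if not (drop_border and r.border_touching)]
    if min_area_um2 is not None:
        cells = [r for r in cells if r.area_um2 >= min_area_um2]
    if cells and max_area_percentile < 100:
        cap = np.percentile([r.area_um2 for r in cells], max_area_percentile)
        cells = [r for r in cells if r.area_um2 <= cap]
    if not cells:
        raise ValueError("all cells filtered out")
    ars = np.array([r.aspect_ratio for r in cells])
    return {"mean_ar": float(ars.mean()), "n_cells": int(ars.size)}


def shape_speed_coupling(
    ar_per_fov: np.ndarray, speed_per_fov: np.ndarray
) -> tuple[StatResult, pd.DataFrame]:
    """Spearman correlation between per-FOV mean aspect ratio and per-FOV
    mean speed; returns the test result and the scatter table."""
    ar = np.asarray(ar_per_fov, dtype=float)
    sp = np.asarray(speed_per_fov, dtype=float)
    if ar.shape != sp.shape:
        raise ValueError("AR and speed lists must be paired (same length)")
    res = spearman(ar, sp)
    table = pd.DataFrame({"mean_ar": ar, "mean_speed_um_per_h": sp})
    return res, table
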