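"""Collective-motion metrics: spatial autocorrelation with 50%-decay
correlation length, and coordinated-pack detection on velocity fields.

The correlation length L50 of a scalar field (here, monolayer tension) is
the distance at which its radially averaged, normalized spatial
autocorrelation first drops below 0.5, linearly interpolated between
distance bins.  Packs are connected components of the alignment graph:
grid nodes moving at or above a speed threshold, joined to 4-neighbours
whose velocity directions differ by at most ``angle_max`` degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .core import DomainMask, ScalarField2D, VectorField2D, require_units

__all__ = [
    "CorrelationCurve",
    "PackAnalysis",
    "radial_autocorrelation",
    "correlation_length",
    "detect_packs",
]

#: Pair-count cap for the pairwise autocorrelation estimator.
MAX_PAIRS = 2_000_000


@dataclass
class CorrelationCurve:
    """Radially averaged normalized spatial autocorrelation.

    ``r_um`` are bin centres (uniform width = grid spacing); ``c`` the
    normalized correlation (C(0) = 1 by construction); ``length_um`` the
    50%-decay correlation length, or None when the curve never reaches 0.5
    within the measured range ("not reached").
    """

    r_um: np.ndarray
    c: np.ndarray
    n_pairs: np.ndarray
    length_um: float | None


def radial_autocorrelation(
    f: ScalarField2D,
    omega: DomainMask | None = None,
    max_distance_um: float | None = None,
    max_pairs: int = MAX_PAIRS,
    seed: int = 0,
) -> CorrelationCurve:
    """Pairwise radial autocorrelation of a scalar field over a mask.

    The field is centred by its mask mean; the correlation at distance bin
    r is the mean product of fluctuations over node pairs whose separation
    falls in the bin, normalized by the mask variance.  All pairs are used
    when their number is at most ``max_pairs``; otherwise a fixed-seed
    random subsample.  Bin width equals the grid spacing.
    """
    vals = f.values
    if omega is None:
        m = np.isfinite(vals)
        if not m.any():
            raise ValueError("field has no finite values")
        omega = DomainMask(m, f.grid_spacing)
    omega.check_congruent(f)
    m = omega.mask & np.isfinite(vals)
    ii, jj = np.nonzero(m)
    n = ii.size
    if n < 3:
        raise ValueError("mask too small for a correlation curve")
    v = vals[ii, jj]
    var = v.var()
    if var == 0:
        raise ValueError("zero variance: correlation undefined for a constant field")
    dv = v - v.mean()

    h = f.grid_spacing
    x = jj * h
    y = ii * h
    if max_distance_um is None:
        max_distance_um = 0.5 * min(
            (np.ptp(x) if np.ptp(x) > 0 else h), (np.ptp(y) if np.ptp(y) > 0 else h)
        )
        max_distance_um = max(max_distance_um, 2 * h)

    n_total = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_total <= max_pairs:
        a, b = np.triu_indices(n, k=1)
    else:
        a = rng.integers(0, n, size=max_pairs)
        b = rng.integers(0, n, size=max_pairs)
        keep = a != b
        a, b = a[keep], b[keep]
    d = np.hypot(x[a] - x[b], y[a] - y[b])
    keep = d <= max_distance_um
    a, b, d = a[keep], b[keep], d[keep]

    nbins = int(np.floor(max_distance_um / h)) + 1
    idx = np.clip(np.round(d / h).astype(int), 0, nbins - 1)
    prod = dv[a] * dv[b]
    sums = np.bincount(idx, weights=prod, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)

    r_centres = np.arange(nbins) * h
    c = np.full(nbins, np.nan)
    nonzero = counts > 0
    c[nonzero] = sums[nonzero] / counts[nonzero] / var
    # bin 0: self-pairs, exactly 1 by definition
    c[0] = 1.0
    counts[0] = n

    good = ~np.isnan(c)
    r_centres, c, counts = r_centres[good], c[good], counts[good]
    if r_centres.size < 2:
        raise ValueError("mask too small: fewer than 2 distance bins")
    return CorrelationCurve(r_centres, c, counts, correlation_length(r_centres, c))


def correlation_length(r_um: np.ndarray, c: np.ndarray) -> float | None:
    """First downward crossing of C = 0.5, linearly interpolated between
    adjacent bin centres; None when the curve stays above 0.5."""
    r_um = np.asarray(r_um, dtype=float)
    c = np.asarray(c, dtype=float)
    below = np.nonzero(c < 0.5)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(r_um[0])
    c0, c1 = c[i - 1], c[i]
    frac = (c0 - 0.5) / (c0 - c1)
    return float(r_um[i - 1] + frac * (r_um[i] - r_um[i - 1]))


@dataclass
class PackAnalysis:
    """Coordinated packs of a velocity field.

    ``pack_labels`` is 0 outside packs, 1..n_packs inside; ``areas_um2``
    one entry per pack; ``mean_area_um2`` is the unweighted mean pack area
    (0, with ``empty=True``, when no node passes the speed threshold).
    """

    pack_labels: np.ndarray
    areas_um2: np.ndarray
    node_counts: np.ndarray
    mean_area_um2: float
    n_packs: int
    speed_min: float
    angle_max_deg: float
    empty: bool


def detect_packs(
    v: VectorField2D,
    speed_min: float = 1.8,
    angle_max_deg: float = 45.0,
) -> PackAnalysis:
    """Alignment-graph pack detection.

    Nodes with speed >= ``speed_min`` are vertices; 4-neighbouring vertices
    are joined when the angle between their velocity vectors is at most
    ``angle_max_deg``; packs are the connected components.  Pack area is
    node count times grid-cell area.
    """
    require_units(v.units, "um/h")
    speed = np.hypot(v.vx, v.vy)
    above = speed >= speed_min
    ny, nx = above.shape
    ids = -np.ones((ny, nx), dtype=int)
    ii, jj = np.nonzero(above)
    n = ii.size
    labels = np.zeros((ny, nx), dtype=int)
    if n == 0:
        return PackAnalysis(
            labels, np.array([]), np.array([], dtype=int), 0.0, 0,
            speed_min, angle_max_deg, True,
        )
    ids[ii, jj] = np.arange(n)
    cos_max = np.cos(np.deg2rad(angle_max_deg))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for di, dj in ((0, 1), (1, 0)):
        a_sl = (slice(0, ny - di), slice(0, nx - dj))
        b_sl = (slice(di, ny), slice(dj, nx))
        both = above[a_sl] & above[b_sl]
        dot = (v.vx[a_sl] * v.vx[b_sl] + v.vy[a_sl] * v.vy[b_sl])
        norm = speed[a_sl] * speed[b_sl]
        aligned = both & (dot >= cos_max * norm)
        ai = ids[a_sl][aligned]
        bi = ids[b_sl][aligned]
        rows.append(ai)
        cols.append(bi)
    if rows and sum(r.size for r in rows) > 0:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        adj = sp.coo_matrix((np.ones(r.size), (r, c)), shape=(n, n))
    else:
        adj = sp.coo_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)

    labels[ii, jj] = comp + 1
    node_counts = np.bincount(comp, minlength=n_comp)
    cell_area = v.grid_spacing**2
    areas = node_counts * cell_area
    return PackAnalysis(
        labels,
        areas.astype(float),
        node_counts,
        float(areas.mean()),
        int(n_comp),
        speed_min,
        angle_max_deg,
        False,
    )
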