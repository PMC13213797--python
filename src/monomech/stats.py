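"""Statistical layer: densitometry normalization, rank correlation, t tests,
and tidy per-figure report assembly.

Densitometry follows the blot-normalization convention: each band is divided
by its lane's GAPDH loading control, then expressed as a fold change over
the mean normalized value of the reference group (the non-asthma / unprimed
control group at the earliest differentiation day), so the reference group
has mean fold change 1 by construction.  No multiple-testing correction is
applied across days; that choice is recorded in report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "normalize_densitometry",
    "densitometry_fold_changes",
    "spearman",
    "ttest",
    "assemble_report",
]

#: Exact permutation p-values are used for rank correlations up to this n.
EXACT_SPEARMAN_N = 9


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n: int
    test: str
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.n < 3:
            raise ValueError("n >= 3 required for any reported p-value")


def normalize_densitometry(
    band: float | np.ndarray,
    gapdh: float | np.ndarray,
    reference_mean: float,
) -> float | np.ndarray:
    """Fold change = (band / gapdh) / reference_mean.

    ``reference_mean`` is the mean band/GAPDH ratio of the reference group.
    All inputs must be positive.
    """
    band = np.asarray(band, dtype=float)
    gapdh = np.asarray(gapdh, dtype=float)
    if np.any(band <= 0) or np.any(gapdh <= 0) or reference_mean <= 0:
        raise ValueError("band, gapdh and reference_mean must all be > 0")
    out = band / gapdh / reference_mean
    return float(out) if out.ndim == 0 else out


def densitometry_fold_changes(
    df: pd.DataFrame,
    reference_group: str,
    reference_day: int,
    group_col: str = "group",
    day_col: str = "day",
) -> pd.DataFrame:
    """Compute normalized ratios and fold changes for a densitometry table.

    Requires columns ``band`` and ``gapdh`` (positive intensities) plus the
    group/day keys; one protein per call.  Adds ``ratio``, ``fold_change``
    and ``reference_mean`` columns.
    """
    for col in ("band", "gapdh", group_col, day_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    out = df.copy()
    out["ratio"] = out["band"] / out["gapdh"]
    ref = out[(out[group_col] == reference_group) & (out[day_col] == reference_day)]
    if ref.empty:
        raise ValueError(
            f"no rows for reference group {reference_group!r} day {reference_day}"
        )
    ref_mean = float(ref["ratio"].mean())
    out["reference_mean"] = ref_mean
    out["fold_change"] = out["ratio"] / ref_mean
    return out


# ----------------------------------------------------------------------------
# Correlation and t tests
# ----------------------------------------------------------------------------

def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value: exact permutation distribution for n <= 9,
    otherwise the standard large-sample t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("n >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    rx = _rank(x)
    ry = _rank(y)
    r = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_SPEARMAN_N:
        perms = np.array(list(permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        r_perm = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = float(2 * sps.t.sf(abs(t), n - 2))
    return StatResult(r, p, n, "spearman")


def ttest(
    group_a,
    group_b,
    paired: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> StatResult:
    """Two-sided Student t test (two-sample or paired)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("n >= 3 required per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires matched lengths")
        if np.std(a - b) == 0:
            raise ValueError("zero variance of paired differences")
        t, p = sps.ttest_rel(a, b)
        n = a.size
        name = "paired t"
    else:
        t, p = sps.ttest_ind(a, b)
        n = a.size + b.size
        name = "two-sample t"
    return StatResult(float(t), float(p), n, name, labels)


# ----------------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------------

REPORT_KEYS = ["donor", "group", "day", "fov"]


def assemble_report(
    tables: dict[str, pd.DataFrame],
    required: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Join per-stage tables into one tidy frame keyed by
    (donor, group, day, fov).

    ``tables`` maps a stage name to its frame; each frame must carry the key
    columns (a subset of the canonical keys is allowed, e.g. well-level
    tables without ``fov``) and is joined on the keys it has.  Key
    collisions (duplicate key tuples within one table) and missing required
    columns raise with the offending name.
    """
    merged: pd.DataFrame | None = None
    for name, df in tables.items():
        keys = [k for k in REPORT_KEYS if k in df.columns]
        if not keys:
            raise ValueError(f"table {name!r} carries none of the keys {REPORT_KEYS}")
        if required and name in required:
            for col in required[name]:
                if col not in df.columns:
                    raise ValueError(f"table {name!r} is missing column {col!r}")
        if df.duplicated(subset=keys).any():
            raise ValueError(f"table {name!r} has key collisions on {keys}")
        merged = df if merged is None else merged.merge(df, on=keys, how="outer")
    if merged is None:
        raise ValueError("no tables given")
    sort_keys = [k for k in REPORT_KEYS if k in merged.columns]
    return merged.sort_values(sort_keys).reset_index(drop=True)
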