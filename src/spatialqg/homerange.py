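"""Kernel home ranges: utilization distributions, sizes, and overlap.

Location fixes recorded to the nearest 100 m are jittered (uniform on
[-20, 20] m by default) to break ties, then turned into utilization
distributions (UDs) by bivariate product-normal kernel density estimation
on a regular grid.  Home-range size is the area of the smallest set of
cells holding a stated fraction (isopleth) of the UD mass.  Pairwise
overlap is Bhattacharyya's affinity

    BA = sum_cells sqrt(m1 * m2),

which is 1 for identical UDs and 0 for disjoint ones — the same 0..1 scale
as pedigree relatedness, which is what makes the overlap matrix ("S
matrix") usable as a random-effect covariance alongside the A matrix.

Cell masses are computed by exact integration of the Gaussian kernel over
each cell (per-axis normal CDF differences), not by midpoint evaluation,
so discretization error is limited to grid truncation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import ndtr

from .matrices import MatrixError, OverlapMatrix

logger = logging.getLogger(__name__)

SEASONS = ("spring", "rut")
BIRTH_WEIGHT_KG_PER_HOUR = 0.01539  # neonate growth correction, kg/h


class HomeRangeError(ValueError):
    """Raised for invalid home-range computations."""


class TooFewFixesError(HomeRangeError):
    """Raised when a fix group is below the minimum for UD estimation."""


@dataclass
class UtilizationDistribution:
    """Per-cell mass of an individual's space use on a regular grid.

    ``x0``/``y0`` are the west/south edges of the grid; ``density`` holds
    cell masses (row index increases northward) and sums to 1.
    """

    x0: float
    y0: float
    cell: float
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 2 or self.density.size == 0:
            raise HomeRangeError("UD density must be a non-empty 2-D grid")
        if (self.density < 0).any():
            raise HomeRangeError("UD masses must be non-negative")
        total = float(self.density.sum())
        if abs(total - 1.0) > 1e-9:
            raise HomeRangeError(f"UD masses sum to {total}, expected 1")

    @property
    def nrows(self) -> int:
        return self.density.shape[0]

    @property
    def ncols(self) -> int:
        return self.density.shape[1]

    def x_edges(self) -> np.ndarray:
        return self.x0 + self.cell * np.arange(self.ncols + 1)

    def y_edges(self) -> np.ndarray:
        return self.y0 + self.cell * np.arange(self.nrows + 1)


def jitter_fixes(
    fixes: pd.DataFrame, amplitude: float = 20.0, seed: int = 0
) -> pd.DataFrame:
    """Add independent uniform noise on [-amplitude, amplitude] to x and y.

    Census fixes are recorded to the nearest 100 m, so many coincide
    exactly; jittering breaks these ties before kernel estimation.  The
    input frame is not modified.
    """
    if amplitude <= 0:
        raise HomeRangeError("jitter amplitude must be positive")
    rng = np.random.default_rng(seed)
    out = fixes.copy()
    out["x"] = out["x"].to_numpy(float) + rng.uniform(
        -amplitude, amplitude, len(out)
    )
    out["y"] = out["y"].to_numpy(float) + rng.uniform(
        -amplitude, amplitude, len(out)
    )
    return out


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Reference ("href") bandwidth: sigma_pooled * n^(-1/6).

    sigma_pooled = sqrt((var(x) + var(y)) / 2), the default rule of kernel
    home-range software for bivariate normal kernels.
    """
    n = len(x)
    sig = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    return float(sig * n ** (-1.0 / 6.0))


def _axis_masses(coords: np.ndarray, edges: np.ndarray, h: float) -> np.ndarray:
    """(n_fix, n_cells) matrix of per-axis Gaussian cell integrals."""
    z = (edges[None, :] - coords[:, None]) / h
    cdf = ndtr(z)
    return np.diff(cdf, axis=1)


def estimate_ud(
    x: Sequence[float],
    y: Sequence[float],
    bandwidth: str | float = "reference",
    cell: float = 10.0,
    extent_pad: float | None = None,
    min_fixes: int = 10,
    snap_origin: bool = True,
) -> UtilizationDistribution:
    """Kernel utilization distribution from one individual's fixes.

    The grid covers the fixes plus ``extent_pad`` (default 3 bandwidths)
    on every side; with ``snap_origin`` the origin is snapped to a
    multiple of ``cell`` so that UDs of different individuals share a
    common lattice and overlap reduces to aligned cell sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise HomeRangeError("x and y must have equal length")
    if len(x) < min_fixes:
        raise TooFewFixesError(
            f"{len(x)} fixes < minimum of {min_fixes}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise HomeRangeError("non-finite coordinates in fixes")
    if np.var(x) == 0 and np.var(y) == 0:
        raise HomeRangeError(
            "fixes have zero spatial variance; jitter the coordinates first"
        )
    if bandwidth == "reference":
        h = reference_bandwidth(x, y)
    else:
        h = float(bandwidth)
    if h <= 0:
        raise HomeRangeError("bandwidth must be positive")
    pad = 3.0 * h if extent_pad is None else float(extent_pad)

    x_lo, x_hi = x.min() - pad, x.max() + pad
    y_lo, y_hi = y.min() - pad, y.max() + pad
    if snap_origin:
        x0 = np.floor(x_lo / cell) * cell
        y0 = np.floor(y_lo / cell) * cell
    else:
        x0, y0 = x_lo, y_lo
    ncols = int(np.ceil((x_hi - x0) / cell))
    nrows = int(np.ceil((y_hi - y0) / cell))

    kx = _axis_masses(x, x0 + cell * np.arange(ncols + 1), h)
    ky = _axis_masses(y, y0 + cell * np.arange(nrows + 1), h)
    dens = ky.T @ kx / len(x)
    dens[dens < dens.max() * 1e-12] = 0.0  # drop numerically empty cells
    dens /= dens.sum()
    return UtilizationDistribution(x0=float(x0), y0=float(y0), cell=cell, density=dens)


def estimate_uds(
    fixes: pd.DataFrame,
    by: Sequence[str] = ("individual",),
    min_fixes: int = 10,
    **kwargs,
) -> tuple[dict, pd.DataFrame]:
    """Estimate one UD per group of ``fixes``.

    Returns (uds, exclusions): groups with fewer than ``min_fixes`` fixes
    or degenerate geometry are skipped, each with a logged exclusion
    record rather than silently dropped.
    """
    uds: dict = {}
    excluded = []
    for key, grp in fixes.groupby(list(by), sort=True):
        key = key[0] if len(by) == 1 else key
        try:
            uds[key] = estimate_ud(
                grp["x"].to_numpy(), grp["y"].to_numpy(),
                min_fixes=min_fixes, **kwargs,
            )
        except TooFewFixesError:
            excluded.append(
                {"group": key, "n_fixes": len(grp), "reason": "too_few_fixes"}
            )
            logger.info("excluded %s: %d fixes < %d", key, len(grp), min_fixes)
    exclusions = pd.DataFrame(excluded, columns=["group", "n_fixes", "reason"])
    return uds, exclusions


def gaussian_ud(
    center: tuple[float, float],
    sigma: float,
    cell: float = 10.0,
    extent_pad: float | None = None,
    snap_origin: bool = True,
) -> UtilizationDistribution:
    """Exact circular-Gaussian UD on a grid (closed-form cell masses).

    Useful as an analytic reference distribution: range size and overlap
    of Gaussian UDs have closed forms against which the grid estimators
    can be checked, and synthetic truth can be expressed this way.
    """
    if sigma <= 0:
        raise HomeRangeError("sigma must be positive")
    pad = 5.0 * sigma if extent_pad is None else float(extent_pad)
    cx, cy = center
    if snap_origin:
        x0 = np.floor((cx - pad) / cell) * cell
        y0 = np.floor((cy - pad) / cell) * cell
    else:
        x0, y0 = cx - pad, cy - pad
    ncols = int(np.ceil((cx + pad - x0) / cell))
    nrows = int(np.ceil((cy + pad - y0) / cell))
    px = np.diff(ndtr((x0 + cell * np.arange(ncols + 1) - cx) / sigma))
    py = np.diff(ndtr((y0 + cell * np.arange(nrows + 1) - cy) / sigma))
    dens = np.outer(py, px)
    dens /= dens.sum()
    return UtilizationDistribution(x0=float(x0), y0=float(y0), cell=cell, density=dens)


def range_size(ud: UtilizationDistribution, isopleth: float = 0.95) -> float:
    """Home-range area in hectares at a given isopleth.

    Cells are accumulated in descending density order (stable ties) until
    their cumulative mass first reaches ``isopleth``; the area is the cell
    count times cell^2, converted to hectares.
    """
    if not (0.0 < isopleth <= 1.0):
        raise HomeRangeError("isopleth must be in (0, 1]")
    flat = ud.density.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, isopleth - 1e-12) + 1)
    k = min(k, flat.size)
    return k * ud.cell ** 2 / 1e4


def _resample_weights(
    src_edges: np.ndarray, dst_edges: np.ndarray
) -> np.ndarray:
    """1-D mass-reassignment matrix: fraction of each source cell's mass
    falling in each destination cell (area-weighted overlap)."""
    lo = np.maximum(src_edges[:-1, None], dst_edges[None, :-1])
    hi = np.minimum(src_edges[1:, None], dst_edges[None, 1:])
    w = np.clip(hi - lo, 0.0, None)
    width = np.diff(src_edges)[:, None]
    return w / width


def resample_ud(
    ud: UtilizationDistribution,
    x0: float,
    y0: float,
    cell: float,
    ncols: int,
    nrows: int,
) -> np.ndarray:
    """Conservatively reassign UD mass onto an arbitrary target grid."""
    wx = _resample_weights(ud.x_edges(), x0 + cell * np.arange(ncols + 1))
    wy = _resample_weights(ud.y_edges(), y0 + cell * np.arange(nrows + 1))
    return wy.T @ ud.density @ wx


def _aligned(ud1: UtilizationDistribution, ud2: UtilizationDistribution) -> bool:
    if ud1.cell != ud2.cell:
        return False
    c = ud1.cell
    return (
        abs((ud1.x0 - ud2.x0) / c - round((ud1.x0 - ud2.x0) / c)) < 1e-9
        and abs((ud1.y0 - ud2.y0) / c - round((ud1.y0 - ud2.y0) / c)) < 1e-9
    )


def ba_overlap(
    ud1: UtilizationDistribution, ud2: UtilizationDistribution
) -> float:
    """Bhattacharyya's affinity between two UDs on a common grid.

    UDs on congruent lattices are compared cell-by-cell over the window
    where both grids exist; otherwise both are conservatively resampled
    to the union bounding box at the finer cell size.  Non-overlapping
    extents yield 0.
    """
    if _aligned(ud1, ud2):
        c = ud1.cell
        dx = round((ud2.x0 - ud1.x0) / c)
        dy = round((ud2.y0 - ud1.y0) / c)
        c1_lo, c1_hi = max(0, dx), min(ud1.ncols, dx + ud2.ncols)
        r1_lo, r1_hi = max(0, dy), min(ud1.nrows, dy + ud2.nrows)
        if c1_lo >= c1_hi or r1_lo >= r1_hi:
            return 0.0
        a = ud1.density[r1_lo:r1_hi, c1_lo:c1_hi]
        b = ud2.density[r1_lo - dy : r1_hi - dy, c1_lo - dx : c1_hi - dx]
        return float(np.minimum(np.sqrt(a * b).sum(), 1.0))
    cell = min(ud1.cell, ud2.cell)
    x0 = min(ud1.x0, ud2.x0)
    y0 = min(ud1.y0, ud2.y0)
    x1 = max(ud1.x0 + ud1.cell * ud1.ncols, ud2.x0 + ud2.cell * ud2.ncols)
    y1 = max(ud1.y0 + ud1.cell * ud1.nrows, ud2.y0 + ud2.cell * ud2.nrows)
    ncols = int(np.ceil((x1 - x0) / cell))
    nrows = int(np.ceil((y1 - y0) / cell))
    a = resample_ud(ud1, x0, y0, cell, ncols, nrows)
    b = resample_ud(ud2, x0, y0, cell, ncols, nrows)
    return float(np.minimum(np.sqrt(a * b).sum(), 1.0))


def build_s_matrix(
    uds: Mapping[str, UtilizationDistribution],
    all_ids: Sequence[str],
    psd: str = "none",
    eps: float = 1e-8,
) -> OverlapMatrix:
    """Pairwise-BA overlap matrix over ``all_ids``.

    Individuals without a UD keep an overlap of 1 with themselves and 0
    with everyone else, so the matrix always spans the full pedigree.
    When every UD lives on one congruent lattice the whole matrix is a
    Gram product of square-root mass vectors; otherwise pairs are
    resampled individually.  ``psd="clip"`` raises eigenvalues below
    ``eps`` and restores the unit diagonal, recording the largest entry
    change (a Gram-form S is already positive semidefinite; the clip
    guards the singular case of identical UDs).
    """
    all_ids = [str(i) for i in all_ids]
    if len(set(all_ids)) != len(all_ids):
        raise MatrixError("duplicate ids in S-matrix request")
    missing = set(map(str, uds)) - set(all_ids)
    if missing:
        raise MatrixError(f"UD ids not in requested id list: {sorted(missing)[:5]}")
    if psd not in ("none", "clip"):
        raise MatrixError(f"unknown psd policy {psd!r}")

    n = len(all_ids)
    S = np.eye(n)
    with_ud = [i for i in all_ids if i in uds]
    k = len(with_ud)
    if k:
        idx = [all_ids.index(i) for i in with_ud]
        ud_list = [uds[i] for i in with_ud]
        ref = ud_list[0]
        if all(_aligned(ref, u) for u in ud_list[1:]):
            # shared lattice: S = R R' with R the sqrt-mass matrix on a
            # global cell index
            cell = ref.cell
            row_parts, key_parts, val_parts = [], [], []
            for r, u in enumerate(ud_list):
                ci0 = round(u.x0 / cell)
                ri0 = round(u.y0 / cell)
                rr, cc = np.nonzero(u.density)
                # encode (row, col) global cell coords as one int64 key
                key_parts.append(
                    (ri0 + rr.astype(np.int64)) << 32 | (ci0 + cc + 2**31)
                )
                row_parts.append(np.full(len(rr), r, dtype=np.int64))
                val_parts.append(np.sqrt(u.density[rr, cc]))
            keys = np.concatenate(key_parts)
            _, cols_i = np.unique(keys, return_inverse=True)
            R = sparse.csr_matrix(
                (
                    np.concatenate(val_parts),
                    (np.concatenate(row_parts), cols_i),
                ),
                shape=(k, int(cols_i.max()) + 1 if len(cols_i) else 0),
            )
            B = np.asarray((R @ R.T).todense())
            np.clip(B, 0.0, 1.0, out=B)
        else:
            B = np.eye(k)
            for a in range(k):
                for b in range(a):
                    B[a, b] = B[b, a] = ba_overlap(ud_list[a], ud_list[b])
        np.fill_diagonal(B, 1.0)
        S[np.ix_(idx, idx)] = B

    adjusted = False
    magnitude = 0.0
    if psd == "clip":
        w, Q = np.linalg.eigh(S)
        if w.min() < eps:
            w_clipped = np.maximum(w, eps)
            S_new = (Q * w_clipped) @ Q.T
            d = np.sqrt(np.diag(S_new))
            S_new = S_new / np.outer(d, d)
            S_new = (S_new + S_new.T) / 2.0
            np.fill_diagonal(S_new, 1.0)
            magnitude = float(np.abs(S_new - S).max())
            S = S_new
            adjusted = True
    return OverlapMatrix(
        ids=all_ids,
        values=S,
        kind="S",
        psd_adjusted=adjusted,
        adjustment_magnitude=magnitude,
    )


def write_ascii_grid(
    ud: UtilizationDistribution, path, nodata: float = -9999.0
) -> None:
    """Export a UD as an ESRI ASCII grid (cell masses, row 1 = north)."""
    from pathlib import Path

    lines = [
        f"ncols {ud.ncols}",
        f"nrows {ud.nrows}",
        f"xllcorner {ud.x0:.6f}",
        f"yllcorner {ud.y0:.6f}",
        f"cellsize {ud.cell:.6f}",
        f"NODATA_value {nodata:g}",
    ]
    for row in ud.density[::-1]:  # ASCII grids run north to south
        lines.append(" ".join(f"{v:.14g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path) -> UtilizationDistribution:
    """Read a UD written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        rows = [
            [float(v) for v in line.split()] for line in fh if line.strip()
        ]
    dens = np.asarray(rows)[::-1]
    dens = dens / dens.sum()
    return UtilizationDistribution(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        density=dens,
    )


def birth_weight_adjust(capture_weight: float, age_at_capture: float) -> float:
    """Estimated birth weight (kg) from capture weight and age in hours.

    birth weight = capture weight - 0.01539 * age at capture (hours).
    """
    if age_at_capture < 0:
        raise HomeRangeError("age at capture must be non-negative")
    return capture_weight - BIRTH_WEIGHT_KG_PER_HOUR * age_at_capture


def local_population_size(
    mean_locations: Mapping[str, tuple[float, float]],
    regions: Mapping[str, object],
    year: int | None = None,
) -> tuple[dict[str, int], dict[str, str]]:
    """Count individuals whose mean location falls in each region.

    ``regions`` maps labels to shapely geometries partitioning the study
    area.  Boundary points go to the lexicographically lowest matching
    label; locations outside every region are assigned to ``"outside"``
    with a warning.  Returns (counts per region, region label per id) —
    the labels double as a fixed-effect covariate.
    """
    from shapely.geometry import Point

    labels: dict[str, str] = {}
    counts = {label: 0 for label in regions}
    ordered = sorted(regions)
    outside = []
    for ident in sorted(mean_locations, key=str):
        pt = Point(*mean_locations[ident])
        for label in ordered:
            if regions[label].covers(pt):
                labels[str(ident)] = label
                counts[label] += 1
                break
        else:
            labels[str(ident)] = "outside"
            outside.append(str(ident))
    if outside:
        counts.setdefault("outside", 0)
        counts["outside"] += len(outside)
        warnings.warn(
            f"{len(outside)} individuals outside all regions "
            f"(e.g. {outside[0]!r}); assigned to 'outside'",
            stacklevel=2,
        )
    return counts, labels
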