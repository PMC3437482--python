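"""The 100-m study lattice and separable AR1xAR1 spatial covariance.

Average lifetime locations are snapped to a grid whose origin is the most
south-westerly reference point, one step = 100 m.  Spatial autocorrelation
(SAC) is modelled as a first-order separable autoregressive process on
this lattice: the correlation between cells (r1, c1) and (r2, c2) is

    phi_row^|r1-r2| * phi_col^|c1-c2|,

i.e. the Kronecker product of two AR1 correlation matrices, restricted to
the cells that are actually occupied.  Fitting a column-only (or row-only)
process is the same structure with the other phi fixed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz


class LatticeError(ValueError):
    """Raised for invalid lattice constructions."""


@dataclass
class SACParameters:
    """Parameters of a separable AR1xAR1 spatial process."""

    phi_col: float = 0.0
    phi_row: float = 0.0
    variance: float = 1.0


@dataclass
class LatticeIndex:
    """Grid placement of individuals on the 100-m lattice.

    Each id maps to one occupied cell; ``occupied_cells`` lists distinct
    (row, col) pairs in row-major order and ``cell_index`` gives, for each
    id, its position in that list.
    """

    ids: list[str]
    row: np.ndarray
    col: np.ndarray
    occupied_cells: list[tuple[int, int]]
    cell_index: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.occupied_cells)

    def cell_of(self, ident: str) -> tuple[int, int]:
        k = self.ids.index(str(ident))
        return int(self.row[k]), int(self.col[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.ids,
                "row": self.row,
                "col": self.col,
                "cell_index": self.cell_index,
            }
        )


def grid_coordinates(
    mean_locations: Mapping[str, tuple[float, float]],
    origin: tuple[float, float],
    spacing: float = 100.0,
) -> LatticeIndex:
    """Snap mean locations to the study lattice.

    col = floor((x - x0)/spacing), row = floor((y - y0)/spacing); the
    origin cell is (0, 0).  Locations south or west of the origin are an
    error naming the offending individual.
    """
    x0, y0 = origin
    ids = [str(i) for i in sorted(mean_locations, key=str)]
    xs = np.array([mean_locations[i][0] for i in ids], dtype=float)
    ys = np.array([mean_locations[i][1] for i in ids], dtype=float)
    bad = np.flatnonzero((xs < x0) | (ys < y0))
    if len(bad):
        raise LatticeError(
            f"location of {ids[bad[0]]!r} lies south/west of the grid origin"
        )
    col = np.floor((xs - x0) / spacing).astype(int)
    row = np.floor((ys - y0) / spacing).astype(int)
    occupied = sorted(set(zip(row.tolist(), col.tolist())))
    pos = {cell: k for k, cell in enumerate(occupied)}
    cell_index = np.array([pos[(r, c)] for r, c in zip(row, col)], dtype=int)
    return LatticeIndex(
        ids=ids, row=row, col=col, occupied_cells=occupied, cell_index=cell_index
    )


def ar1_correlation(n: int, phi: float) -> np.ndarray:
    """AR1 correlation matrix: R[i, j] = phi^|i-j| (symmetric Toeplitz)."""
    if n < 1:
        raise LatticeError("n must be >= 1")
    if not abs(phi) < 1:
        raise LatticeError("|phi| must be < 1")
    return toeplitz(phi ** np.arange(n, dtype=float))


def ar1xar1_covariance(
    idx: "LatticeIndex | Sequence[tuple[int, int]]", pars: SACParameters
) -> np.ndarray:
    """Separable covariance over occupied cells.

    Cov[(r1,c1),(r2,c2)] = variance * phi_row^|r1-r2| * phi_col^|c1-c2| —
    the occupied-cell principal submatrix of the full Kronecker product,
    hence positive definite whenever both |phi| < 1.
    """
    for phi in (pars.phi_row, pars.phi_col):
        if not abs(phi) < 1:
            raise LatticeError("|phi| must be < 1")
    cells = idx.occupied_cells if isinstance(idx, LatticeIndex) else list(idx)
    r = np.array([c[0] for c in cells], dtype=int)
    c = np.array([c[1] for c in cells], dtype=int)
    # integer exponents keep phi^d exact for phi <= 0 (0^0 = 1 covers the
    # single-axis case where the other phi is held at 0)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    G = np.power(pars.phi_row, dr) * np.power(pars.phi_col, dc)
    return pars.variance * G


@dataclass
class AR1xAR1Kernel:
    """Parametric covariance factory for a SAC random term.

    ``axes`` selects which autoregressive parameters are estimated:
    ("col",) for a column-only process, ("row",) for row-only, or
    ("row", "col") for the full separable model (the omitted phi is held
    at 0).  ``phi_bounds`` is the optimizer search interval.
    """

    cells: list[tuple[int, int]]
    axes: tuple[str, ...] = ("row", "col")
    phi_bounds: tuple[float, float] = (0.0, 0.999)

    def __post_init__(self) -> None:
        for a in self.axes:
            if a not in ("row", "col"):
                raise LatticeError(f"unknown axis {a!r}")

    @property
    def n_phi(self) -> int:
        return len(self.axes)

    @property
    def phi_names(self) -> list[str]:
        return [f"phi_{a}" for a in self.axes]

    def correlation(self, phis: Sequence[float]) -> np.ndarray:
        """Unit-variance AR1xAR1 correlation over the occupied cells."""
        pars = SACParameters(variance=1.0)
        for name, value in zip(self.axes, phis):
            setattr(pars, f"phi_{name}", float(value))
        return ar1xar1_covariance(self.cells, pars)
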