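"""Symmetric similarity matrices over ordered individual ids.

Two matrix kinds circulate in the package: the additive genetic
relationship matrix ("A", diagonal >= 1) and the home-range overlap
matrix ("S", Bhattacharyya affinities, diagonal exactly 1).  Both are
stored dense with an explicit ordered id list, and both are exchanged on
disk as lower-triangle triplet text (1-based row/col index, value) with
an ordered-id sidecar file — the de-facto dialect of mixed-model software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class MatrixError(ValueError):
    """Raised for malformed or inconsistent matrix requests."""


@dataclass
class RelationshipMatrix:
    """Symmetric pairwise similarity over an ordered id list.

    ``kind`` tags the provenance: "A" (pedigree additive relatedness,
    diagonal 1 + inbreeding), "S" (overlap, diagonal 1) or "identity".
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "A"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if n and not np.allclose(self.values, self.values.T, atol=1e-10):
            raise MatrixError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {v: k for k, v in enumerate(self.ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise MatrixError(f"id {exc.args[0]!r} not in matrix") from exc


@dataclass
class OverlapMatrix(RelationshipMatrix):
    """Bhattacharyya-affinity overlap matrix (the "S matrix").

    Entries lie in [0, 1] before any positive-definiteness adjustment;
    the diagonal is exactly 1.  ``psd_adjusted`` records whether a
    clip-to-epsilon eigenvalue repair was applied and
    ``adjustment_magnitude`` the largest resulting entry change.
    """

    kind: str = "S"
    psd_adjusted: bool = False
    adjustment_magnitude: float = 0.0


def align_matrix(
    M: RelationshipMatrix,
    ids: Sequence[str],
    missing_policy: str = "identity_row",
) -> RelationshipMatrix:
    """Reorder/subset ``M`` onto ``ids``.

    Individuals absent from ``M`` receive a diagonal of 1 and
    off-diagonals of 0 (the convention for individuals with no overlap or
    relatedness information).
    """
    if missing_policy != "identity_row":
        raise MatrixError(f"unknown missing_policy {missing_policy!r}")
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise MatrixError("duplicate ids in alignment request")
    pos = {v: k for k, v in enumerate(M.ids)}
    out = np.eye(len(ids))
    present = [k for k, i in enumerate(ids) if i in pos]
    src = [pos[ids[k]] for k in present]
    if present:
        out[np.ix_(present, present)] = M.values[np.ix_(src, src)]
    if isinstance(M, OverlapMatrix):
        return OverlapMatrix(
            ids=ids,
            values=out,
            kind=M.kind,
            psd_adjusted=M.psd_adjusted,
            adjustment_magnitude=M.adjustment_magnitude,
        )
    return RelationshipMatrix(ids=ids, values=out, kind=M.kind)


def write_lower_triplets(
    M: RelationshipMatrix, path: str | Path, ids_path: str | Path | None = None
) -> None:
    """Write the lower triangle as ``row col value`` triplets (1-based).

    Zero entries are omitted; the ordered id list goes to ``ids_path``
    (default: ``<path>.ids``).
    """
    path = Path(path)
    ids_path = Path(ids_path) if ids_path is not None else path.with_suffix(
        path.suffix + ".ids"
    )
    with open(path, "w") as fh:
        for i in range(M.n):
            for j in range(i + 1):
                v = M.values[i, j]
                if v != 0.0:
                    fh.write(f"{i + 1} {j + 1} {v:.12g}\n")
    with open(ids_path, "w") as fh:
        for ident in M.ids:
            fh.write(f"{ident}\n")


def read_lower_triplets(
    path: str | Path, ids_path: str | Path | None = None, kind: str = "A"
) -> RelationshipMatrix:
    """Read a triplet file written by :func:`write_lower_triplets`."""
    path = Path(path)
    ids_path = Path(ids_path) if ids_path is not None else path.with_suffix(
        path.suffix + ".ids"
    )
    ids = [line.strip() for line in open(ids_path) if line.strip()]
    n = len(ids)
    vals = np.zeros((n, n))
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            i, j, v = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
            if not (0 <= j <= i < n):
                raise MatrixError(f"triplet index ({i + 1},{j + 1}) out of range")
            vals[i, j] = v
            vals[j, i] = v
    cls = OverlapMatrix if kind == "S" else RelationshipMatrix
    return cls(ids=ids, values=vals, kind=kind)
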