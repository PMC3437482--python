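"""Pedigree reading, validation and the additive relationship (A) matrix.

A pedigree is a table of (individual, dam, sire) triples; unknown parents
are encoded by configurable sentinels.  The A matrix is built with the
tabular (recursive) method: processing individuals so that parents precede
offspring,

    a_ii = 1 + 0.5 * a(dam_i, sire_i)        (1 when a parent is unknown)
    a_ij = 0.5 * (a(j, dam_i) + a(j, sire_i))  for j processed before i,

with unknown parents contributing 0.  The diagonal is therefore
1 + inbreeding coefficient, and the matrix is positive definite for any
acyclic pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrices import RelationshipMatrix, align_matrix  # noqa: F401  (re-export)

DEFAULT_UNKNOWN = ("", "0", "NA", "NaN", "nan", "*")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class PedigreeTable:
    """A validated pedigree in canonical (parents-first) order.

    ``frame`` has columns ``individual``, ``dam``, ``sire`` (parent entries
    are ``None`` for founders) and optionally ``sex`` and ``cohort``.  Rows
    are sorted by (generation depth, id), so the ordering is independent of
    the input row order.
    """

    frame: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.frame["individual"])

    @property
    def n(self) -> int:
        return len(self.frame)

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {
            r.individual: (r.dam, r.sire)
            for r in self.frame.itertuples(index=False)
        }

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        unknown: Iterable[str] = DEFAULT_UNKNOWN,
        founder_policy: str = "implicit",
    ) -> "PedigreeTable":
        """Validate and canonically sort a raw pedigree frame.

        ``founder_policy="implicit"`` appends founder rows for parents that
        never appear as individuals; ``"error"`` rejects such pedigrees.
        """
        if founder_policy not in ("implicit", "error"):
            raise PedigreeError(f"unknown founder_policy {founder_policy!r}")
        unknown = {str(u) for u in unknown}

        def clean(v: object) -> str | None:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            s = str(v).strip()
            return None if s in unknown else s

        cols = {c.lower(): c for c in frame.columns}
        for required in ("individual", "dam", "sire"):
            if required not in cols:
                raise PedigreeError(f"missing column {required!r}")
        rows = []
        for _, r in frame.iterrows():
            rec = {
                "individual": clean(r[cols["individual"]]),
                "dam": clean(r[cols["dam"]]),
                "sire": clean(r[cols["sire"]]),
            }
            if rec["individual"] is None:
                raise PedigreeError("blank individual id")
            for opt in ("sex", "cohort"):
                if opt in cols:
                    rec[opt] = r[cols[opt]]
            rows.append(rec)

        ids = [r["individual"] for r in rows]
        dup = pd.Series(ids).duplicated()
        if dup.any():
            raise PedigreeError(
                f"duplicate individual id {ids[int(np.flatnonzero(dup)[0])]!r}"
            )
        known = set(ids)
        implicit = []
        for r in rows:
            for p in (r["dam"], r["sire"]):
                if p is not None and p not in known:
                    if founder_policy == "error":
                        raise PedigreeError(
                            f"parent {p!r} never appears as an individual"
                        )
                    known.add(p)
                    implicit.append(
                        {"individual": p, "dam": None, "sire": None}
                    )
        rows = implicit + rows

        # generation depth by memoized recursion; cycles surface as
        # revisits of an in-progress node.
        parent_of = {
            r["individual"]: (r["dam"], r["sire"]) for r in rows
        }
        depth: dict[str, int] = {}
        IN_PROGRESS = -1

        def depth_of(ident: str) -> int:
            got = depth.get(ident)
            if got == IN_PROGRESS:
                raise PedigreeError(
                    f"pedigree cycle detected involving {ident!r}"
                )
            if got is not None:
                return got
            depth[ident] = IN_PROGRESS
            dam, sire = parent_of[ident]
            d = 0
            for p in (dam, sire):
                if p is not None:
                    d = max(d, depth_of(p) + 1)
            depth[ident] = d
            return d

        for r in rows:
            depth_of(r["individual"])
        rows.sort(key=lambda r: (depth[r["individual"]], r["individual"]))
        out = pd.DataFrame(rows)
        return cls(frame=out.reset_index(drop=True))


def read_pedigree(
    path: str | Path,
    founder_policy: str = "implicit",
    unknown: Iterable[str] = DEFAULT_UNKNOWN,
) -> PedigreeTable:
    """Read a pedigree CSV (columns individual, dam, sire[, sex, cohort])."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return PedigreeTable.from_frame(
        frame, unknown=unknown, founder_policy=founder_policy
    )


def additive_relationship(ped: PedigreeTable) -> RelationshipMatrix:
    """Additive genetic relationship matrix by the tabular method."""
    ids = ped.ids
    pos = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    dam_idx = np.full(n, -1, dtype=int)
    sire_idx = np.full(n, -1, dtype=int)
    for k, r in enumerate(ped.frame.itertuples(index=False)):
        if r.dam is not None:
            dam_idx[k] = pos[r.dam]
        if r.sire is not None:
            sire_idx[k] = pos[r.sire]
        if dam_idx[k] >= k or sire_idx[k] >= k:
            raise PedigreeError("pedigree not in parents-first order")

    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam_idx[i], sire_idx[i]
        if i:
            row = np.zeros(i)
            if d >= 0:
                row += A[:i, d]
            if s >= 0:
                row += A[:i, s]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)
    return RelationshipMatrix(ids=ids, values=A, kind="A")
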