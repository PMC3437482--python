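"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: relatedness is
estimated by Monte-Carlo gene dropping (allele transmission simulated
down the pedigree), not by the tabular recursion they are used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from spatialqg.pedigree import PedigreeTable


def assert_matches_gene_drop(
    A: np.ndarray, A_hat: np.ndarray, se: np.ndarray
) -> None:
    """Assert tabular A is consistent with the gene-dropping estimate.

    Elements whose allele-drop outcome is deterministic (se = 0) must
    match exactly.  For the stochastic elements the standardized errors
    z = (A_hat - A)/se are approximately standard normal, so we require
    |z| <= 5 everywhere and the count beyond 3 se within its binomial
    chance range (nominal rate 0.27%; allowance max(5, 1% of n)).  A
    systematic error of even a fraction of one se trips both checks.
    """
    iu = np.triu_indices(A.shape[0])
    A, A_hat, se = A[iu], A_hat[iu], se[iu]
    det = se == 0.0
    assert np.array_equal(A[det], A_hat[det])
    z = (A_hat[~det] - A[~det]) / se[~det]
    assert np.abs(z).max() <= 5.0
    assert (np.abs(z) > 3.0).sum() <= max(5, 0.01 * z.size)


def random_pedigree(
    seed: int, n: int = 30, n_founders: int = 8, unknown_parent_p: float = 0.1
) -> PedigreeTable:
    """Random multi-generation pedigree with occasional unknown parents."""
    rng = np.random.default_rng(seed)
    rows = [
        {"individual": f"P{k:03d}", "dam": None, "sire": None}
        for k in range(n_founders)
    ]
    for k in range(n_founders, n):
        ident = f"P{k:03d}"
        pool = [r["individual"] for r in rows]
        dam = sire = None
        if rng.random() > unknown_parent_p:
            dam = pool[rng.integers(len(pool))]
        if rng.random() > unknown_parent_p:
            sire = pool[rng.integers(len(pool))]
            if sire == dam:
                sire = None
        rows.append({"individual": ident, "dam": dam, "sire": sire})
    return PedigreeTable.from_frame(pd.DataFrame(rows))


def gene_drop_relatedness(
    ped: PedigreeTable, n_drops: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo additive relatedness (2x kinship) and its standard error.

    Each replicate drops two distinguishable founder alleles down the
    pedigree; the kinship of (i, j) is the probability that one random
    allele from each is identical by descent, averaged over the four
    allele pairs.  Unknown parents contribute unique founder alleles.
    Returns (A_hat, se) with A_hat[i, i] = 1 + F_hat.
    """
    ids = ped.ids
    n = len(ids)
    pos = {v: k for k, v in enumerate(ids)}
    parents = ped.parents()
    dam = np.array([pos.get(parents[i][0], -1) for i in ids])
    sire = np.array([pos.get(parents[i][1], -1) for i in ids])

    rng = np.random.default_rng(seed)
    R = n_drops
    a1 = np.empty((R, n), dtype=np.int32)
    a2 = np.empty((R, n), dtype=np.int32)
    for k in range(n):
        if dam[k] >= 0:
            pick = rng.random(R) < 0.5
            a1[:, k] = np.where(pick, a1[:, dam[k]], a2[:, dam[k]])
        else:
            a1[:, k] = 2 * k
        if sire[k] >= 0:
            pick = rng.random(R) < 0.5
            a2[:, k] = np.where(pick, a1[:, sire[k]], a2[:, sire[k]])
        else:
            a2[:, k] = 2 * k + 1

    A_hat = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        # relatedness = 2 * mean over replicates of the 4-pair IBD fraction
        m = (
            (a1[:, i : i + 1] == a1[:, i:]).astype(np.int8)
            + (a1[:, i : i + 1] == a2[:, i:])
            + (a2[:, i : i + 1] == a1[:, i:])
            + (a2[:, i : i + 1] == a2[:, i:])
        ) / 4.0
        vals = 2.0 * m.mean(axis=0)
        errs = 2.0 * m.std(axis=0) / np.sqrt(R)
        A_hat[i, i:] = vals
        A_hat[i:, i] = vals
        se[i, i:] = errs
        se[i:, i] = errs
        # diagonal: a_ii = 1 + F, F = P(the two own alleles are IBD)
        f = (a1[:, i] == a2[:, i]).astype(float)
        A_hat[i, i] = 1.0 + f.mean()
        se[i, i] = f.std() / np.sqrt(R)
    return A_hat, se
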