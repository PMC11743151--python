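"""Per-(miRNA, cell/spot) activity p-values.

An active miRNA represses its targets, so in a cell where it is active the
targets concentrate at the low end of the z-score-ranked gene list.  For
every requested miRNA and every cell, the genes are ranked by ascending
z-score (ties broken by gene identifier), the ranking is converted into a
binary membership list over the miRNA's filtered target set, and the exact
mHG test is applied.  The resulting p-value matrix (miRNA x cell) is the
method's central output; a miRNA with no targets present in the matrix
receives the constant row 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .mhg import MHGTester
from .mti import TargetIndex
from .preprocess import ZScoreMatrix

__all__ = [
    "ActivityMatrix",
    "rank_genes_for_sample",
    "target_membership_vector",
    "compute_activity_matrix",
]


@dataclass
class ActivityMatrix:
    """miRNA x cell/spot activity p-values in (0, 1]."""

    pvalues: pd.DataFrame
    population: pd.Series | None = None
    coords: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mirna_ids(self):
        return list(self.pvalues.index)

    @property
    def sample_ids(self):
        return list(self.pvalues.columns)


def _rank_order(z: ZScoreMatrix) -> np.ndarray:
    """Column-wise rank orders: entry [i, s] is the row index of the gene at
    ascending-z rank i in sample s, ties broken by gene identifier."""
    genes = np.asarray(z.z.index, dtype=object)
    id_order = np.argsort(genes, kind="stable")
    # lexsort: primary key z (last), secondary the gene-id rank
    id_rank = np.empty(genes.size, dtype=np.int64)
    id_rank[id_order] = np.arange(genes.size)
    zv = z.z.to_numpy()
    orders = np.empty(zv.shape, dtype=np.int64)
    for s in range(zv.shape[1]):
        orders[:, s] = np.lexsort((id_rank, zv[:, s]))
    return orders


def rank_genes_for_sample(z: ZScoreMatrix, sample) -> list:
    """Genes of one sample sorted by ascending z-score (most down-regulated
    first); ties broken by ascending gene identifier."""
    if sample not in z.z.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = z.z[sample]
    genes = np.asarray(col.index, dtype=object)
    id_order = np.argsort(genes, kind="stable")
    id_rank = np.empty(genes.size, dtype=np.int64)
    id_rank[id_order] = np.arange(genes.size)
    order = np.lexsort((id_rank, col.to_numpy()))
    return list(genes[order])


def target_membership_vector(ranked, targets) -> np.ndarray:
    """Binary list over a ranked gene sequence: 1 where the gene is a target
    (uppercase symbol match)."""
    tset = {str(t).upper() for t in targets}
    return np.fromiter(
        (1 if str(g).upper() in tset else 0 for g in ranked),
        dtype=np.int64,
        count=len(ranked),
    )


def _mirna_row(mask: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Activity p-values of one miRNA (target mask over gene rows) for all
    samples, sharing one DP engine per (N, K)."""
    N = orders.shape[0]
    K = int(mask.sum())
    S = orders.shape[1]
    if K == 0:
        return np.ones(S)
    tester = MHGTester(N, K)
    out = np.empty(S)
    for s in range(S):
        out[s] = tester.test(mask[orders[:, s]]).pvalue
    return out


def compute_activity_matrix(
    z: ZScoreMatrix,
    index: TargetIndex,
    mirnas=None,
    n_jobs: int = -1,
) -> ActivityMatrix:
    """Exact mHG activity p-value for every (miRNA, sample) pair.

    ``mirnas`` restricts the test to a subset of the index (default: all).
    Work is parallelized across miRNAs with a deterministic merge, so the
    result is independent of the worker count, and of the gene/sample
    ordering of the input.
    """
    if z.z.empty:
        raise ValueError("empty z-score matrix")
    if mirnas is None:
        mirnas = index.mirnas
    else:
        unknown = [m for m in mirnas if m not in index.map]
        if unknown:
            raise KeyError(f"miRNAs absent from the target index: {unknown}")
    genes_upper = np.asarray([str(g).upper() for g in z.z.index], dtype=object)
    orders = _rank_order(z)
    masks = []
    for mir in mirnas:
        tset = {t.upper() for t in index.map[mir]}
        masks.append(np.isin(genes_upper, list(tset)))
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_mirna_row)(mask, orders) for mask in masks
    )
    pv = pd.DataFrame(np.vstack(rows), index=list(mirnas), columns=z.z.columns)
    return ActivityMatrix(
        pvalues=pv,
        population=z.population,
        coords=z.coords,
        meta={"species": index.species, "n_genes": int(z.z.shape[0])},
    )
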