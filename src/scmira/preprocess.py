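"""Count-matrix containers and the normalization / z-score pipeline.

The activity test consumes a per-gene standardized matrix: raw counts are
cleaned, optionally filtered and subsampled, scaled to a common total per
cell/spot (10,000 by default), and each gene is transformed to z-scores

    z(g, s) = (c(g, s) - a(g)) / sigma(g)

with the mean a(g) and the *population* standard deviation sigma(g)
(denominator 1/S) taken across all S cells/spots.  The pipeline order is
fixed: clean -> (optional low-count filter) -> sample -> normalize ->
z-score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ZScoreMatrix",
    "clean_matrix",
    "filter_low_count_cells",
    "sample_cells",
    "normalize_total",
    "zscore_by_gene",
    "preprocess_pipeline",
]

#: Default library-size target and cell sample size.
DEFAULT_TOTAL = 10_000
DEFAULT_SAMPLE_SIZE = 10_000
DEFAULT_SEED = 0


@dataclass
class CountMatrix:
    """Gene x sample count matrix with optional coordinates and labels.

    counts     -- DataFrame, genes in rows (index = symbols), samples in
                  columns (barcodes); nonnegative
    coords     -- optional DataFrame indexed by sample with columns x, y
    population -- optional Series mapping sample -> population label
    """

    counts: pd.DataFrame
    coords: pd.DataFrame | None = None
    population: pd.Series | None = None

    @property
    def gene_ids(self):
        return list(self.counts.index)

    @property
    def sample_ids(self):
        return list(self.counts.columns)

    @property
    def S(self) -> int:
        return self.counts.shape[1]

    def _subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[:, samples],
            coords=None if self.coords is None else self.coords.loc[
                self.coords.index.intersection(samples)
            ],
            population=None if self.population is None else self.population.loc[samples],
        )


@dataclass
class ZScoreMatrix:
    """Per-gene standardized expression.

    z     -- genes x samples; each retained gene has mean 0 and population
             variance 1 across samples
    mean  -- a(g) per gene (on the normalized-count scale)
    std   -- sigma(g) per gene, population denominator, strictly positive
    """

    z: pd.DataFrame
    mean: pd.Series
    std: pd.Series
    population: pd.Series | None = None
    coords: pd.DataFrame | None = None

    @property
    def gene_ids(self):
        return list(self.z.index)

    @property
    def sample_ids(self):
        return list(self.z.columns)


def clean_matrix(raw: CountMatrix) -> CountMatrix:
    """Collapse duplicate gene symbols, drop all-zero genes, drop cells with
    bit-identical expression profiles (first occurrence kept)."""
    df = raw.counts
    if (df.values < 0).any():
        raise ValueError("counts must be nonnegative")
    # duplicate symbols: keep the row with the larger total count
    if df.index.has_duplicates:
        totals = df.sum(axis=1)
        order = np.argsort(-totals.values, kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.loc[[g for g in raw.counts.index.drop_duplicates() if g in df.index]]
    # all-zero genes
    df = df.loc[df.sum(axis=1) > 0]
    # identical cells: keep the first in input order
    dup = df.T.duplicated(keep="first")
    if dup.any():
        logger.info("dropping %d duplicate expression profiles", int(dup.sum()))
        df = df.loc[:, ~dup.values]
    if df.empty:
        raise ValueError("matrix is empty after cleaning")
    out = CountMatrix(counts=df, coords=raw.coords, population=raw.population)
    return out._subset_samples(list(df.columns))


def filter_low_count_cells(m: CountMatrix, min_reads: int = 1000) -> CountMatrix:
    """Drop cells/spots with total counts below ``min_reads`` (strict <).

    Cells with very few reads can disproportionately distort the per-gene
    z-scores, so removing them before standardization is recommended.
    """
    totals = m.counts.sum(axis=0)
    keep = totals >= min_reads
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_low_count_cells: dropped %d cells below %d reads",
                    n_dropped, min_reads)
    if not keep.any():
        raise ValueError(f"all cells have fewer than {min_reads} reads")
    return m._subset_samples(list(m.counts.columns[keep]))


def sample_cells(
    m: CountMatrix,
    n: int = DEFAULT_SAMPLE_SIZE,
    seed: int = DEFAULT_SEED,
    stratify: bool = False,
) -> CountMatrix:
    """Uniform sample of ``n`` cells without replacement (identity when the
    matrix is already at most that large).

    With ``stratify`` and population labels present, an equal-size sample
    (n // n_populations) is drawn from each population, so comparative runs
    keep balanced groups.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if m.S <= n:
        return m
    rng = np.random.default_rng(seed)
    cols = np.asarray(m.counts.columns)
    if stratify and m.population is not None:
        pops = m.population.loc[cols]
        groups = list(dict.fromkeys(pops))
        per_group = n // len(groups)
        chosen = []
        for g in groups:
            gcols = cols[(pops == g).values]
            take = min(per_group, gcols.size)
            idx = np.sort(rng.choice(gcols.size, size=take, replace=False))
            chosen.extend(gcols[idx])
    else:
        idx = np.sort(rng.choice(cols.size, size=n, replace=False))
        chosen = list(cols[idx])
    return m._subset_samples(list(chosen))


def normalize_total(m: CountMatrix, total: float = DEFAULT_TOTAL) -> CountMatrix:
    """Scale every cell/spot column so its counts sum to ``total``."""
    sums = m.counts.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero-total samples present (clean first): {bad[:5]}")
    scaled = m.counts * (total / sums)
    return CountMatrix(counts=scaled, coords=m.coords, population=m.population)


def zscore_by_gene(m: CountMatrix) -> ZScoreMatrix:
    """Standardize each gene across samples with population (1/S) moments.

    Genes with zero variance carry no ranking information and are dropped
    with a warning (the transform is undefined for them).
    """
    if m.S < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = m.counts.to_numpy(dtype=np.float64)
    a = vals.mean(axis=1)
    sigma = vals.std(axis=1)  # ddof=0: population denominator
    keep = sigma > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant gene(s) with sigma=0",
            stacklevel=2,
        )
    z = (vals[keep] - a[keep, None]) / sigma[keep, None]
    genes = m.counts.index[keep]
    return ZScoreMatrix(
        z=pd.DataFrame(z, index=genes, columns=m.counts.columns),
        mean=pd.Series(a[keep], index=genes),
        std=pd.Series(sigma[keep], index=genes),
        population=m.population,
        coords=m.coords,
    )


def preprocess_pipeline(
    raw: CountMatrix,
    min_reads: int | None = None,
    sample_size: int | None = DEFAULT_SAMPLE_SIZE,
    seed: int = DEFAULT_SEED,
    stratify: bool = False,
    total: float = DEFAULT_TOTAL,
) -> ZScoreMatrix:
    """Fixed-order pipeline: clean -> low-count filter (opt-in) -> sample ->
    normalize -> z-score."""
    m = clean_matrix(raw)
    if min_reads is not None:
        m = filter_low_count_cells(m, min_reads=min_reads)
    if sample_size is not None:
        m = sample_cells(m, n=sample_size, seed=seed, stratify=stratify)
    m = normalize_total(m, total=total)
    return zscore_by_gene(m)
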