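"""Synthetic data with planted miRNA activity.

Every pipeline stage is testable without external downloads: this module
generates miRTarBase-layout interaction tables, negative-binomial count
matrices (single-cell or spatial grids) and the matching ground truth.

The count model draws per-gene baseline means from a log-normal (so the
matrix spans the usual orders of magnitude of expression) and counts from a
negative binomial with fixed dispersion, giving realistic overdispersion.
Activity is planted *on the count means*, not on z-scores: in designated
cells, each planted miRNA's target genes have their mean multiplied by
exp(-delta * sigma_g / mu_g), which after library-size normalization and
per-gene standardization produces a downward z-shift of roughly ``delta``.
Planting on means ensures the whole pipeline, normalization included, is
exercised by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

__all__ = [
    "SyntheticTruth",
    "generate_mti_fixture",
    "generate_single_cell_dataset",
    "generate_spatial_dataset",
    "downsample_counts",
]

# Baseline expression model defaults: log-normal gene means centred near 5
# counts with ~1 dex spread, negative-binomial dispersion theta=10 (variance
# mu + mu^2/theta) -- typical droplet-like overdispersion.
DEFAULT_MEAN_LOG_MU = np.log(5.0)
DEFAULT_MEAN_LOG_SIGMA = 1.0
DEFAULT_DISPERSION = 10.0


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset.

    planted_mirnas -- miRNAs with planted activity (must exist in the MTI
                      fixture used downstream)
    planted_cells  -- miRNA -> list of cell/spot ids where it is active
    delta          -- target z-shift magnitude (z-score scale), >= 0
    """

    planted_mirnas: list = field(default_factory=list)
    planted_cells: dict = field(default_factory=dict)
    delta: float = 2.0
    mean_log_mu: float = DEFAULT_MEAN_LOG_MU
    mean_log_sigma: float = DEFAULT_MEAN_LOG_SIGMA
    dispersion: float = DEFAULT_DISPERSION
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def generate_mti_fixture(
    n_mirnas: int,
    targets_per_mirna: int,
    n_genes: int,
    seed: int = 0,
    species: str = "homo_sapiens",
    disjoint: bool = False,
) -> pd.DataFrame:
    """miRTarBase-layout table of synthetic interactions.

    Target sets are drawn without replacement from a universe of
    ``n_genes`` symbols; every row is functional with one strong evidence,
    so the whole table survives the evidence filter.  With ``disjoint``,
    the sets are additionally disjoint across miRNAs -- required when a
    test needs non-planted miRNAs to be genuinely null (a miRNA sharing
    targets with a planted one inherits real planted activity).
    """
    if targets_per_mirna > n_genes:
        raise ValueError("targets_per_mirna cannot exceed n_genes")
    if disjoint and n_mirnas * targets_per_mirna > n_genes:
        raise ValueError("disjoint target sets exceed the gene universe")
    rng = np.random.default_rng(seed)
    prefix = {"homo_sapiens": "hsa", "mus_musculus": "mmu"}[species]
    genes = gene_universe(n_genes)
    rows = []
    if disjoint:
        pool = rng.choice(
            n_genes, size=n_mirnas * targets_per_mirna, replace=False
        )
    for i in range(n_mirnas):
        mir = f"{prefix}-miR-synth{i + 1}-5p"
        if disjoint:
            targets = pool[i * targets_per_mirna : (i + 1) * targets_per_mirna]
        else:
            targets = rng.choice(n_genes, size=targets_per_mirna, replace=False)
        for t in sorted(targets):
            rows.append((mir, genes[t], "Functional MTI"))
    return pd.DataFrame(rows, columns=["miRNA", "Target Gene", "Support Type"])


def gene_universe(n_genes: int) -> list:
    return [f"GENE{i + 1:05d}" for i in range(n_genes)]


def _nb_counts(rng, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; supports per-entry means."""
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def _planted_mean_matrix(
    truth: SyntheticTruth,
    mu: np.ndarray,
    genes: list,
    cells: list,
    mti: pd.DataFrame,
) -> np.ndarray:
    """Per-(gene, cell) mean matrix with the multiplicative down-shift
    applied to planted targets in planted cells."""
    theta = truth.dispersion
    sigma = np.sqrt(mu + mu**2 / theta)
    factor = np.exp(-truth.delta * sigma / mu)
    gene_pos = {g: i for i, g in enumerate(genes)}
    cell_pos = {c: j for j, c in enumerate(cells)}
    M = np.tile(mu[:, None], (1, len(cells)))
    for mir in truth.planted_mirnas:
        targets = mti.loc[mti["miRNA"] == mir, "Target Gene"]
        gi = np.array([gene_pos[g] for g in targets if g in gene_pos], dtype=np.int64)
        cj = np.array(
            [cell_pos[c] for c in truth.planted_cells.get(mir, []) if c in cell_pos],
            dtype=np.int64,
        )
        if gi.size and cj.size:
            M[np.ix_(gi, cj)] *= factor[gi, None]
    return M


def generate_single_cell_dataset(
    truth: SyntheticTruth,
    mti: pd.DataFrame,
    n_genes: int,
    n_cells: int,
    populations: tuple | None = None,
    universal: bool = False,
    universal_fraction: float = 0.25,
) -> CountMatrix:
    """Negative-binomial count matrix with planted activity.

    ``populations`` optionally names two groups ``(a, b)``; the first half
    of the cells is labelled ``a`` and the second ``b``, and the labels are
    embedded in the cell identifiers (as real comparative inputs carry
    them).  With ``universal``, each planted cell down-shifts a random
    minority subset of the targets (``universal_fraction`` of them, a
    different subset per cell) -- activity that every cell shows without
    any globally down-regulated gene.  The subset must be a minority: a
    gene shifted in most cells drags its own mean and variance along and
    the signal cancels under per-gene standardization.
    """
    rng = np.random.default_rng(truth.seed)
    genes = gene_universe(n_genes)
    if populations is not None:
        if len(populations) != 2:
            raise ValueError("populations must name exactly two groups")
        half = n_cells // 2
        labels = [populations[0]] * half + [populations[1]] * (n_cells - half)
        cells = [f"CELL{j + 1:05d}_{lab}" for j, lab in enumerate(labels)]
        population = pd.Series(labels, index=cells)
    else:
        cells = [f"CELL{j + 1:05d}" for j in range(n_cells)]
        population = None
    mu = rng.lognormal(truth.mean_log_mu, truth.mean_log_sigma, size=n_genes)
    if universal:
        M = np.tile(mu[:, None], (1, n_cells))
        theta = truth.dispersion
        factor = np.exp(-truth.delta * np.sqrt(mu + mu**2 / theta) / mu)
        gene_pos = {g: i for i, g in enumerate(genes)}
        cell_pos = {c: j for j, c in enumerate(cells)}
        for mir in truth.planted_mirnas:
            targets = [
                gene_pos[g]
                for g in mti.loc[mti["miRNA"] == mir, "Target Gene"]
                if g in gene_pos
            ]
            n_sub = max(1, int(round(universal_fraction * len(targets))))
            for c in truth.planted_cells.get(mir, []):
                sub = rng.choice(targets, size=n_sub, replace=False)
                M[sub, cell_pos[c]] *= factor[sub]
    else:
        M = _planted_mean_matrix(truth, mu, genes, cells, mti)
    counts = _nb_counts(rng, M, truth.dispersion)
    df = pd.DataFrame(counts, index=genes, columns=cells)
    return CountMatrix(counts=df, population=population)


def generate_spatial_dataset(
    truth: SyntheticTruth,
    mti: pd.DataFrame,
    n_genes: int,
    grid: tuple = (20, 20),
    active_region=None,
) -> CountMatrix:
    """Spatial grid of spots with activity planted in a coordinate region.

    ``active_region`` is a predicate (x, y) -> bool selecting the planted
    spots for every planted miRNA (overriding ``truth.planted_cells``);
    coordinates are the integer grid positions.
    """
    nx, ny = grid
    coords = [(x, y) for y in range(ny) for x in range(nx)]
    spots = [f"SPOT_{x}_{y}" for x, y in coords]
    coord_df = pd.DataFrame(coords, index=spots, columns=["x", "y"])
    if active_region is not None:
        planted = [s for s, (x, y) in zip(spots, coords) if active_region(x, y)]
        truth = SyntheticTruth(
            planted_mirnas=truth.planted_mirnas,
            planted_cells={m: planted for m in truth.planted_mirnas},
            delta=truth.delta,
            mean_log_mu=truth.mean_log_mu,
            mean_log_sigma=truth.mean_log_sigma,
            dispersion=truth.dispersion,
            seed=truth.seed,
        )
    rng = np.random.default_rng(truth.seed)
    genes = gene_universe(n_genes)
    mu = rng.lognormal(truth.mean_log_mu, truth.mean_log_sigma, size=n_genes)
    M = _planted_mean_matrix(truth, mu, genes, spots, mti)
    counts = _nb_counts(rng, M, truth.dispersion)
    df = pd.DataFrame(counts, index=genes, columns=spots)
    return CountMatrix(counts=df, coords=coord_df)


def downsample_counts(m: CountMatrix, fraction: float, seed: int = 0) -> CountMatrix:
    """Binomial thinning: each count replaced by Binomial(count, fraction)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return m
    rng = np.random.default_rng(seed)
    vals = m.counts.to_numpy().astype(np.int64)
    thinned = rng.binomial(vals, fraction)
    return CountMatrix(
        counts=pd.DataFrame(thinned, index=m.counts.index, columns=m.counts.columns),
        coords=m.coords,
        population=m.population,
    )
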