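"""Activity maps and comparative histograms.

Maps color each cell/spot by -log10 of its activity p-value, either on
spatial coordinates or on a 2-D embedding.  The embedding itself is
delegated to the standard scanpy/UMAP pipeline; only the preprocessing
contract is owned here: cells with <200 genes and genes seen in <3 cells
are excluded, cells below the bottom 2% / above the top 2% of total counts
are trimmed, counts are normalized to 10,000 and log(1+x)-transformed,
then highly-variable-gene selection, PCA, neighborhood graph and the 2-D
embedding follow.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .activity import ActivityMatrix
from .preprocess import CountMatrix

__all__ = ["embedding_preprocess", "activity_map", "comparative_histograms"]

DEFAULT_N_HVG = 2000
DEFAULT_N_PCS = 50


def embedding_preprocess(
    m: CountMatrix,
    n_hvg: int = DEFAULT_N_HVG,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
):
    """Standard single-cell reduction ending in 2-D embedding coordinates.

    Returns (AnnData with the reduced representation, coords DataFrame
    indexed by cell with columns x, y).  Embedding coordinates are treated
    as opaque; only the preprocessing steps are contractual.
    """
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=m.counts.T.to_numpy(dtype=np.float32),
        obs=pd.DataFrame(index=m.counts.columns),
        var=pd.DataFrame(index=m.counts.index),
    )
    sc.pp.filter_cells(adata, min_genes=200)
    sc.pp.filter_genes(adata, min_cells=3)
    if adata.n_obs < 10:
        raise ValueError("too few cells left after gene/cell filters")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    lo, hi = np.quantile(totals, [0.02, 0.98])
    adata = adata[(totals >= lo) & (totals <= hi)].copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    n_hvg = min(n_hvg, adata.n_vars - 1)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg)
    adata = adata[:, adata.var.highly_variable].copy()
    n_pcs = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(adata, random_state=seed)
    sc.tl.umap(adata, random_state=seed)
    coords = pd.DataFrame(
        adata.obsm["X_umap"], index=adata.obs_names, columns=["x", "y"]
    )
    return adata, coords


def _neglog10(a: ActivityMatrix, mirna) -> pd.Series:
    if mirna not in a.pvalues.index:
        raise KeyError(f"miRNA {mirna!r} not in the activity matrix")
    return -np.log10(a.pvalues.loc[mirna])


def activity_map(coords: pd.DataFrame, a: ActivityMatrix, mirna, path) -> None:
    """Scatter of samples at their (spatial or embedding) coordinates,
    colored by -log10 activity p-value."""
    vals = _neglog10(a, mirna)
    shared = coords.index.intersection(vals.index)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    sct = ax.scatter(
        coords.loc[shared, "x"],
        coords.loc[shared, "y"],
        c=vals.loc[shared],
        s=14,
        cmap="viridis",
    )
    fig.colorbar(sct, ax=ax, label="-log10(activity p-value)")
    ax.set_title(f"{mirna} activity")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def comparative_histograms(
    a: ActivityMatrix, labels, mirna, path, split: bool = True
) -> None:
    """Overlaid per-population histograms of -log10 activity p-values."""
    vals = _neglog10(a, mirna)
    labels = a.population if labels is None else pd.Series(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    if split and labels is not None:
        labels = labels.loc[vals.index]
        for pop in dict.fromkeys(labels):
            ax.hist(
                vals[(labels == pop).values], bins=30, alpha=0.55, label=str(pop)
            )
        ax.legend()
    else:
        ax.hist(vals, bins=30, alpha=0.8)
    ax.set_xlabel("-log10(activity p-value)")
    ax.set_ylabel("cells")
    ax.set_title(f"{mirna} activity distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
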