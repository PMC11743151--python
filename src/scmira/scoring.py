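"""Aggregation of activity p-values into ranked per-miRNA reports.

Three reporting modes:

spatial      -- score = fraction of spots with activity p < threshold
                (default 1e-5), ranked descending;
total        -- score = Benjamini-Hochberg-corrected mean activity p-value
                across cells, ranked ascending;
comparative  -- score = BH-corrected two-sided Wilcoxon rank-sum p-value
                comparing the activity p-values of two cell populations,
                with a tiering rule that promotes miRNAs showing both
                strong differential activity (score < 1e-8) and
                consistently high activity (mean -log10 p at or above the
                0.97 / 0.9 across-miRNA quantile in at least one
                population).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .activity import ActivityMatrix

__all__ = [
    "spatial_scores",
    "total_scores",
    "comparative_scores",
    "assign_comparative_tiers",
    "wilcoxon_rank_sum",
    "bonferroni_pairwise",
    "significance_bracket",
    "DEFAULT_SPATIAL_THRESHOLD",
]

DEFAULT_SPATIAL_THRESHOLD = 1e-5
TIER_SCORE_THRESHOLD = 1e-8
TIER_QUANTILES = {1: 0.97, 2: 0.9}


def _bh(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value, normal approximation with
    midranks and tie correction, no continuity correction.

    The degenerate all-tied case (zero rank variance) returns 1.0 rather
    than dividing by zero.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    n = n1 + n2
    ranks = rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    zstat = (r1 - mu) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(zstat)))


def _finalize(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    df = df.copy()
    df["rank"] = np.arange(1, len(df) + 1)
    df["mode"] = mode
    return df.reset_index(drop=True)


def spatial_scores(
    a: ActivityMatrix, threshold: float = DEFAULT_SPATIAL_THRESHOLD
) -> pd.DataFrame:
    """Fraction of spots with significant activity (strict p < threshold),
    per miRNA, sorted descending."""
    if a.pvalues.empty:
        raise ValueError("empty activity matrix")
    frac = (a.pvalues.to_numpy() < threshold).mean(axis=1)
    df = pd.DataFrame({"mirna": a.mirna_ids, "score": frac, "tier": "none"})
    df = df.sort_values(["score", "mirna"], ascending=[False, True], kind="stable")
    return _finalize(df, "spatial")


def total_scores(a: ActivityMatrix) -> pd.DataFrame:
    """BH-corrected mean activity p-value per miRNA, sorted ascending."""
    if a.pvalues.empty:
        raise ValueError("empty activity matrix")
    mean_p = a.pvalues.to_numpy().mean(axis=1)
    df = pd.DataFrame(
        {
            "mirna": a.mirna_ids,
            "mean_p": mean_p,
            "score": _bh(mean_p),
            "tier": "none",
        }
    )
    df = df.sort_values(["score", "mean_p", "mirna"], kind="stable")
    return _finalize(df, "total")


def _two_populations(a: ActivityMatrix, labels: pd.Series | None):
    labels = a.population if labels is None else labels
    if labels is None:
        raise ValueError("comparative mode requires population labels")
    labels = pd.Series(labels).loc[a.pvalues.columns]
    pops = list(dict.fromkeys(labels))
    if len(pops) != 2:
        raise ValueError(f"comparative mode requires exactly 2 populations, got {pops}")
    for p in pops:
        n = int((labels == p).sum())
        if n < 2:
            raise ValueError(f"population {p!r} has fewer than 2 cells")
        if n < 100:
            warnings.warn(
                f"population {p!r} has only {n} cells; comparisons are "
                "recommended for populations of at least 100 cells",
                stacklevel=3,
            )
    return labels, pops


def comparative_scores(a: ActivityMatrix, labels=None) -> pd.DataFrame:
    """Differential-activity score per miRNA between two cell populations.

    Two-sided Wilcoxon rank-sum on the activity p-values, BH-corrected
    across miRNAs; also records each population's mean -log10 activity
    p-value (the activity level used by the tiering rule).
    """
    if a.pvalues.empty:
        raise ValueError("empty activity matrix")
    labels, pops = _two_populations(a, labels)
    g1 = a.pvalues.loc[:, (labels == pops[0]).values].to_numpy()
    g2 = a.pvalues.loc[:, (labels == pops[1]).values].to_numpy()
    wrs = np.array([wilcoxon_rank_sum(g1[i], g2[i]) for i in range(g1.shape[0])])
    df = pd.DataFrame(
        {
            "mirna": a.mirna_ids,
            "wrs_p": wrs,
            "score": _bh(wrs),
            "tier": "none",
            f"mean_neglog10_{pops[0]}": -np.log10(g1).mean(axis=1),
            f"mean_neglog10_{pops[1]}": -np.log10(g2).mean(axis=1),
        }
    )
    df = df.sort_values(["score", "wrs_p", "mirna"], kind="stable")
    return _finalize(df, "comparative")


def assign_comparative_tiers(
    report: pd.DataFrame,
    a: ActivityMatrix,
    labels=None,
    scale: str = "neglog10",
) -> pd.DataFrame:
    """Tier the comparative report.

    Tier 1: activity level at or above the 0.97 across-miRNA quantile in at
    least one population AND score < 1e-8.  Tier 2: same with the 0.9
    quantile.  Tier 3: the rest, sorted by score.  The activity level is
    the per-population mean -log10 activity p-value by default
    (``scale="neglog10"``); ``scale="raw"`` applies the rule to the raw
    mean p-value instead (levels *at or below* the complementary quantile).
    """
    labels, pops = _two_populations(a, labels)
    level = {}
    for p in pops:
        block = a.pvalues.loc[:, (labels == p).values].to_numpy()
        if scale == "neglog10":
            level[p] = pd.Series(-np.log10(block).mean(axis=1), index=a.mirna_ids)
        elif scale == "raw":
            level[p] = pd.Series(-block.mean(axis=1), index=a.mirna_ids)
        else:
            raise ValueError("scale must be 'neglog10' or 'raw'")
    df = report.copy().set_index("mirna")
    tier = pd.Series("3", index=df.index)
    for t in (2, 1):  # tier 1 assigned last so it overrides tier 2
        q = TIER_QUANTILES[t]
        hits = pd.Series(False, index=df.index)
        for p in pops:
            cutoff = np.quantile(level[p].to_numpy(), q)  # linear interpolation
            hits |= level[p] >= cutoff
        hits &= df["score"] < TIER_SCORE_THRESHOLD
        tier[hits] = str(t)
    df["tier"] = tier
    df = df.reset_index()
    df = df.sort_values(["tier", "score", "wrs_p", "mirna"], kind="stable")
    return _finalize(df.drop(columns="rank"), "comparative")


def bonferroni_pairwise(pvals, n_comparisons: int):
    """Bonferroni adjustment: min(1, p * n_comparisons) elementwise."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    p = np.asarray(pvals, dtype=np.float64)
    out = np.minimum(1.0, p * n_comparisons)
    return float(out) if np.isscalar(pvals) or p.ndim == 0 else out


def significance_bracket(p: float) -> str:
    """Conventional star bracket: ns > 0.05 >= * > 0.01 >= ** > 1e-3 >=
    *** > 1e-4 >= ****."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 1e-3:
        return "**"
    if p > 1e-4:
        return "***"
    return "****"
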