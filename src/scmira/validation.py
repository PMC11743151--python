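"""Agreement between miRNA expression and inferred activity.

When an independent measurement of miRNA expression exists for the same
cells (e.g. total-RNA protocols that capture miRNAs) or samples, expressed
miRNAs should tend to be active and unexpressed ones inactive.  These
procedures quantify that agreement: miRNAs are classified active
(activity p < 0.05) / non-active (p > 0.1), strand-specific calls are
collapsed onto strandless identifiers to match expression catalogues,
miRNAs are ranked by expression, and the mHG test measures the enrichment
of active miRNAs at the top (or of non-active miRNAs at the bottom) of the
ranking.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .mhg import mhg_test
from .preprocess import CountMatrix
from .scoring import wilcoxon_rank_sum

__all__ = [
    "sum_precursor_expression",
    "classify_activity",
    "collapse_strands",
    "expression_activity_agreement",
    "compare_target_expression",
    "ACTIVE_THRESHOLD",
    "NON_ACTIVE_THRESHOLD",
]

ACTIVE_THRESHOLD = 0.05
NON_ACTIVE_THRESHOLD = 0.1

_PRECURSOR_RE = re.compile(r"^(?P<base>.+)-(?P<copy>\d+)$")
_STRAND_RE = re.compile(r"-(3p|5p)$")


def sum_precursor_expression(expr: pd.Series | pd.DataFrame):
    """Sum precursor rows ("name-1", "name-2", ...) into the mature name;
    drop rows left with zero expression everywhere."""
    is_frame = isinstance(expr, pd.DataFrame)
    df = expr if is_frame else expr.to_frame("expression")

    def base(mid: str) -> str:
        m = _PRECURSOR_RE.match(str(mid))
        return m.group("base") if m else str(mid)

    out = df.groupby(df.index.map(base), sort=False).sum()
    out = out.loc[out.sum(axis=1) > 0]
    return out if is_frame else out.iloc[:, 0]


def classify_activity(scores: pd.Series) -> pd.Series:
    """Label each miRNA: active (p < 0.05), non_active (p > 0.1), else
    neither.  ``scores`` are activity p-values (per sample, or aggregated
    means, depending on the study design)."""
    p = pd.Series(scores, dtype=np.float64)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("activity values must be in (0, 1]")
    labels = pd.Series("neither", index=p.index, dtype=object)
    labels[p < ACTIVE_THRESHOLD] = "active"
    labels[p > NON_ACTIVE_THRESHOLD] = "non_active"
    return labels


def collapse_strands(classification: pd.Series) -> pd.Series:
    """Map -3p/-5p strand-level calls onto strandless miRNA names.

    A strandless miRNA is active if at least one strand is active; it is
    non_active only if some strand is non_active and no strand is active
    (a non-active strand whose sibling is active is excluded from the
    non-active set); otherwise neither.
    """
    strandless = classification.index.map(lambda m: _STRAND_RE.sub("", str(m)))
    out = {}
    for base, group in classification.groupby(strandless):
        labels = set(group)
        if "active" in labels:
            out[base] = "active"
        elif "non_active" in labels:
            out[base] = "non_active"
        else:
            out[base] = "neither"
    return pd.Series(out, dtype=object)


def expression_activity_agreement(
    expr: pd.Series,
    classification: pd.Series,
    end: str = "top_active",
):
    """mHG enrichment of active (non-active) miRNAs among the most (least)
    expressed miRNAs.

    end="top_active":       sort by descending expression, 1 = active
    end="bottom_nonactive": sort by ascending expression, 1 = non_active
    Ties in expression are broken by identifier.  Returns the MHGResult
    (``.pvalue`` is the agreement p-value).
    """
    shared = expr.index.intersection(classification.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 miRNAs shared between expression and activity")
    e = expr.loc[shared]
    ascending = {"top_active": False, "bottom_nonactive": True}
    positive = {"top_active": "active", "bottom_nonactive": "non_active"}
    if end not in ascending:
        raise ValueError("end must be 'top_active' or 'bottom_nonactive'")
    order = sorted(shared, key=lambda m: ((1 if ascending[end] else -1) * e[m], str(m)))
    binary = [1 if classification[m] == positive[end] else 0 for m in order]
    return mhg_test(binary)


def compare_target_expression(
    m: CountMatrix,
    targets,
    labels: pd.Series | None = None,
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing, between two cell
    populations, the per-cell mean normalized expression of a miRNA's
    target set.  A direct expression-level counterpart of the comparative
    activity test."""
    labels = m.population if labels is None else pd.Series(labels)
    if labels is None:
        raise ValueError("population labels are required")
    labels = labels.loc[m.counts.columns]
    pops = list(dict.fromkeys(labels))
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    tset = {str(t).upper() for t in targets}
    present = [g for g in m.counts.index if str(g).upper() in tset]
    if not present:
        raise ValueError("none of the targets are present in the matrix")
    per_cell_mean = m.counts.loc[present].mean(axis=0)
    x = per_cell_mean[(labels == pops[0]).values]
    y = per_cell_mean[(labels == pops[1]).values]
    return wilcoxon_rank_sum(x, y)
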