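"""miRNA-target interaction (MTI) catalogue: loading, filtering, indexing.

Interactions come from a miRTarBase-like table (one row per supporting
reference) with at least the columns ``miRNA``, ``Target Gene`` and
``Support Type``.  Only functional interactions backed by strong evidence,
or by at least two independent weak evidences, are retained; evidence is
pooled across rows of the same (miRNA, target) pair before the rule is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mhg import hypergeometric_tail

__all__ = [
    "MTIRecord",
    "TargetIndex",
    "read_mti_table",
    "filter_mtis",
    "build_target_index",
    "target_jaccard",
    "set_overlap_pvalue",
]

SPECIES_PREFIX = {"homo_sapiens": "hsa-", "mus_musculus": "mmu-"}

#: Default mapping from miRTarBase "Support Type" strings to evidence
#: strength. Any label containing "(Weak)" counts as weak; any other
#: functional label counts as strong. Override via the ``strength_map``
#: arguments if a catalogue uses a different vocabulary.
DEFAULT_STRENGTH_MAP = {
    "Functional MTI": "strong",
    "Functional MTI (Weak)": "weak",
    "Non-Functional MTI": None,
    "Non-Functional MTI (Weak)": None,
}


@dataclass
class MTIRecord:
    """One miRNA-target interaction with its pooled evidence labels."""

    mirna: str
    target: str
    functional: bool
    evidence: list = field(default_factory=list)

    def __post_init__(self):
        bad = [e for e in self.evidence if e not in ("strong", "weak")]
        if bad:
            raise ValueError(f"unknown evidence strength label(s) {bad!r}")


@dataclass
class TargetIndex:
    """Species-restricted map miRNA -> set of uppercase target symbols."""

    species: str
    map: dict

    def __len__(self):
        return len(self.map)

    @property
    def mirnas(self):
        return list(self.map)

    def to_table(self, path):
        """Serialize as tab-delimited miRNA -> comma-joined targets."""
        with open(path, "w") as fh:
            for mir, targets in self.map.items():
                fh.write(f"{mir}\t{','.join(sorted(targets))}\n")

    @classmethod
    def from_table(cls, path, species: str):
        mapping = {}
        with open(path) as fh:
            for line in fh:
                mir, targets = line.rstrip("\n").split("\t")
                mapping[mir] = frozenset(targets.split(","))
        return cls(species=species, map=mapping)


def _strength(label: str, strength_map: dict) -> str | None:
    label = label.strip()
    if label in strength_map:
        return strength_map[label]
    # fall back to the documented rule on unseen miRTarBase-style labels
    if "Non-Functional" in label:
        return None
    if "(Weak)" in label:
        return "weak"
    if "Functional" in label:
        return "strong"
    raise ValueError(f"unrecognized Support Type label: {label!r}")


def read_mti_table(path, strength_map: dict | None = None) -> list[MTIRecord]:
    """Read a miRTarBase-like tab-delimited table into pooled MTIRecords.

    Required columns: ``miRNA``, ``Target Gene``, ``Support Type``.
    Multiple rows for the same (miRNA, target) pair (one per supporting
    reference) are pooled into a single record.
    """
    strength_map = strength_map or DEFAULT_STRENGTH_MAP
    df = pd.read_csv(path, sep="\t")
    required = {"miRNA", "Target Gene", "Support Type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MTI table {path} lacks columns {sorted(missing)}")
    records: dict[tuple, MTIRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        mirna = str(getattr(row, "miRNA"))
        target = str(getattr(row, "_1"))  # "Target Gene"
        label = str(getattr(row, "_2"))  # "Support Type"
        try:
            strength = _strength(label, strength_map)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        key = (mirna, target.upper())
        rec = records.get(key)
        if rec is None:
            rec = MTIRecord(mirna=mirna, target=target, functional=True, evidence=[])
            records[key] = rec
        if strength is None:
            rec.functional = False
        else:
            rec.evidence.append(strength)
    return list(records.values())


def filter_mtis(records: list[MTIRecord]) -> list[MTIRecord]:
    """Keep functional MTIs with >=1 strong evidence or >=2 weak evidences.

    Evidence for duplicate (miRNA, target) rows must have been pooled
    beforehand (``read_mti_table`` does this).  Idempotent.
    """
    kept = []
    for rec in records:
        if not rec.functional:
            continue
        n_strong = sum(1 for e in rec.evidence if e == "strong")
        n_weak = sum(1 for e in rec.evidence if e == "weak")
        if n_strong >= 1 or n_weak >= 2:
            kept.append(rec)
    return kept


def build_target_index(filtered: list[MTIRecord], species: str) -> TargetIndex:
    """Group filtered records by miRNA into an uppercase-symbol index,
    restricted to the species prefix (hsa-/mmu-)."""
    if species not in SPECIES_PREFIX:
        raise ValueError(f"species must be one of {sorted(SPECIES_PREFIX)}")
    prefix = SPECIES_PREFIX[species]
    mapping: dict[str, set] = {}
    for rec in filtered:
        if not rec.mirna.startswith(prefix):
            continue
        mapping.setdefault(rec.mirna, set()).add(rec.target.upper())
    if not mapping:
        raise ValueError(f"no {species} interactions left after filtering")
    return TargetIndex(species=species, map={m: frozenset(t) for m, t in mapping.items()})


def target_jaccard(index: TargetIndex) -> pd.DataFrame:
    """Jaccard index |A∩B|/|A∪B| for every pair of miRNA target lists."""
    mirnas = index.mirnas
    if len(mirnas) < 2:
        raise ValueError("need at least two miRNAs to compare target lists")
    J = np.eye(len(mirnas))
    for i, a in enumerate(mirnas):
        for j in range(i + 1, len(mirnas)):
            A, B = index.map[a], index.map[mirnas[j]]
            J[i, j] = J[j, i] = len(A & B) / len(A | B)
    return pd.DataFrame(J, index=mirnas, columns=mirnas)


def set_overlap_pvalue(set_a, set_b, universe_size: int, side: str = "over") -> float:
    """Hypergeometric over/under-enrichment p-value of the overlap of two
    sets drawn from a common universe.

    over:  P(X >= |A∩B|); under: P(X <= |A∩B|),
    X ~ Hypergeometric(universe_size, |A|, |B|).
    """
    a, b = set(set_a), set(set_b)
    overlap = len(a & b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set sizes exceed the universe")
    if overlap > min(len(a), len(b)):
        raise ValueError("overlap exceeds the smaller set")
    if side == "over":
        return hypergeometric_tail(universe_size, len(a), len(b), overlap)
    if side == "under":
        return _hypergeometric_lower_tail(universe_size, len(a), len(b), overlap)
    raise ValueError("side must be 'over' or 'under'")


def _hypergeometric_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X <= k), X ~ Hypergeometric(N, K, n), by integer arithmetic.

    Computed as a direct sum of the lower-tail pmf (not 1 - upper tail), so
    extremely small under-enrichment p-values keep full relative accuracy.
    """
    import math
    from fractions import Fraction

    lo = max(0, n - (N - K))
    hi = min(n, K)
    if k >= hi:
        return 1.0
    if k < lo:
        return 0.0
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, k + 1))
    return float(Fraction(num, math.comb(N, n)))
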