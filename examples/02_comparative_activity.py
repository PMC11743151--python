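"""Differential miRNA activity between two cell populations.

Builds a synthetic two-population single-cell dataset in which one miRNA's
targets are down-regulated in population A only, runs the full pipeline
(clean -> normalize -> z-score -> per-cell exact mHG test), and ranks
miRNAs by the FDR-corrected two-sided Wilcoxon rank-sum p-value comparing
the per-cell activity p-values of the two populations.
"""

import tempfile
from pathlib import Path

from scmira import (
    assign_comparative_tiers,
    build_target_index,
    comparative_scores,
    compute_activity_matrix,
    filter_mtis,
    preprocess_pipeline,
    read_mti_table,
)
from scmira.synth import SyntheticTruth, generate_mti_fixture, generate_single_cell_dataset

# ---- synthetic study: 10 miRNAs, one with activity planted in popA ----
mti = generate_mti_fixture(n_mirnas=10, targets_per_mirna=20, n_genes=200, seed=1)
planted = "hsa-miR-synth1-5p"
truth = SyntheticTruth(planted_mirnas=[planted], delta=2.0, seed=1)
cm = generate_single_cell_dataset(truth, mti, 200, 400, populations=("popA", "popB"))
truth.planted_cells = {planted: [c for c in cm.counts.columns if c.endswith("popA")]}
cm = generate_single_cell_dataset(truth, mti, 200, 400, populations=("popA", "popB"))

with tempfile.TemporaryDirectory() as d:
    mti_path = Path(d) / "mti.tsv"
    mti.to_csv(mti_path, sep="\t", index=False)
    index = build_target_index(filter_mtis(read_mti_table(mti_path)), "homo_sapiens")

# ---- pipeline ----
z = preprocess_pipeline(cm, sample_size=None)
activity = compute_activity_matrix(z, index, n_jobs=1)
report = assign_comparative_tiers(comparative_scores(activity), activity)

print(report[["mirna", "wrs_p", "score", "tier", "rank"]].head(5).to_string(index=False))
print()
print(f"planted miRNA: {planted} -> rank "
      f"{int(report.loc[report.mirna == planted, 'rank'].iloc[0])}")
# The planted miRNA should top the list with an extremely small corrected
# WRS p-value (its targets rank low only in popA cells); tier 1 means it is
# both differentially active (score < 1e-8) and among the most active
# miRNAs in at least one population.
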