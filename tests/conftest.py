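import numpy as np
import pandas as pd
import pytest

from scmira.mti import build_target_index, filter_mtis, read_mti_table
from scmira.synth import SyntheticTruth, generate_mti_fixture, generate_single_cell_dataset


@pytest.fixture
def tiny_counts():
    """4 genes x 4 cells with simple integer counts."""
    return pd.DataFrame(
        [[1, 3, 0, 2], [4, 0, 2, 2], [0, 5, 5, 1], [2, 2, 3, 3]],
        index=["G1", "G2", "G3", "G4"],
        columns=["c1", "c2", "c3", "c4"],
    )


def make_index(mti_df, species="homo_sapiens", tmp_path=None):
    """Build a TargetIndex from a fixture DataFrame via the table reader."""
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        p = os.path.join(d, "mti.tsv")
        mti_df.to_csv(p, sep="\t", index=False)
        return build_target_index(filter_mtis(read_mti_table(p)), species)


def make_planted_comparative(
    seed,
    delta=2.0,
    n_mirnas=10,
    targets_per_mirna=20,
    n_genes=200,
    cells_per_group=200,
    planted_mirna="hsa-miR-synth1-5p",
    disjoint=False,
):
    """Two-population dataset with activity planted in the first population.

    Returns (CountMatrix, TargetIndex, truth).  With delta=0 the planted
    list is empty and the populations are exchangeable.  ``disjoint``
    makes the miRNA target sets non-overlapping, so non-planted miRNAs are
    genuinely null.
    """
    mti = generate_mti_fixture(
        n_mirnas, targets_per_mirna, n_genes, seed=seed, disjoint=disjoint
    )
    n_cells = 2 * cells_per_group
    planted = [planted_mirna] if delta > 0 else []
    truth = SyntheticTruth(planted_mirnas=planted, delta=delta, seed=seed)
    cm = generate_single_cell_dataset(
        truth, mti, n_genes, n_cells, populations=("popA", "popB")
    )
    if planted:
        truth.planted_cells = {
            planted_mirna: [c for c in cm.counts.columns if c.endswith("popA")]
        }
        cm = generate_single_cell_dataset(
            truth, mti, n_genes, n_cells, populations=("popA", "popB")
        )
    return cm, make_index(mti), truth
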