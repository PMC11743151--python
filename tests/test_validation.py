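"""Expression-vs-activity agreement procedures."""

import numpy as np
import pandas as pd
import pytest

from scmira.activity import compute_activity_matrix
from scmira.preprocess import CountMatrix, normalize_total, preprocess_pipeline
from scmira.validation import (
    classify_activity,
    collapse_strands,
    compare_target_expression,
    expression_activity_agreement,
    sum_precursor_expression,
)

from conftest import make_planted_comparative


class TestPrecursorSummation:
    def test_precursors_summed_into_mature_name(self):
        expr = pd.Series({"miR-Y-1": 5.0, "miR-Y-2": 7.0, "miR-X": 3.0})
        out = sum_precursor_expression(expr)
        assert out["miR-Y"] == 12.0
        assert out["miR-X"] == 3.0

    def test_identity_without_suffixed_rows(self):
        expr = pd.Series({"miR-A": 1.0, "miR-B": 2.0})
        assert sum_precursor_expression(expr).equals(expr)

    def test_all_zero_rows_removed(self):
        expr = pd.Series({"miR-Y-1": 0.0, "miR-Y-2": 0.0, "miR-X": 3.0})
        out = sum_precursor_expression(expr)
        assert list(out.index) == ["miR-X"]


class TestClassification:
    @pytest.mark.parametrize(
        "p,label", [(0.04, "active"), (0.07, "neither"), (0.2, "non_active"),
                    (0.05, "neither"), (0.1, "neither")]
    )
    def test_thresholds(self, p, label):
        out = classify_activity(pd.Series({"m": p}))
        assert out["m"] == label

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_activity(pd.Series({"m": 0.0}))


class TestStrandCollapse:
    def test_any_active_strand_wins(self):
        c = pd.Series({"miR-1-5p": "active", "miR-1-3p": "non_active"})
        assert collapse_strands(c)["miR-1"] == "active"

    def test_nonactive_strand_with_active_sibling_excluded(self):
        c = pd.Series({"miR-2-5p": "non_active", "miR-2-3p": "active"})
        assert collapse_strands(c)["miR-2"] == "active"

    def test_both_neither(self):
        c = pd.Series({"miR-3-5p": "neither", "miR-3-3p": "neither"})
        assert collapse_strands(c)["miR-3"] == "neither"

    def test_strandless_ids_pass_through(self):
        c = pd.Series({"miR-4": "non_active"})
        assert collapse_strands(c)["miR-4"] == "non_active"


class TestAgreement:
    def test_active_mirnas_at_top_give_small_pvalue(self):
        mirnas = [f"miR-{i}" for i in range(40)]
        expr = pd.Series(np.arange(40, 0, -1, dtype=float), index=mirnas)
        labels = pd.Series(
            ["active"] * 10 + ["neither"] * 30, index=mirnas
        )
        res = expression_activity_agreement(expr, labels, end="top_active")
        assert res.pvalue < 0.01

    def test_all_active_is_degenerate(self):
        mirnas = ["a", "b", "c"]
        expr = pd.Series([3.0, 2.0, 1.0], index=mirnas)
        labels = pd.Series(["active"] * 3, index=mirnas)
        res = expression_activity_agreement(expr, labels, end="top_active")
        assert res.pvalue == 1.0

    def test_independent_labels_usually_insignificant(self):
        rng = np.random.default_rng(0)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mirnas = [f"miR-{i}" for i in range(60)]
            expr = pd.Series(rng.uniform(size=60), index=mirnas)
            labels = pd.Series(
                rng.choice(["active", "neither"], size=60, p=[0.3, 0.7]), index=mirnas
            )
            res = expression_activity_agreement(expr, labels, end="top_active")
            ok += res.pvalue >= 0.05
        assert ok >= 18  # >= 90% of seeds

    def test_bottom_end_targets_non_active(self):
        mirnas = [f"miR-{i}" for i in range(30)]
        expr = pd.Series(np.arange(30, dtype=float), index=mirnas)
        labels = pd.Series(
            ["non_active"] * 8 + ["neither"] * 22, index=mirnas
        )  # least expressed are non-active
        res = expression_activity_agreement(expr, labels, end="bottom_nonactive")
        assert res.pvalue < 0.01

    def test_requires_shared_mirnas(self):
        with pytest.raises(ValueError):
            expression_activity_agreement(
                pd.Series({"a": 1.0}), pd.Series({"b": "active"})
            )


class TestTargetExpressionComparison:
    def test_identical_groups_give_one(self):
        counts = pd.DataFrame(
            {"c1_A": [5, 5], "c2_A": [5, 5], "c1_B": [5, 5], "c2_B": [5, 5]},
            index=["G1", "G2"],
        )
        m = CountMatrix(
            counts=counts,
            population=pd.Series(["A", "A", "B", "B"], index=counts.columns),
        )
        assert compare_target_expression(m, {"G1"}, None) == 1.0

    def test_disjoint_groups_match_wrs_arithmetic(self):
        counts = pd.DataFrame(
            [[1, 2, 3, 10, 11, 12]], index=["G1"],
            columns=[f"c{i}" for i in range(6)],
        )
        m = CountMatrix(
            counts=counts,
            population=pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns),
        )
        assert compare_target_expression(m, {"G1"}, None) == pytest.approx(0.0495, abs=5e-4)

    def test_planted_downshift_detected(self):
        cm, idx, truth = make_planted_comparative(seed=7)
        planted = truth.planted_mirnas[0]
        norm = normalize_total(cm)
        p = compare_target_expression(norm, idx.map[planted], None)
        assert p < 0.01


def test_agreement_on_planted_coexpression_and_under_null():
    """Expressed miRNAs with planted activity are detected as enriched at
    the top of the expression ranking (p < 0.05 in >= 90% of 20 seeds);
    with activity labels shuffled the agreement disappears (p >= 0.05 in
    >= 90% of seeds).  Mirrors the per-sample agreement procedure: one
    planted cell's activity p-values are classified and compared against a
    miRNA expression ranking in which the active miRNAs are the most
    expressed."""
    from scmira.synth import SyntheticTruth, generate_mti_fixture, generate_single_cell_dataset
    from conftest import make_index

    hits, null_misses = 0, 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        mti = generate_mti_fixture(15, 20, 400, seed=seed)
        mirnas = sorted(mti["miRNA"].unique())
        planted = mirnas[:5]
        truth = SyntheticTruth(planted_mirnas=planted, delta=2.0, seed=seed)
        all_cells = [f"CELL{j + 1:05d}" for j in range(60)]
        planted_cells = all_cells[:30]
        truth.planted_cells = {m: planted_cells for m in planted}
        cmat = generate_single_cell_dataset(truth, mti, 400, 60)
        z = preprocess_pipeline(cmat, sample_size=None)
        a = compute_activity_matrix(z, make_index(mti), n_jobs=1)
        labels = classify_activity(a.pvalues[planted_cells[0]])
        # expressed miRNAs are exactly the planted (active) ones
        expr = pd.Series(
            [10.0 + rng.uniform() if m in planted else rng.uniform() for m in mirnas],
            index=mirnas,
        )
        res = expression_activity_agreement(expr, labels, end="top_active")
        hits += res.pvalue < 0.05
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        res_null = expression_activity_agreement(expr, shuffled, end="top_active")
        null_misses += res_null.pvalue >= 0.05
    assert hits >= 0.9 * n_seeds
    assert null_misses >= 0.9 * n_seeds
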