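"""DEG classification, response summaries, amplitude decomposition, rank test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from auxphase import (
    amplitude_decomposition,
    classify_degs,
    rank_sum_test,
    response_summary,
    zscore_normalize,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj",
                                       "norm_expr_mock", "norm_expr_treated"])


class TestClassifyDegs:
    def test_basic_partition(self):
        table = make_table(
            [
                ("a", 2.0, 0.01, 1, 3),
                ("b", 2.0, 0.20, 1, 3),
                ("c", -1.5, 0.01, 3, 1),
                ("d", 0.0, 0.01, 2, 2),
                ("e", 1.0, np.nan, 1, 2),
            ]
        )
        out = classify_degs(table)
        assert dict(zip(out["gene_id"], out["deg_class"])) == {
            "a": "up", "b": "ns", "c": "down", "d": "ns", "e": "ns",
        }

    def test_fold_change_cutoff_excludes_weak_genes(self):
        """A non-stringent |log2fc| > 0.3 cutoff drops sub-threshold genes."""
        table = make_table([("a", 0.2, 0.01, 1, 1.2)])
        assert classify_degs(table, lfc_threshold=0.3)["deg_class"].iloc[0] == "ns"

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        table = make_table(
            [(f"g{i}", rng.normal(), rng.random(), 0, 0) for i in range(200)]
        )
        up1 = set(classify_degs(table, alpha=0.01).query("deg_class=='up'")["gene_id"])
        up5 = set(classify_degs(table, alpha=0.05).query("deg_class=='up'")["gene_id"])
        assert up1 <= up5


class TestResponseSummary:
    def test_counts_and_mean(self):
        table = classify_degs(
            make_table(
                [("a", 1, 0.01, 0, 0), ("b", 2, 0.01, 0, 0),
                 ("c", 3, 0.01, 0, 0), ("d", -1, 0.01, 0, 0)]
            )
        )
        profile = response_summary(table)
        assert (profile.n_up, profile.n_down) == (3, 1)
        assert profile.up_fraction == 0.75
        assert profile.mean_l2fc == pytest.approx(1.25)
        assert sum(profile.hist_counts) == 4

    def test_all_up_ratio_string_handles_zero_down(self):
        table = classify_degs(make_table([("a", 1, 0.01, 0, 0), ("b", 2, 0.01, 0, 0)]))
        profile = response_summary(table)
        assert profile.up_fraction == 1.0
        assert profile.ratio_string == "2:0"

    def test_empty_deg_set_rejected(self):
        table = classify_degs(make_table([("a", 1.0, 0.9, 0, 0)]))
        with pytest.raises(ValueError, match="empty DEG"):
            response_summary(table)


class TestAmplitudeDecomposition:
    def test_worked_example_means(self):
        table = classify_degs(
            make_table(
                [(f"g{i}", fc, 0.01, mock, 6.0)
                 for i, (fc, mock) in enumerate([(5, 1), (4, 2), (3, 3), (2, 4), (1, 5)])]
            )
        )
        d = amplitude_decomposition(table, k=2)
        assert d.top_mock_mean == pytest.approx(1.5)
        assert d.bottom_mock_mean == pytest.approx(4.5)
        assert d.top_treated_mean == d.bottom_treated_mean == pytest.approx(6.0)
        assert set(d.top_genes).isdisjoint(d.bottom_genes)

    def test_k_clamped_when_few_degs(self):
        table = classify_degs(
            make_table([(f"g{i}", i + 1, 0.01, 1, 2) for i in range(5)])
        )
        d = amplitude_decomposition(table, k=20)
        assert d.k == 5 and d.k_clamped
        assert set(d.top_genes) == set(d.bottom_genes)

    def test_identical_mock_distributions_give_p_one(self):
        table = classify_degs(
            make_table([(f"g{i}", i + 1, 0.01, 2.0, 6.0) for i in range(4)])
        )
        d = amplitude_decomposition(table, k=2)
        assert d.mock_p == 1.0

    def test_no_degs_in_direction_rejected(self):
        table = classify_degs(make_table([("a", 1.0, 0.01, 0, 1)]))
        with pytest.raises(ValueError, match="down"):
            amplitude_decomposition(table, direction="down")


class TestRankSumTest:
    def test_exact_one_sided_small_case(self):
        assert rank_sum_test([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=5).tolist()
            b = rng.normal(size=4).tolist()
            assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))

    def test_exact_branch_matches_scipy_exact(self):
        """Independent cross-check of the enumerated null distribution."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(2, 7))).tolist()
            b = rng.normal(size=int(rng.integers(2, 7))).tolist()
            ours = rank_sum_test(a, b, "greater")
            ref = mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_branches_agree_at_crossover(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_a = int(rng.integers(2, 11))
            a = rng.normal(size=n_a).tolist()
            b = rng.normal(size=12 - n_a).tolist()
            exact = rank_sum_test(a, b, method="exact")
            approx = rank_sum_test(a, b, method="asymptotic")
            assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestZscoreNormalize:
    def test_unit_spaced_row(self):
        out = zscore_normalize(np.array([[1.0, 2.0, 3.0]]))
        assert out == pytest.approx(np.array([[-1.0, 0.0, 1.0]]))

    def test_constant_row_maps_to_zero(self):
        out = zscore_normalize(np.array([[5.0, 5.0, 5.0]]))
        assert out == pytest.approx(np.zeros((1, 3)))

    def test_rows_have_zero_mean(self):
        rng = np.random.default_rng(1)
        out = zscore_normalize(rng.normal(size=(30, 6)))
        assert np.abs(out.mean(axis=1)).max() < 1e-12

    def test_dataframe_round_trip_keeps_labels(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 7.0]], index=["g1", "g2"], columns=["s1", "s2"])
        out = zscore_normalize(df)
        assert list(out.index) == ["g1", "g2"]
        assert list(out.columns) == ["s1", "s2"]

    def test_short_rows_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(np.array([[1.0]]))
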