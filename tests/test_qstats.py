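"""ΔΔCt quantification, Wilcoxon/t tests and viability normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ernascan as es


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])


class TestDdctFoldChange:
    def test_no_change_gives_fold_one(self):
        rows = []
        for i, cond in enumerate(["control", "control", "treated", "treated"]):
            rows += [(f"s{i}", cond, "TARGET", 24.0), (f"s{i}", cond, "REF", 18.0)]
        out = es.ddct_fold_change(ct_frame(rows), "TARGET", "REF")
        assert out["fold_change"].tolist() == pytest.approx([1.0] * 4)

    def test_one_cycle_shift_halves_expression(self):
        rows = [
            ("c0", "control", "TARGET", 23.0), ("c0", "control", "REF", 18.0),
            ("t0", "treated", "TARGET", 24.0), ("t0", "treated", "REF", 18.0),
        ]
        out = es.ddct_fold_change(ct_frame(rows), "TARGET", "REF", efficiency=2.0)
        treated = out.loc[out["condition"] == "treated", "fold_change"].iloc[0]
        assert treated == pytest.approx(0.5)

    def test_random_table_matches_spreadsheet_oracle(self, oracles):
        rng = np.random.default_rng(41)
        rows = []
        for i in range(20):
            cond = "control" if i % 2 else "treated"
            sample = f"s{i}"
            for gene, base in (("TARGET", 25.0), ("REF", 18.0)):
                for _ in range(3):
                    rows.append((sample, cond, gene, base + rng.normal(0, 1)))
        out = es.ddct_fold_change(ct_frame(rows), "TARGET", "REF")
        expected = oracles.ddct_by_spreadsheet(rows, "TARGET", "REF")
        for _, row in out.iterrows():
            assert row["fold_change"] == pytest.approx(expected[row["sample_id"]])

    def test_invariant_to_per_sample_ct_offset(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(8):
            cond = "control" if i < 4 else "treated"
            rows.append((f"s{i}", cond, "TARGET", 24 + rng.normal()))
            rows.append((f"s{i}", cond, "REF", 18 + rng.normal()))
        base = es.ddct_fold_change(ct_frame(rows), "TARGET", "REF")
        shifted_rows = [
            (s, c, g, ct + 3.7 * int(s[1:])) for (s, c, g, ct) in rows
        ]
        shifted = es.ddct_fold_change(ct_frame(shifted_rows), "TARGET", "REF")
        assert shifted["fold_change"].tolist() == pytest.approx(base["fold_change"].tolist())

    def test_sample_missing_reference_excluded_with_warning(self, caplog):
        rows = [
            ("c0", "control", "TARGET", 23.0), ("c0", "control", "REF", 18.0),
            ("t0", "treated", "TARGET", 24.0),  # no REF row
        ]
        import logging
        with caplog.at_level(logging.WARNING, logger="ernascan"):
            out = es.ddct_fold_change(ct_frame(rows), "TARGET", "REF")
        assert list(out["sample_id"]) == ["c0"]
        assert "excluded" in caplog.text

    def test_same_target_and_reference_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            es.ddct_fold_change(ct_frame([]), "REF", "REF")


class TestWilcoxon:
    def test_identical_pairs_undefined(self):
        result = es.wilcoxon_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.undefined and result.n_dropped == 3

    def test_one_sample_vs_one_matches_enumeration(self, oracles):
        data = [0.4, 0.5, 0.6, 0.45, 0.55]
        result = es.wilcoxon_test(data, 1.0)
        expected = oracles.signed_rank_p_by_enumeration([v - 1.0 for v in data])
        assert result.method == "exact"
        assert result.p_value == pytest.approx(expected)

    def test_exact_signed_rank_equals_enumeration_all_small_n(self, oracles):
        rng = np.random.default_rng(43)
        for n in range(3, 11):
            for _ in range(5):
                d = rng.normal(0.2, 1.0, size=n)
                result = es.wilcoxon_test(d, 0.0)
                assert result.p_value == pytest.approx(
                    oracles.signed_rank_p_by_enumeration(list(d))
                ), f"n={n}"

    def test_exact_signed_rank_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, size=9)
            ours = es.wilcoxon_test(d, 0.0)
            ref = sps.wilcoxon(d, mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_rank_sum_equals_enumeration(self, oracles):
        rng = np.random.default_rng(45)
        for _ in range(5):
            a = rng.normal(0, 1, size=5)
            b = rng.normal(0.5, 1, size=6)
            result = es.wilcoxon_test(a, b, mode="rank_sum")
            assert result.method == "exact"
            assert result.p_value == pytest.approx(
                oracles.rank_sum_p_by_enumeration(list(a), list(b))
            )

    def test_rank_sum_type_one_error_near_alpha(self):
        rng = np.random.default_rng(46)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            if es.wilcoxon_test(a, b, mode="rank_sum").p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_normal_approximation_close_to_scipy_large_n(self):
        rng = np.random.default_rng(47)
        d = rng.normal(0.2, 1.0, size=30)
        ours = es.wilcoxon_test(d, 0.0)
        ref = sps.wilcoxon(d, mode="approx", correction=False)
        assert ours.method == "normal_approx"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestTTest:
    def test_identical_groups_t_zero_p_one(self):
        result = es.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_matches_textbook_formula_and_scipy(self, oracles):
        rng = np.random.default_rng(48)
        for _ in range(5):
            a = list(rng.normal(0, 1, size=6))
            b = list(rng.normal(0.8, 1.2, size=8))
            result = es.t_test(a, b)
            assert result.statistic == pytest.approx(oracles.t_test_by_hand(a, b))
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert result.statistic == pytest.approx(ref.statistic)
            assert result.p_value == pytest.approx(ref.pvalue)

    def test_zero_variance_unequal_means_degenerate(self):
        result = es.t_test([1.0, 1.0], [2.0, 2.0])
        assert result.undefined and result.method == "degenerate"

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(49)
        rejections = sum(
            es.t_test(rng.normal(size=10), rng.normal(size=10)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestNormalizeViability:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["cell_line", "arm", "concentration", "value"])

    def test_all_equal_normalizes_to_one(self):
        rows = [("L", "targeting", c, 100.0) for c in (0, 0, 3, 5)]
        out = es.normalize_viability(self._table(rows))
        assert out["normalized"].tolist() == pytest.approx([1.0] * 4)

    def test_half_of_baseline(self):
        rows = [("L", "targeting", 0, 100.0), ("L", "targeting", 5, 50.0)]
        out = es.normalize_viability(self._table(rows))
        assert out.loc[out["concentration"] == 5, "normalized"].iloc[0] == pytest.approx(0.5)

    def test_random_table_equals_groupwise_division(self):
        rng = np.random.default_rng(50)
        rows = []
        for line in ("A", "B"):
            for arm in ("targeting", "scrambled"):
                for conc in (0, 0, 0, 3, 4, 5):
                    rows.append((line, arm, conc, float(rng.uniform(40, 120))))
        table = self._table(rows)
        out = es.normalize_viability(table)
        for (line, arm), group in table.groupby(["cell_line", "arm"]):
            baseline = group.loc[group["concentration"] == 0, "value"].mean()
            expected = group["value"] / baseline
            assert out.loc[group.index, "normalized"].tolist() == pytest.approx(
                expected.tolist()
            )

    def test_missing_drug_free_row_names_arm(self):
        rows = [("L", "targeting", 3, 80.0)]
        with pytest.raises(ValueError, match="targeting"):
            es.normalize_viability(self._table(rows))


class TestKnockdownRecovery:
    def test_two_fold_knockdown_recovered_at_n8(self):
        """Median recovered fold change sits in [0.4, 0.6] for >= 8/10 seeds
        under a true two-fold reduction with realistic replicate noise."""
        in_band = 0
        for seed in range(10):
            ct = es.simulate_knockdown_ct(
                n_experiments=8, true_fold=0.5, ct_noise_sd=0.3, seed=seed
            )
            out = es.ddct_fold_change(ct, "TARGET", "REF")
            median = out.loc[out["condition"] == "treated", "fold_change"].median()
            if 0.4 <= median <= 0.6:
                in_band += 1
        assert in_band >= 8
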