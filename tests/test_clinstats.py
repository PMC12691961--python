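"""Closed-form and hand-computed oracles for the statistics layer."""

import numpy as np
import pandas as pd
import pytest

from rectseg.clinstats import (
    RatingTable,
    bh_adjust,
    bland_altman,
    compare_metric_table,
    compare_paired,
    compare_unpaired,
    fleiss_kappa,
    fold_ci,
    normality_gate,
    rating_summary,
    simulate_ratings,
)


class TestNormalityGate:
    def test_normal_draws_pass_mostly(self):
        """Seeded standard-normal samples should be gated normal >= 90%."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(50)
            hits += normality_gate(x) == "normal"
        assert hits >= 90

    def test_bimodal_sample_non_normal(self):
        assert normality_gate([1, 1, 1, 1, 10, 10, 10, 10]) == "non_normal"

    def test_constant_sample_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate([2.0, 2.0, 2.0]) == "non_normal"

    def test_too_small(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestComparePaired:
    def test_all_equal_degenerate(self):
        res = compare_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.degenerate

    def test_wilcoxon_exact_n6_all_positive(self):
        """All 6 differences positive: exact two-sided p = 2/2^6."""
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 30.0])
        b = a - np.array([1.0, 2.0, 3.0, 4.0, 5.0, 20.0])
        res = compare_paired(a, b)
        assert res.test_name == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(2 / 64)
        assert res.effect_size == pytest.approx(1.0)

    def test_normal_shift_uses_paired_t(self):
        from scipy import stats

        a = np.zeros(30)
        # differences are exact normal quantiles -> Shapiro passes
        b = a + 1.0 + 0.5 * stats.norm.ppf((np.arange(30) + 0.5) / 30)
        res = compare_paired(b, a)
        assert res.test_name == "paired_t"
        d_expected = (b - a).mean() / (b - a).std(ddof=1)
        assert res.effect_size == pytest.approx(d_expected)

    def test_constant_shift_guarded(self):
        a = np.arange(10, dtype=float)
        res = compare_paired(a + 2.0, a)
        # sd of differences is zero -> degenerate, no fabricated p
        assert res.degenerate


class TestCompareUnpaired:
    def test_identical_groups_null_center(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(20)
        res = compare_unpaired(a, a.copy())
        assert res.p_value > 0.99
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_rank_biserial(self):
        res = compare_unpaired([1.0, 2.0, 3.0], [10.0, 11.0, 12.0],
                               force="nonparametric")
        assert res.test_name == "mann_whitney_u"
        assert res.effect_size == pytest.approx(-1.0)

    def test_welch_statistic_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(25) * 1.0 + 0.3
        b = rng.standard_normal(40) * 2.0
        res = compare_unpaired(a, b)
        assert res.test_name == "welch_t"
        t_expected = (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        )
        assert res.statistic == pytest.approx(t_expected)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_step_up_worked_example(self):
        adj = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_output_dominates_input(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFoldCI:
    def test_identical_folds_zero_width(self):
        mean, lo, hi = fold_ci([0.9, 0.9, 0.9])
        assert (mean, lo, hi) == (0.9, 0.9, 0.9)

    def test_closed_form_k5(self):
        values = [0.88, 0.90, 0.91, 0.92, 0.89]
        mean, lo, hi = fold_ci(values)
        from scipy import stats

        se = np.std(values, ddof=1) / np.sqrt(5)
        t4 = stats.t.ppf(0.975, 4)
        assert mean == pytest.approx(0.90)
        assert lo == pytest.approx(0.90 - t4 * se)
        assert hi == pytest.approx(0.90 + t4 * se)
        assert (lo, hi) == (pytest.approx(0.8804, abs=2e-4), pytest.approx(0.9196, abs=2e-4))

    def test_wider_at_higher_level(self):
        v = [0.8, 0.85, 0.9, 0.95]
        _, lo95, hi95 = fold_ci(v, 0.95)
        _, lo99, hi99 = fold_ci(v, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            fold_ci([0.9])


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_constant_offset(self):
        res = bland_altman([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(2.0)
        assert res.loa_low == pytest.approx(2.0)
        assert res.loa_high == pytest.approx(2.0)

    def test_closed_form_differences(self):
        ref = np.zeros(4)
        pred = np.array([-1.0, 0.0, 1.0, 2.0])
        res = bland_altman(pred, ref)
        sd = np.std(pred, ddof=1)
        assert res.bias == pytest.approx(0.5)
        assert res.loa_low == pytest.approx(0.5 - 1.96 * sd)
        assert res.loa_high == pytest.approx(0.5 + 1.96 * sd)
        assert (res.loa_low, res.loa_high) == (
            pytest.approx(-2.030, abs=1e-3), pytest.approx(3.030, abs=1e-3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0, 2.0])


class TestFleissKappa:
    def test_unanimous_items_kappa_one(self):
        table = RatingTable(np.array([
            ["Poor"] * 3, ["Excellent"] * 3, ["Fair"] * 3, ["Excellent"] * 3,
        ], dtype=object))
        assert fleiss_kappa(table)["kappa"] == pytest.approx(1.0)

    def test_hand_computed_two_items(self):
        """(A,A,B), (B,B,A) with 2 categories: kappa = -1/3."""
        table = RatingTable(np.array([
            ["Poor", "Poor", "Fair"],
            ["Fair", "Fair", "Poor"],
        ], dtype=object))
        assert fleiss_kappa(table)["kappa"] == pytest.approx(-1 / 3)

    def test_rater_permutation_invariance(self):
        rng = np.random.default_rng(0)
        table = simulate_ratings(12, 4, agreement=0.6, seed=3)
        permuted = RatingTable(table.ratings[:, rng.permutation(4)])
        assert fleiss_kappa(permuted)["kappa"] == pytest.approx(
            fleiss_kappa(table)["kappa"]
        )

    def test_single_category_chance_saturated(self):
        table = RatingTable(np.array([["Excellent"] * 3] * 4, dtype=object))
        with pytest.warns(UserWarning, match="chance-saturated"):
            res = fleiss_kappa(table)
        assert not res["defined"]

    def test_kappa_bounded(self):
        for seed in range(5):
            table = simulate_ratings(20, 3, agreement=0.5, seed=seed)
            res = fleiss_kappa(table)
            if res["defined"]:
                assert -1.0 <= res["kappa"] <= 1.0


class TestRatingSummary:
    def test_all_excellent(self):
        table = RatingTable(np.array([["Excellent"] * 3] * 4, dtype=object))
        summary = rating_summary(table)
        assert summary["Excellent"] == pytest.approx(100.0)
        assert summary["Poor"] == 0.0

    def test_uniform_thirds(self):
        table = RatingTable(np.array([
            ["Poor", "Fair", "Excellent"],
            ["Fair", "Excellent", "Poor"],
            ["Excellent", "Poor", "Fair"],
        ], dtype=object))
        for pct in rating_summary(table).values():
            assert pct == pytest.approx(100 / 3)

    def test_counting_oracle(self):
        table = simulate_ratings(15, 3, agreement=0.7, seed=2)
        summary = rating_summary(table)
        for cat in table.categories:
            expected = 100.0 * (table.ratings == cat).sum() / table.ratings.size
            assert summary[cat] == pytest.approx(expected)


class TestWilcoxonTypeIError:
    def test_null_rejection_rate_near_nominal(self):
        """Symmetric-null paired differences, n=20, 2000 replicates."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            from scipy import stats

            d = rng.standard_normal(20)
            _, p = stats.wilcoxon(d, alternative="two-sided", method="exact")
            rejections += p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 0.015


class TestCompareMetricTable:
    def test_bh_applied_across_family(self):
        rng = np.random.default_rng(0)
        n = 30
        df = pd.DataFrame({
            "diagnosis": ["prostate"] * n + ["cervical"] * n,
            "dsc": np.r_[rng.normal(0.91, 0.02, n), rng.normal(0.89, 0.02, n)],
            "hd_mm": np.r_[rng.normal(3.2, 0.5, n), rng.normal(3.5, 0.5, n)],
            "asd_mm": np.r_[rng.normal(1.1, 0.2, n), rng.normal(1.2, 0.2, n)],
        })
        results = compare_metric_table(df, metric_cols=("dsc", "hd_mm", "asd_mm"))
        assert len(results) == 3
        raw = [r.p_value for r in results]
        adj = [r.p_adjusted for r in results]
        assert all(q >= p - 1e-12 for p, q in zip(raw, adj))
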