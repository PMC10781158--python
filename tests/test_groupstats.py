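"""ANOVA, Levene and the stepwise Student-Newman-Keuls procedure."""

import numpy as np
import pytest
from scipy import stats

from barovar.groupstats import (
    GroupData,
    levene_test,
    oneway_anova,
    snk_posthoc,
    summarize,
)


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        g = GroupData({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        res = oneway_anova(g)
        assert res.f_stat == pytest.approx(27.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.ms_within == pytest.approx(1.0)

    def test_identical_groups_give_zero_f(self):
        g = GroupData({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        res = oneway_anova(g)
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, 8) for i in range(4)}
        res = oneway_anova(GroupData(groups))
        ref = stats.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_invariance_to_shift_and_scaling(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(i, 1.0, 6) for i in range(3)}
        base = oneway_anova(GroupData(groups))
        shifted = oneway_anova(GroupData({k: v + 100.0 for k, v in groups.items()}))
        scaled = oneway_anova(GroupData({k: 3.0 * v for k, v in groups.items()}))
        assert shifted.f_stat == pytest.approx(base.f_stat)
        assert scaled.f_stat == pytest.approx(base.f_stat)


class TestLevene:
    def test_equal_spreads_give_zero_w(self):
        g = GroupData({"a": [0.0, 2.0], "b": [10.0, 12.0], "c": [5.0, 7.0]})
        res = levene_test(g)
        assert res.w_stat == pytest.approx(0.0)

    def test_matches_scipy_variants(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(0, 1 + i, 8) for i in range(3)}
        for center in ("mean", "median"):
            res = levene_test(GroupData(groups), center=center)
            ref = stats.levene(*groups.values(), center=center)
            assert res.w_stat == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(3)
        rej = 0
        reps = 2000
        for _ in range(reps):
            g = GroupData({f"g{i}": rng.normal(0, 1, 8) for i in range(4)})
            rej += levene_test(g).p_value <= 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.015)


class TestSnk:
    def test_identical_groups_have_no_significant_pairs(self):
        g = GroupData({n: [2.0, 2.1, 1.9, 2.0] for n in "abcd"})
        res = snk_posthoc(g)
        assert not any(p.significant for p in res.pairwise)
        assert len(set(res.letters.values())) == 1

    def test_two_groups_equivalent_to_pooled_t_test(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
            g = GroupData({"x": x, "y": y})
            snk_sig = snk_posthoc(g).pairwise[0].significant
            t_sig = stats.ttest_ind(x, y).pvalue <= 0.05
            assert snk_sig == t_sig

    def test_two_low_one_high_letters(self):
        rng = np.random.default_rng(5)
        g = GroupData(
            {
                "low": 0.0 + rng.normal(0, 0.5, 8),
                "low2": 0.1 + rng.normal(0, 0.5, 8),
                "high": 5.0 + rng.normal(0, 0.5, 8),
            }
        )
        res = snk_posthoc(g)
        assert not res.is_significant("low", "low2")
        assert res.is_significant("low", "high")
        assert res.is_significant("low2", "high")
        assert res.letters["low"] == res.letters["low2"]
        assert res.letters["high"] != res.letters["low"]

    def test_blocking_never_exceeds_full_span_range_test(self):
        # monotonicity: a pair inside a non-significant span stays non-significant
        rng = np.random.default_rng(6)
        for _ in range(100):
            g = GroupData({f"g{i}": rng.normal(0, 1, 8) for i in range(4)})
            a = oneway_anova(g)
            res = snk_posthoc(g, a)
            names = sorted(g.groups, key=lambda n: g.groups[n].mean())
            full_span_sig = res.is_significant(names[0], names[-1])
            if not full_span_sig:
                assert not any(p.significant for p in res.pairwise)

    def test_unavailable_quantiles_error(self):
        g = GroupData({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValueError):
            snk_posthoc(g, alpha_level=-0.5)


class TestSummarize:
    def test_mean_sd_label(self):
        g = GroupData({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        table = summarize(g)
        row = table[table["group"] == "a"].iloc[0]
        assert row["label"].startswith("2.00 ± 1.00")

    def test_single_group_has_no_annotations(self):
        g = GroupData({"only": [1.0, 2.0, 3.0]})
        table = summarize(g)
        assert table.iloc[0]["label"] == "2.00 ± 1.00"

    def test_reference_symbols_follow_order(self):
        rng = np.random.default_rng(7)
        g = GroupData(
            {
                "SO": rng.normal(0.4, 0.05, 8),
                "SOE": rng.normal(0.45, 0.05, 8),
                "TO": rng.normal(0.8, 0.05, 8),
                "TOE": rng.normal(1.0, 0.05, 8),
            }
        )
        table = summarize(g, order=["SO", "SOE", "TO", "TOE"])
        to_label = table[table["group"] == "TO"].iloc[0]["label"]
        assert "*" in to_label  # vs SO
        so_label = table[table["group"] == "SO"].iloc[0]["label"]
        assert "*" not in so_label
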