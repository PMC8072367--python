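import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ece_screen.assay_stats import (
    allelic_imbalance_table,
    allelic_ratio_normalized,
    chip_percent_input,
    fold_induction,
    group_percent_difference,
    group_tests,
    ifp_gland_mean,
    percent_input,
)


class TestPercentInput:
    def test_closed_forms(self):
        assert percent_input(25, 25) == pytest.approx(100.0)
        assert percent_input(25, 30) == pytest.approx(3.125)
        assert percent_input(30, 25) == pytest.approx(3200.0)

    @settings(derandomize=True, max_examples=60)
    @given(ct=st.floats(min_value=1.0, max_value=40.0))
    def test_equal_cts_always_give_100(self, ct):
        assert percent_input(ct, ct) == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        ct_in=st.floats(min_value=5.0, max_value=35.0),
        ct_ip=st.floats(min_value=5.0, max_value=35.0),
        delta=st.floats(min_value=0.01, max_value=5.0),
    )
    def test_monotonic_in_both_arguments(self, ct_in, ct_ip, delta):
        assert percent_input(ct_in + delta, ct_ip) > percent_input(ct_in, ct_ip)
        assert percent_input(ct_in, ct_ip + delta) < percent_input(ct_in, ct_ip)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            percent_input(0, 25)

    def test_table_averages_technical_replicates_first(self):
        rows = []
        for tech, jitter in enumerate((-0.3, 0.0, 0.3)):
            rows.append({"target": "siteA", "condition": "input",
                         "replicate": 1, "tech": tech, "ct": 25 + jitter})
            rows.append({"target": "siteA", "condition": "IP_SP1",
                         "replicate": 1, "tech": tech, "ct": 30 + jitter})
        out = chip_percent_input(pd.DataFrame(rows))
        assert len(out) == 1
        # mean Cts are exactly 25 and 30 after technical averaging
        assert out.loc[0, "percent_input"] == pytest.approx(3.125)

    def test_missing_input_condition_raises(self):
        df = pd.DataFrame(
            [{"target": "a", "condition": "IP_SP1", "replicate": 1, "ct": 30}]
        )
        with pytest.raises(ValueError, match="input"):
            chip_percent_input(df)


class TestFoldInduction:
    def _table(self, folds, reps=3, renilla=2.0e5, base=0.05):
        rows = []
        for construct, fold in folds.items():
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "construct": construct,
                        "replicate": r,
                        "firefly": base * fold * renilla,
                        "renilla": renilla,
                    }
                )
        return pd.DataFrame(rows)

    def test_construct_at_control_level_folds_to_one(self):
        df = self._table({"Control": 1.0, "x": 1.0})
        out = fold_induction(df, "Control")
        assert np.allclose(out["fold"], 1.0)

    def test_thirteen_fold_headline_shape(self):
        df = self._table({"Control": 1.0, "hECE18": 13.0})
        out = fold_induction(df, "Control")
        mean = out.groupby("construct")["fold"].mean()
        assert mean["hECE18"] == pytest.approx(13.0)
        assert mean["Control"] == pytest.approx(1.0)

    def test_invariant_to_joint_rescaling_of_luminescence(self):
        rng = np.random.default_rng(0)
        df = self._table({"Control": 1.0, "a": 4.0, "b": 0.5})
        df["firefly"] *= np.exp(rng.normal(0, 0.2, len(df)))
        scaled = df.copy()
        scaled["firefly"] *= 2.0
        scaled["renilla"] *= 2.0
        assert np.allclose(
            fold_induction(df, "Control")["fold"],
            fold_induction(scaled, "Control")["fold"],
        )

    def test_missing_control_raises(self):
        df = self._table({"x": 2.0})
        with pytest.raises(ValueError, match="Control"):
            fold_induction(df, "Control")

    def test_nonpositive_renilla_rejected(self):
        df = self._table({"Control": 1.0})
        df.loc[0, "renilla"] = 0.0
        with pytest.raises(ValueError, match="Renilla"):
            fold_induction(df, "Control")

    def test_per_experiment_control_normalization(self):
        # experiment 2 has a 10x hotter control; per-experiment folds
        # must still be 2.0 for the construct
        rows = []
        for exp, scale in ((1, 1.0), (2, 10.0)):
            for construct, fold in (("Control", 1.0), ("x", 2.0)):
                rows.append(
                    {"construct": construct, "replicate": 1,
                     "experiment": exp, "firefly": scale * fold,
                     "renilla": 1.0}
                )
        out = fold_induction(pd.DataFrame(rows), "Control",
                             per_experiment=True)
        assert np.allclose(out.loc[out["construct"] == "x", "fold"], 2.0)


class TestAllelic:
    def test_balanced_and_imbalanced_closed_forms(self):
        assert allelic_ratio_normalized(0.5, 0.5) == pytest.approx(1.0)
        assert allelic_ratio_normalized(0.8, 0.5) == pytest.approx(1.6)

    def test_swapping_allele_labels_gives_reciprocal(self):
        c, g = 0.8, 0.5
        orig = allelic_ratio_normalized(c, g)
        flipped = allelic_ratio_normalized(1 / c, 1 / g)
        assert flipped == pytest.approx(1 / orig)

    def test_zero_gdna_rejected(self):
        with pytest.raises(ValueError):
            allelic_ratio_normalized(0.8, 0.0)

    def test_table_matches_samples(self):
        df = pd.DataFrame(
            [
                {"sample": "s1", "template": "cDNA", "ratio_raw": 1.6},
                {"sample": "s1", "template": "gDNA", "ratio_raw": 1.0},
                {"sample": "s2", "template": "cDNA", "ratio_raw": 0.9},
                {"sample": "s2", "template": "gDNA", "ratio_raw": 0.9},
            ]
        )
        out = allelic_imbalance_table(df)
        assert dict(zip(out["sample"], out["ratio_normalized"])) == pytest.approx(
            {"s1": 1.6, "s2": 1.0}
        )

    def test_unmatched_sample_raises(self):
        df = pd.DataFrame(
            [{"sample": "s1", "template": "cDNA", "ratio_raw": 1.0}]
        )
        with pytest.raises(ValueError, match="gDNA"):
            allelic_imbalance_table(df)


class TestGlands:
    def test_left_right_average(self):
        df = pd.DataFrame(
            [
                {"animal": "m1", "left": 10, "right": 12},
                {"animal": "m2", "left": 0, "right": 0},
            ]
        )
        out = ifp_gland_mean(df)
        assert out["mean_glands"].tolist() == [11.0, 0.0]
        assert not out["single_limb"].any()

    def test_single_limb_flagged(self):
        df = pd.DataFrame([{"animal": "m1", "left": 9, "right": np.nan}])
        out = ifp_gland_mean(df)
        assert out.loc[0, "mean_glands"] == 9.0
        assert bool(out.loc[0, "single_limb"])

    def test_fractional_counts_rejected(self):
        df = pd.DataFrame([{"animal": "m1", "left": 9.5, "right": 10}])
        with pytest.raises(ValueError, match="integer"):
            ifp_gland_mean(df)

    def test_group_difference_recovers_planted_effect(self):
        rng = np.random.default_rng(17)
        base, effect = 14.0, 17.0
        a = rng.normal(base, 1.5, size=4000)
        b = rng.normal(base * (1 + effect / 100), 1.5, size=4000)
        est = group_percent_difference(a, b)
        assert est == pytest.approx(effect, abs=0.6)


class TestGroupTests:
    def test_identical_groups_t_zero_p_one(self):
        res = group_tests({"a": [1, 2, 3], "b": [1, 2, 3]}, design="ttest")
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_equal_group_means_give_f_zero(self):
        res = group_tests(
            {"a": [1, 2, 3], "b": [2, 1, 3], "c": [3, 2, 1]}, design="anova"
        )
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_f_matches_hand_computed_sums_of_squares(self):
        groups = {
            "g1": [10.0, 11.0, 12.0, 9.0, 13.0],
            "g2": [14.0, 15.0, 13.0, 16.0, 12.0],
            "g3": [20.0, 19.0, 21.0, 18.0, 22.0],
        }
        arrays = [np.array(v) for v in groups.values()]
        grand = np.concatenate(arrays).mean()
        ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        f_manual = (ss_between / 2) / (ss_within / 12)
        res = group_tests(groups, design="anova")
        assert res.statistic == pytest.approx(f_manual)

    def test_tukey_agrees_with_statsmodels(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(1, 1, 8),
            "c": rng.normal(0.5, 1, 8),
        }
        res = group_tests(groups, design="anova")
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(values, labels)
        assert np.allclose(
            sorted(res.pairwise["pvalue_adj"]), sorted(sm.pvalues), atol=1e-6
        )

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            group_tests({"a": [1.0, 1.0], "b": [1.0, 1.0]}, design="ttest")

    def test_anova_needs_two_values_per_group(self):
        with pytest.raises(ValueError):
            group_tests({"a": [1.0], "b": [1.0, 2.0]}, design="anova")

    def test_ttest_needs_exactly_two_groups(self):
        with pytest.raises(ValueError):
            group_tests(
                {"a": [1, 2], "b": [2, 3], "c": [3, 4]}, design="ttest"
            )
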