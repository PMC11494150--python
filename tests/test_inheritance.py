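import itertools

import numpy as np
import pandas as pd
import pytest

from heterotx import (SimConfig, TrioSpec, classify_all, classify_mode,
                      classify_pav, expressed_flag, merged_overdominant,
                      midparent_test, simulate)
from heterotx.inheritance import mode_gene_set, summarize_calls

ONE_TRIO = (TrioSpec("AB", "AB", "AA", "BB"),)


class TestExpressedFlag:
    @pytest.mark.parametrize("values,expected", [
        ((0, 0, 0), False),
        ((5, 3, 0.2), True),
        ((1.0, 0.9, 0.9), False),  # only one replicate reaches tau
        ((1.0, 1.0, 0.0), True),
    ])
    def test_threshold_rule(self, values, expected):
        assert expressed_flag(values, tau=1.0, min_reps=2) is expected


def _pav_oracle(f1, p1, p2):
    """Independently coded PAV truth table."""
    table = {
        (False, True, True): "I",
        (False, True, False): "II",
        (False, False, True): "II",
        (True, False, False): "III",
        (True, True, False): "IV",
        (True, False, True): "IV",
        (True, True, True): "V",
    }
    return table[(f1, p1, p2)]


class TestClassifyPav:
    def test_parents_only_is_type_one(self):
        assert classify_pav(False, True, True) == "I"

    def test_hybrid_only_is_type_three(self):
        assert classify_pav(True, False, False) == "III"

    def test_exhaustive_truth_table(self):
        """All 7 informative rows match the independent enumeration."""
        for f1, p1, p2 in itertools.product([True, False], repeat=3):
            if not (f1 or p1 or p2):
                with pytest.raises(ValueError):
                    classify_pav(f1, p1, p2)
                continue
            assert classify_pav(f1, p1, p2) == _pav_oracle(f1, p1, p2)


def _mode_oracle(fp1, fp2, fmpv, pp):
    """Independently coded rule table for the dominance taxonomy."""
    if fmpv == "equal":
        return "additive"
    if fp1 == "higher" and fp2 == "higher":
        return "overdominant"
    if fp1 == "lower" and fp2 == "lower":
        return "underdominant"
    if (fp1, pp) == ("equal", "higher") or (fp2, pp) == ("equal", "lower"):
        return "high_dominance"
    if (fp1, pp) == ("equal", "lower") or (fp2, pp) == ("equal", "higher"):
        return "low_dominance"
    return "other"


class TestClassifyMode:
    def test_above_both_parents_is_overdominant(self):
        assert classify_mode("higher", "higher", "higher", "equal") \
            == "overdominant"

    def test_equal_to_higher_parent_is_high_dominance(self):
        assert classify_mode("equal", "lower", "lower", "higher") \
            == "high_dominance"

    def test_additive_has_precedence(self):
        assert classify_mode("higher", "higher", "equal", "equal") \
            == "additive"

    def test_exhaustive_enumeration_matches_oracle(self):
        states = ("higher", "equal", "lower")
        for combo in itertools.product(states, repeat=4):
            assert classify_mode(*combo) == _mode_oracle(*combo)

    def test_invalid_tri_state_rejected(self):
        with pytest.raises(ValueError, match="tri-state"):
            classify_mode("up", "equal", "equal", "equal")


class TestMidparentTest:
    def test_additive_genes_not_significant(self):
        cfg = SimConfig(n_genes=300, trios=ONE_TRIO, conditions=("WW",),
                        mode_proportions={"additive": 1.0},
                        response_proportions={"null": 1.0}, seed=21)
        eset, _ = simulate(cfg)
        res = midparent_test(eset, "AB", "WW")
        assert (res["state"] == "equal").mean() > 0.95
        assert abs(res["log2fc"].median()) < 0.2

    def test_strong_overdominance_detected(self):
        """8x overdominant genes called higher than mid-parent.

        Most genes stay additive so median-of-ratios normalization has a
        non-DE majority to anchor on."""
        cfg = SimConfig(n_genes=600, trios=ONE_TRIO, conditions=("WW",),
                        mode_proportions={"overdominant": 0.2,
                                          "additive": 0.8},
                        effect_log2fc=3.0, dispersion=0.01,
                        response_proportions={"null": 1.0}, seed=22)
        eset, truth = simulate(cfg)
        res = midparent_test(eset, "AB", "WW").set_index("gene_id")
        modes = truth.modes("AB")
        over = modes.index[modes == "overdominant"]
        assert (res.loc[over, "state"] == "higher").mean() > 0.95
        assert (res.loc[over, "log2fc"] > 0).all()


class TestClassifyAll:
    def test_pure_additive_recovery(self):
        cfg = SimConfig(n_genes=400, trios=ONE_TRIO,
                        mode_proportions={"additive": 1.0},
                        response_proportions={"null": 1.0}, seed=31)
        eset, _ = simulate(cfg)
        calls = classify_all(eset)
        ww = calls[calls["condition"] == "WW"]
        assert (ww["mode"] == "additive").mean() >= 0.90

    def test_pav_simulation_never_type_five(self):
        cfg = SimConfig(n_genes=100, trios=ONE_TRIO,
                        mode_proportions={"pav_I": 1.0},
                        response_proportions={"null": 1.0}, seed=32)
        eset, _ = simulate(cfg)
        calls = classify_all(eset)
        assert (calls["pav_type"] == "I").all()

    def test_labels_partition_detected_genes(self, small_sim):
        cfg, eset, _ = small_sim
        calls = classify_all(eset)
        for (_, _), sub in calls.groupby(["trio_id", "condition"]):
            detected = sub[sub["pav_type"] != "not_detected"]
            assert len(sub) == cfg.n_genes
            # PAV labels exhaustive and exclusive over detected genes
            assert detected["pav_type"].isin(list("IV") + ["I", "II", "III",
                                                           "IV", "V"]).all()
            type_v = detected[detected["pav_type"] == "V"]
            mode_total = type_v["mode"].value_counts().sum()
            assert mode_total == len(type_v)

    def test_parent_swap_symmetry(self, small_sim):
        """Swapping P1/P2 leaves additive/over/under calls invariant and
        maps high<->high, low<->low dominance."""
        cfg, eset, _ = small_sim
        calls = classify_all(eset)
        df = eset.sheet.df.copy()
        df["role"] = df["role"].map({"hybrid": "hybrid",
                                     "parent1": "parent2",
                                     "parent2": "parent1"})
        from heterotx.data_io import SampleSheet, TrioExpressionSet
        swapped = TrioExpressionSet(counts=eset.counts.copy(),
                                    sheet=SampleSheet(df))
        calls_sw = classify_all(swapped)
        key = ["gene_id", "trio_id", "condition"]
        merged = calls.merge(calls_sw, on=key, suffixes=("", "_sw"))
        assert (merged["pav_type"] == merged["pav_type_sw"]).all()
        assert (merged["mode"] == merged["mode_sw"]).all()

    def test_summary_counts_sum_to_detected(self, small_sim):
        _, eset, _ = small_sim
        calls = classify_all(eset)
        summary = summarize_calls(calls)
        for (trio, cond), sub in calls.groupby(["trio_id", "condition"]):
            detected = (sub["pav_type"] != "not_detected").sum()
            pav_sum = summary[(summary["trio_id"] == trio)
                              & (summary["condition"] == cond)
                              & (summary["layer"] == "pav")]["count"].sum()
            assert pav_sum == detected


class TestMergedOverdominant:
    def test_union_with_no_type_three(self):
        calls = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(5)],
            "trio_id": "AB", "condition": "WW",
            "pav_type": ["V"] * 5,
            "mode": ["overdominant"] * 5,
            "merged_overdominant": [True] * 5,
        })
        assert len(merged_overdominant(calls, "AB", "WW")) == 5

    def test_type_three_and_overdominant_disjoint(self, small_sim):
        _, eset, _ = small_sim
        calls = classify_all(eset)
        for (trio, cond), sub in calls.groupby(["trio_id", "condition"]):
            n_iii = (sub["pav_type"] == "III").sum()
            n_over = (sub["mode"] == "overdominant").sum()
            assert len(merged_overdominant(calls, trio, cond)) \
                == n_iii + n_over

    def test_recovery_on_simulation(self):
        """Type-III plus overdominant genes recovered with Jaccard >= 0.8."""
        cfg = SimConfig(
            n_genes=600, trios=ONE_TRIO, conditions=("WW",),
            mode_proportions={"pav_III": 1 / 6, "overdominant": 1 / 6,
                              "additive": 4 / 6},
            response_proportions={"null": 1.0}, seed=33)
        eset, truth = simulate(cfg)
        calls = classify_all(eset)
        recovered = merged_overdominant(calls, "AB", "WW")
        modes = truth.modes("AB")
        expected = frozenset(modes.index[modes.isin(["pav_III",
                                                     "overdominant"])])
        jaccard = len(recovered & expected) / len(recovered | expected)
        assert jaccard >= 0.8
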