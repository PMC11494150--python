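import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterotx import (Contrast, bh_adjust, call_de, fpkm, nb_test, nb_wald,
                      replicate_correlation, size_factors)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = np.tile([[10], [20], [5]], (1, 2))
        assert np.allclose(size_factors(mat), [1.0, 1.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 100, size=(50, 1))
        mat = np.hstack([a, 2 * a])
        f = size_factors(mat)
        assert np.isclose(f[1] / f[0], 2.0)

    def test_matches_median_of_ratios_oracle(self):
        mat = np.array([[10, 20, 14], [5, 8, 6], [100, 210, 160],
                        [1, 2, 1], [40, 90, 55]], dtype=float)
        ref = np.exp(np.mean(np.log(mat), axis=1))
        raw = np.array([np.median(mat[:, j] / ref) for j in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(size_factors(mat), expected)

    def test_fallback_to_totals_with_warning(self):
        mat = np.array([[5, 0], [0, 7]], dtype=float)
        with pytest.warns(UserWarning, match="total-count"):
            f = size_factors(mat)
        assert np.allclose(f, np.array([5, 7]) / np.sqrt(35))


class TestFpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g1"])
        # pad the library to a 1e6 total with a second gene
        counts.loc["g2"] = [1_000_000 - 100]
        lengths = pd.Series({"g1": 1000, "g2": 1000})
        out = fpkm(counts, lengths)
        assert np.isclose(out.loc["g1", "s1"], 100.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 1000})
        assert fpkm(counts, lengths).loc["g1", "s1"] == 0.0

    def test_matches_spreadsheet_recomputation(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(4, 3)),
                              index=list("abcd"), columns=list("xyz"))
        lengths = pd.Series(rng.integers(200, 5000, size=4), index=list("abcd"))
        out = fpkm(counts, lengths)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (
                    lengths[g] * counts[s].sum())
                assert np.isclose(out.loc[g, s], expected)

    def test_missing_length_raises(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(KeyError):
            fpkm(counts, pd.Series({"other": 100}))

    def test_linear_in_counts(self):
        counts = pd.DataFrame({"s1": [10, 20]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 100, "g2": 100})
        a = fpkm(counts, lengths)
        b = fpkm(counts * 3, lengths)
        # tripling all counts triples the totals too: FPKM is unchanged
        assert np.allclose(a, b)


class TestReplicateCorrelation:
    def test_self_correlation_is_one(self):
        expr = pd.DataFrame({"a": [1, 5, 2], "b": [2, 1, 9]})
        corr = replicate_correlation(expr)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.equals(corr.T)

    def test_anti_ordered_pair(self):
        expr = pd.DataFrame({"a": [1.0, 3.0], "b": [3.0, 1.0]})
        corr = replicate_correlation(expr, log_transform=False)
        assert np.isclose(corr.loc["a", "b"], -1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.uniform(0, 100, size=(10, 2)),
                            columns=["a", "b"])
        x = np.log2(expr["a"] + 1)
        y = np.log2(expr["b"] + 1)
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert np.isclose(replicate_correlation(expr).loc["a", "b"], expected)


class TestNbWald:
    def test_all_zero_both_groups(self):
        g = np.zeros((3, 3))
        res = nb_wald(g, g, alpha_mode=0.05)
        assert (res["p_value"] == 1.0).all()
        assert (res["log2fc"] == 0.0).all()

    def test_equal_means_statistic_near_zero(self):
        rng = np.random.default_rng(4)
        g1 = rng.poisson(100, size=(200, 20)).astype(float)
        g2 = rng.poisson(100, size=(200, 20)).astype(float)
        res = nb_wald(g1, g2, alpha_mode=1e-8)
        assert abs(res["log2fc"].mean()) < 0.05
        # p-values roughly uniform under the null
        assert 0.2 < (res["p_value"] > 0.5).mean() < 0.8

    def test_null_type_one_error_calibrated(self):
        """Monte-Carlo: type-I error at p<0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(11)
        n, alpha = 5000, 0.05
        mu = 2.0 ** rng.uniform(5, 11, size=n)
        def draw():
            lam = rng.gamma(1 / alpha, mu[:, None] * alpha, size=(n, 3))
            return rng.poisson(lam).astype(float)
        res = nb_wald(draw(), draw(), alpha_mode="shared_mom")
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_increases_with_effect_and_replication(self):
        alpha = 0.05
        mu = np.full(800, 200.0)
        def power(lfc, n_rep, seed):
            rng = np.random.default_rng(seed)
            def draw(m, k):
                lam = rng.gamma(1 / alpha, m[:, None] * alpha, size=(len(m), k))
                return rng.poisson(lam).astype(float)
            res = nb_wald(draw(mu * 2.0 ** lfc, n_rep), draw(mu, n_rep),
                          alpha_mode="shared_mom")
            return (res["p_value"] < 0.05).mean()
        assert power(0.5, 3, 7) < power(1.0, 3, 7) < power(2.0, 3, 7)
        assert power(0.5, 3, 8) < power(0.5, 10, 8)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            nb_wald(np.ones((5, 1)), np.ones((5, 3)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nb_wald(-np.ones((5, 3)), np.ones((5, 3)))

    def test_agrees_with_deseq2_reference(self, small_sim):
        """Independent cross-check: rank agreement with the pydeseq2 fit.

        The engines differ (no shrinkage, MoM dispersion), so the check is
        on log2FC agreement and p-value ranking, not exact values."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        from scipy.stats import spearmanr

        _, eset, _ = small_sim
        samples = (eset.sheet.samples("AB", "hybrid", "WD")
                   + eset.sheet.samples("AB", "hybrid", "WW"))
        counts = eset.counts[samples]
        keep = counts.sum(axis=1) > 0
        counts = counts[keep]
        meta = pd.DataFrame({"condition": ["WD"] * 3 + ["WW"] * 3},
                            index=samples)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "WD", "WW"],
                           quiet=True)
        stats.summary()
        ref = stats.results_df

        contrast = Contrast("AB_WD_vs_WW", ("AB", "hybrid", "WD"),
                            ("AB", "hybrid", "WW"))
        mine = nb_test(eset, contrast).set_index("gene_id").loc[ref.index]
        both = np.isfinite(ref["log2FoldChange"]) & np.isfinite(ref["pvalue"])
        r_lfc = np.corrcoef(mine["log2fc"][both],
                            ref["log2FoldChange"][both])[0, 1]
        rho_p = spearmanr(mine["p_value"][both], ref["pvalue"][both]).statistic
        assert r_lfc > 0.95
        assert rho_p > 0.85


def _bh_brute_force(p):
    """Textbook BH step-up: q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        q[idx] = running_min
    return np.minimum(q, 1.0)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert np.isclose(bh_adjust([0.01])[0], 0.01)

    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_equals_brute_force_bh(self, p):
        assert np.allclose(bh_adjust(p), _bh_brute_force(p))

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_monotone_in_sorted_order_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallDe:
    def _frame(self, lfc, p):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(lfc))],
                             "base_mean": 10.0, "log2fc": lfc,
                             "se_log2fc": 1.0, "p_value": p,
                             "contrast": "c"})

    def test_calling_rule(self):
        # FC 2.5 at FDR 0.01 -> up; FC below gate -> ns; FDR above gate -> ns
        res = call_de(self._frame([1.32, 0.9, -3.0], [0.001, 0.0001, 0.2]))
        assert list(res["call"]) == ["up", "ns", "ns"]

    def test_down_call_symmetric(self):
        res = call_de(self._frame([-1.5], [0.001]))
        assert list(res["call"]) == ["down"]

    def test_custom_thresholds(self):
        res = call_de(self._frame([0.9], [0.001]), fc_threshold=1.5)
        assert list(res["call"]) == ["up"]
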