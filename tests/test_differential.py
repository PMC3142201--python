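import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as st_h

from protquant.differential import (
    AbundanceSeries,
    anova_oneway,
    boxplot_summary,
    concordance,
    fligner_killeen,
    holm_adjust,
    kruskal_wallis,
    run_differential,
    shapiro_wilk_residuals,
)
from protquant.model_io import AnalysisConfig, PeptideQuantTable
from protquant.synthetic import SimulationConfig, simulate_peptide_table


def series(values, groups):
    return AbundanceSeries(np.asarray(values, float), np.asarray(groups))


class TestAnova:
    def test_hand_computed_f(self):
        """SSB = 1.5, SSW = 4 on the 2x3 fixture, so F = (1.5/1)/(4/4)."""
        f, p = anova_oneway(series([1, 2, 3, 2, 3, 4], list("aaabbb")))
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(st.f.sf(1.5, 1, 4))

    def test_matches_scipy_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            groups = np.repeat(["a", "b", "c"], rng.integers(2, 8, size=3))
            vals = rng.normal(size=groups.size)
            f, p = anova_oneway(series(vals, groups))
            ref = st.f_oneway(*[vals[groups == g] for g in "abc"])
            assert f == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_p_matches_f_density_integration(self):
        """p equals numerical integration of the F density tail."""
        from scipy.integrate import quad

        rng = np.random.default_rng(1)
        groups = np.repeat(["a", "b", "c"], 5)
        vals = rng.normal(size=15)
        f, p = anova_oneway(series(vals, groups))
        tail, _ = quad(lambda x: st.f.pdf(x, 2, 12), f, np.inf)
        assert p == pytest.approx(tail, rel=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        f1, _ = anova_oneway(series(vals, groups))
        f2, _ = anova_oneway(series(3.7 * vals - 11.0, groups))
        assert f1 == pytest.approx(f2)

    def test_degenerate_inputs(self):
        assert np.isnan(anova_oneway(series([1, 2], ["a", "b"]))[0])
        f, p = anova_oneway(series([1, 1, 2, 2], ["a", "a", "b", "b"]))
        assert np.isinf(f) and p == 0.0
        f, p = anova_oneway(series([1, 1, 1, 1], ["a", "a", "b", "b"]))
        assert f == 0.0 and p == 1.0


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """Rank sums R_a = 6, R_b = 15 give H = 12/42 * (12 + 75) - 21."""
        h, _ = kruskal_wallis(series([1, 2, 3, 4, 5, 6], list("aaabbb")))
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)
        assert h == pytest.approx(3.857142857, abs=1e-6)

    def test_tie_correction_by_hand(self):
        """With ties, H is divided by 1 - sum(t^3 - t)/(N^3 - N)."""
        vals = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        groups = np.array(list("aaabbb"))
        ranks = st.rankdata(vals)
        n = 6
        h_raw = 12 / (n * (n + 1)) * sum(
            (ranks[groups == g].sum()) ** 2 / 3 for g in "ab") - 3 * (n + 1)
        ties = np.array([2, 2])
        correction = 1 - ((ties ** 3 - ties).sum()) / (n ** 3 - n)
        h, _ = kruskal_wallis(series(vals, groups))
        assert h == pytest.approx(h_raw / correction)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=14)
        groups = np.repeat(["a", "b"], 7)
        h1, _ = kruskal_wallis(series(vals, groups))
        h2, _ = kruskal_wallis(series(np.exp(vals), groups))
        assert h1 == pytest.approx(h2)

    def test_all_equal_values(self):
        h, p = kruskal_wallis(series([2, 2, 2, 2], ["a", "a", "b", "b"]))
        assert h == 0.0 and p == 1.0


class TestShapiro:
    def test_too_small_sample_is_na(self):
        assert np.isnan(shapiro_wilk_residuals(series([1, 2], ["a", "a"])))

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=20)
        groups = np.repeat(["a", "b"], 10)
        p1 = shapiro_wilk_residuals(series(vals, groups))
        p2 = shapiro_wilk_residuals(series(2.5 * vals + 7, groups))
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_w_matches_published_coefficient_computation(self):
        """W for n = 10 from the classic table coefficients: W =
        (sum a_i (x_(n-i+1) - x_(i)))^2 / sum (x - mean)^2."""
        x = np.sort(np.array([148, 154, 158, 160, 161, 162, 166, 170, 182, 195], float))
        a = np.array([0.5739, 0.3291, 0.2141, 0.1224, 0.0399])
        b = (a * (x[::-1][:5] - x[:5])).sum()
        w_hand = b ** 2 / ((x - x.mean()) ** 2).sum()
        w_impl = st.shapiro(x).statistic  # same routine the residual test uses
        assert w_impl == pytest.approx(w_hand, rel=5e-3)


class TestFligner:
    def test_symmetric_case_p_one(self):
        """Groups [1,3] and [2,4] have identical centered spread patterns."""
        p = fligner_killeen(series([1, 3, 2, 4], ["a", "a", "b", "b"]))
        assert p == pytest.approx(1.0)

    def test_detects_scaled_group(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        b = 100 * rng.normal(size=200)
        p = fligner_killeen(series(np.concatenate([a, b]),
                                   np.repeat(["a", "b"], 200)))
        assert p < 0.05

    def test_null_p_values_uniform(self):
        """Under homogeneity the p-value distribution is uniform."""
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            vals = rng.normal(size=30)
            ps.append(fligner_killeen(series(vals, np.repeat(["a", "b", "c"], 10))))
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_is_na(self):
        assert np.isnan(fligner_killeen(series([1, 1, 2, 2], ["a", "a", "b", "b"])))


class TestHolm:
    @pytest.mark.parametrize("raw, expected", [
        ([0.04], [0.04]),
        ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
        ([0.6, 0.5], [1.0, 1.0]),  # cummax: 2*0.5 = 1.0 carries over
    ])
    def test_worked_examples(self, raw, expected):
        np.testing.assert_allclose(holm_adjust(raw), expected)

    def test_na_values_excluded_from_family(self):
        out = holm_adjust([0.01, np.nan, 0.04, 0.03])
        np.testing.assert_allclose(out[[0, 2, 3]], [0.03, 0.06, 0.06])
        assert np.isnan(out[1])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), ref)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st_h.lists(st_h.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_dominated_by_bonferroni_and_order_invariant(self, p):
        adj = holm_adjust(p)
        bonf = np.minimum(np.asarray(p) * len(p), 1.0)
        assert (adj <= bonf + 1e-12).all()
        assert (adj >= np.asarray(p) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(holm_adjust(np.asarray(p)[perm]), adj[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestRunDifferential:
    def test_single_protein_adjusted_equals_raw(self, small_table):
        one = PeptideQuantTable(small_table.data[small_table.data.protein == "P1"])
        res = run_differential(one, AnalysisConfig())
        for test in ("anova", "kw", "shapiro", "fligner"):
            assert res[f"{test}_p_adj"].iloc[0] == pytest.approx(res[f"{test}_p"].iloc[0])

    def test_classification_follows_decision_rule(self):
        cfg = SimulationConfig(n_proteins=150, frac_regulated=0.3,
                               frac_heteroscedastic=0.15, frac_heavy_tailed=0.15,
                               seed=11)
        table, _ = simulate_peptide_table(cfg)
        res = run_differential(table, AnalysisConfig(seed=11))
        a = res.anova_p_adj < 0.05
        k = res.kw_p_adj < 0.05
        ok = (res.fligner_p_adj >= 0.05) & (res.shapiro_p_adj >= 0.05)
        expect = np.select(
            [a & ok, a & k, a, k],
            ["strict_significant", "both_lenient", "anova_only_assumptions_violated", "kw_only"],
            default="not_significant",
        )
        np.testing.assert_array_equal(res.classification.to_numpy(), expect)
        assert (res.anova_p_adj.fillna(0) >= res.anova_p.fillna(0)).all()

    def test_recovers_strongly_regulated_proteins(self):
        cfg = SimulationConfig(n_proteins=200, frac_regulated=0.2, effect_size=0.5,
                               frac_heteroscedastic=0.0, frac_heavy_tailed=0.0,
                               missing_rate=0.0, seed=12)
        table, truth = simulate_peptide_table(cfg)
        res = run_differential(table, AnalysisConfig(seed=12)).merge(truth.table, on="protein")
        reg = res[res.regulated]
        unreg = res[~res.regulated]
        assert (reg.classification == "strict_significant").mean() >= 0.9
        assert (unreg.anova_p_adj < 0.05).sum() == 0

    def test_undermeasured_conditions_dropped_not_protein(self):
        data = pd.DataFrame({
            "protein": ["P1"] * 9,
            "peptide": [f"p{i}" for i in range(9)],
            "condition": ["t0"] * 4 + ["t1"] * 4 + ["t2"],
            "replicate": "r1",
            "ratio": [1.0, 1.1, 0.9, 1.05, 2.0, 2.1, 1.9, 2.05, 5.0],
        })
        res = run_differential(PeptideQuantTable(data), AnalysisConfig())
        assert res.classification.iloc[0] != "untestable"
        f, _ = anova_oneway(series([1.0, 1.1, 0.9, 1.05, 2.0, 2.1, 1.9, 2.05],
                                   ["t0"] * 4 + ["t1"] * 4))
        # the singleton t2 measurement must not enter the statistic
        assert res.anova_p.iloc[0] == pytest.approx(st.f.sf(f, 1, 6))

    def test_untestable_protein_reported(self):
        data = pd.DataFrame({
            "protein": ["P1"] * 2, "peptide": ["a", "b"],
            "condition": ["t0", "t1"], "replicate": "r1", "ratio": [1.0, 2.0],
        })
        res = run_differential(PeptideQuantTable(data), AnalysisConfig())
        assert res.classification.iloc[0] == "untestable"


class TestConcordance:
    def _results(self, anova_p, kw_p):
        df = pd.DataFrame({"protein": [f"P{i}" for i in range(len(anova_p))],
                           "anova_p": anova_p, "kw_p": kw_p})
        for t in ("anova", "kw", "shapiro", "fligner"):
            if f"{t}_p" not in df:
                df[f"{t}_p"] = 0.5
            df[f"{t}_p_adj"] = holm_adjust(df[f"{t}_p"])
        df["classification"] = "not_significant"
        return df

    def test_identical_vectors_rho_one(self):
        p = [0.1, 0.5, 0.9, 0.3]
        assert concordance(self._results(p, p), AnalysisConfig()).spearman_rho == pytest.approx(1.0)

    def test_reversed_vectors_rho_minus_one(self):
        p = np.array([0.1, 0.5, 0.9, 0.3])
        out = concordance(self._results(p, 1 - p), AnalysisConfig())
        assert out.spearman_rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        a = np.array([0.1, 0.1, 0.5, 0.9, 0.3, 0.5])
        b = np.array([0.2, 0.4, 0.4, 0.8, 0.1, 0.9])
        rho = concordance(self._results(a, b), AnalysisConfig()).spearman_rho
        oracle = np.corrcoef(st.rankdata(a), st.rankdata(b))[0, 1]
        assert rho == pytest.approx(oracle)

    def test_too_few_pairs_is_na(self):
        out = concordance(self._results([0.1, np.nan, np.nan, np.nan],
                                        [0.2, np.nan, np.nan, np.nan]), AnalysisConfig())
        assert np.isnan(out.spearman_rho)


class TestBoxplot:
    def test_interpolated_quartiles(self):
        box = boxplot_summary(series([1, 2, 3, 4, 5], ["a"] * 5))[0]
        assert (box.median, box.q1, box.q3) == (3, 2, 4)
        assert box.whisker_low == 1 and box.whisker_high == 5
        assert box.outliers.size == 0

    def test_single_value_collapses(self):
        box = boxplot_summary(series([7.0], ["a"]))[0]
        assert box.median == box.q1 == box.q3 == box.whisker_low == box.whisker_high == 7.0

    def test_extreme_point_is_outlier(self):
        box = boxplot_summary(series([1, 2, 3, 4, 5, 100], ["a"] * 6))[0]
        assert 100 in box.outliers
        assert box.whisker_high <= 5
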