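import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bbtraj.association import (bh_fdr, cmh_test, feature_lm, feature_negbin,
                                fisher_exact, fisher_exact_rxc, mdes_wilcoxon,
                                pairwise_wilcoxon_fdr,
                                stratified_categorical_test, tmm_factors,
                                van_elteren, wilcoxon_power_at,
                                wilcoxon_rank_sum)
from bbtraj.synthetic import simulate_differential_features
from bbtraj.tables import AbundanceTable


class TestBhFdr:
    def test_stepup_small_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_order_preserving(self):
        p = np.array([0.04, 0.001, 0.5, 0.03])
        q = bh_fdr(p)
        qs = bh_fdr(np.sort(p))
        np.testing.assert_allclose(np.sort(q), qs)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_monotone_in_p_and_bounded(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= np.asarray(ps) - 1e-12) & (q <= 1))


class TestExactTests:
    def test_fisher_diagonal_table(self):
        _, p = fisher_exact([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)

    def test_fisher_uniform_table(self):
        _, p = fisher_exact([[1, 1], [1, 1]])
        assert p == 1

    def test_fisher_transpose_invariance(self):
        t = [[5, 2], [1, 7]]
        assert fisher_exact(t)[1] == pytest.approx(
            fisher_exact(np.transpose(t))[1])

    def test_fisher_rxc_matches_2x2_route(self):
        t = [[3, 0], [0, 3]]
        p_rxc, method = fisher_exact_rxc(t)
        assert method == "enumeration"
        assert p_rxc == pytest.approx(fisher_exact(t)[1])

    def test_fisher_rxc_monte_carlo_fallback_seeded(self):
        t = [[8, 3, 4], [2, 7, 5], [5, 5, 6]]
        p1, m1 = fisher_exact_rxc(t, max_tables=10, seed=3)
        p2, _ = fisher_exact_rxc(t, max_tables=10, seed=3)
        assert m1 == "monte_carlo" and p1 == p2

    def test_wilcoxon_fully_separated_triples(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_wilcoxon_identical_samples_p_near_one(self):
        x = np.arange(25.0)
        _, p = wilcoxon_rank_sum(x, x)
        assert p > 0.9

    def test_wilcoxon_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            _, p_exact = wilcoxon_rank_sum(x, y)
            p_norm = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.02


class TestPairwiseWilcoxon:
    def test_two_groups_q_equals_p(self):
        g = {"a": np.arange(5.0), "b": np.arange(5.0) + 10}
        q = pairwise_wilcoxon_fdr(g)
        _, p = wilcoxon_rank_sum(g["a"], g["b"])
        assert q.loc["a", "b"] == pytest.approx(p)

    def test_three_identical_groups_all_insignificant(self):
        x = np.arange(30.0)
        q = pairwise_wilcoxon_fdr({"a": x, "b": x, "c": x})
        vals = q.to_numpy()[~np.isnan(q.to_numpy())]
        assert (vals > 0.9).all()

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(size=8) for k in "abc"}
        q = pairwise_wilcoxon_fdr(g)
        np.testing.assert_allclose(q.to_numpy(), q.to_numpy().T)


class TestStratifiedTests:
    def test_cmh_detects_within_stratum_association(self):
        stat, p = cmh_test([[[5, 0], [0, 5]], [[5, 0], [0, 5]]])
        assert p < 0.01

    def test_cmh_deconfounds_simpson_fixture(self):
        s1 = [[9, 1], [27, 3]]   # OR = 1 within stratum
        s2 = [[3, 27], [1, 9]]   # OR = 1 within stratum
        pooled = np.array(s1) + np.array(s2)
        _, p_naive = fisher_exact(pooled)
        _, p_cmh = cmh_test([s1, s2])
        assert p_naive < 0.05 and p_cmh > 0.05

    def test_cmh_all_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cmh_test([[[3, 2], [0, 0]]])

    def test_van_elteren_single_stratum_matches_wilcoxon_direction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 2
        values = np.concatenate([x, y])
        group = np.array(["a"] * 15 + ["b"] * 15)
        z, p = van_elteren(values, group, np.zeros(30))
        _, p_w = wilcoxon_rank_sum(x, y)
        assert p < 0.01 and p_w < 0.01

    def test_stratified_dispatch_numeric_vs_categorical(self):
        rng = np.random.default_rng(4)
        n = 40
        stratum = np.repeat(["s1", "s2"], n // 2)
        exposure = rng.choice(["e0", "e1"], n)
        numeric = rng.normal(size=n)
        res_num = stratified_categorical_test(numeric, exposure, stratum)
        assert res_num.model == "van_elteren"
        binary = rng.choice(["y", "n"], n)
        res_cat = stratified_categorical_test(binary, exposure, stratum)
        assert res_cat.model == "cmh"


class TestTmm:
    def make(self, mat, cols=None):
        cols = cols or [f"s{i}" for i in range(mat.shape[1])]
        return AbundanceTable(pd.DataFrame(
            mat, index=[f"f{i}" for i in range(mat.shape[0])], columns=cols))

    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 1000, size=50).astype(float)
        t = self.make(np.column_stack([col] * 4))
        np.testing.assert_allclose(tmm_factors(t), 1.0, atol=1e-12)

    def test_pure_depth_difference_unit_factor_ratio(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, size=50).astype(float)
        t = self.make(np.column_stack([col, 2 * col]))
        f = tmm_factors(t)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_inflated_subset_pulls_factor_down(self):
        # 10% of features 4-fold inflated in one sample: the extra reads
        # depress every other feature's fraction of the library, so the
        # compensating TMM factor for that sample must drop below 1
        rng = np.random.default_rng(2)
        base = rng.integers(100, 1000, size=100).astype(float)
        inflated = base.copy()
        inflated[:10] *= 4
        t = self.make(np.column_stack([base, base * 1.01, inflated]))
        f = tmm_factors(t)
        assert f.iloc[2] < f.iloc[0]
        assert f.iloc[2] < 1 < f.iloc[0]

    def test_matches_edger_group_structure(self):
        # cross-check the port against the planted fixture's known behaviour
        tab, meta, _ = simulate_differential_features(
            n_per_group=10, n_features=100, n_differential=0, seed=9)
        f = tmm_factors(tab)
        assert f.abs().between(0.5, 2).all()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


class TestFeatureModels:
    def test_lm_identical_groups_insignificant(self):
        # same column repeated in both groups: zero effect for every feature
        rng = np.random.default_rng(0)
        col = rng.integers(100, 1000, 10).astype(float)
        mat = np.column_stack([col] * 20)
        t = AbundanceTable(pd.DataFrame(
            mat, index=[f"f{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(20)]))
        meta = pd.DataFrame({"group": ["A"] * 10 + ["B"] * 10},
                            index=t.sample_ids)
        res = feature_lm(t, meta, "group", prevalence=0.0)
        assert (res["coefficient"].abs() < 1e-9).all()
        assert (res["q_value"] > 0.9).all()

    def test_lm_recovers_planted_fold_change_with_sign(self):
        tab, meta, diff = simulate_differential_features(seed=11)
        res = feature_lm(tab, meta, "group").set_index("feature_id")
        hits = res.loc[diff]
        assert (hits["q_value"] < 0.1).mean() >= 0.8
        # sign convention: negative = higher in reference (alphabetically
        # first) group; second half of planted set is up in group B
        up_in_b = diff[len(diff) // 2:]
        assert (res.loc[up_in_b, "coefficient"] > 0).all()

    def test_lm_rank_deficient_design_rejected(self):
        tab, meta, _ = simulate_differential_features(
            n_per_group=2, n_features=10, n_differential=0, seed=0)
        meta["dup"] = meta["group"]
        with pytest.raises(Exception):
            feature_lm(tab, meta, "group", covariates=["dup"])

    def test_negbin_agrees_in_sign_with_lm(self):
        tab, meta, diff = simulate_differential_features(seed=12)
        lm = feature_lm(tab, meta, "group").set_index("feature_id")
        nb = feature_negbin(tab, meta, "group").set_index("feature_id")
        both = lm.join(nb, lsuffix="_lm", rsuffix="_nb").loc[diff]
        assert (np.sign(both["coefficient_lm"])
                == np.sign(both["coefficient_nb"])).all()

    def test_negbin_null_type_one_error_controlled(self):
        tab, meta, _ = simulate_differential_features(
            n_per_group=30, n_features=200, n_differential=0, seed=21)
        res = feature_negbin(tab, meta, "group")
        assert (res["p_value"] < 0.05).mean() <= 0.07

    def test_negbin_power_on_three_fold_effect(self):
        tab, meta, diff = simulate_differential_features(
            n_per_group=30, fold_change=3.0, dispersion=0.5, seed=22)
        res = feature_negbin(tab, meta, "group").set_index("feature_id")
        assert (res.loc[diff, "q_value"] < 0.1).mean() >= 0.8

    def test_lm_null_permutation_fdr_controlled(self):
        tab, meta, _ = simulate_differential_features(
            n_per_group=40, n_features=200, n_differential=0, seed=23)
        rng = np.random.default_rng(23)
        meta_perm = meta.copy()
        meta_perm["group"] = rng.permutation(meta["group"].to_numpy())
        res = feature_lm(tab, meta_perm, "group")
        assert (res["q_value"] < 0.1).mean() <= 0.1


class TestPowerAnalysis:
    def test_are_one_reduces_to_t_test_mdes(self):
        from statsmodels.stats.power import TTestIndPower
        d = mdes_wilcoxon(21, 32, are=1.0)
        ref = TTestIndPower().solve_power(nobs1=21, ratio=32 / 21,
                                          alpha=0.05, power=0.8)
        assert d == pytest.approx(ref, abs=1e-4)

    def test_printed_sensitivity_value(self):
        assert mdes_wilcoxon(21, 32) == pytest.approx(0.82, abs=0.01)

    def test_power_function_monotone_in_d(self):
        p1 = wilcoxon_power_at(0.3, 21, 32)
        p2 = wilcoxon_power_at(0.9, 21, 32)
        assert p2 > p1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mdes_wilcoxon(1, 10)
        with pytest.raises(ValueError):
            mdes_wilcoxon(10, 10, are=0)

    def test_monte_carlo_wilcoxon_power_matches_target(self):
        # normal shift model at the returned MDES should hit ~80% power
        d = mdes_wilcoxon(21, 32)
        rng = np.random.default_rng(7)
        reps = 5000
        x = rng.normal(0, 1, size=(reps, 21))
        y = rng.normal(d, 1, size=(reps, 32))
        p = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided",
                               method="asymptotic").pvalue
        power = (p < 0.05).mean()
        assert 0.77 <= power <= 0.83
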