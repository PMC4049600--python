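"""Inferential chain: ANOVA, t-tests, regressions, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nback_ica.stats import (compare_correlations, interaction_regression,
                             one_sample_t, rm_anova, spearman, two_sample_t,
                             ttests, zscore_within_group)


def mixed_anova_oracle(values: np.ndarray, groups: np.ndarray):
    """Cell-means sums-of-squares decomposition for a two-group mixed
    design (within factor = columns).  Independent of pingouin."""
    n, k = values.shape
    gnames = list(dict.fromkeys(groups))
    g_masks = [np.asarray(groups) == g for g in gnames]
    grand = values.mean()
    subj_means = values.mean(axis=1)
    comp_means = values.mean(axis=0)
    ss_group = k * sum(m.sum() * (subj_means[m].mean() - grand) ** 2
                       for m in g_masks)
    ss_subj_within = k * sum(((subj_means[m] - subj_means[m].mean()) ** 2).sum()
                             for m in g_masks)
    ss_comp = n * ((comp_means - grand) ** 2).sum()
    ss_inter = 0.0
    for m in g_masks:
        cell = values[m].mean(axis=0)
        ss_inter += m.sum() * ((cell - subj_means[m].mean()
                                - comp_means + grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_within - ss_comp - ss_inter
    df_g, df_sw = 1, n - 2
    df_c, df_i = k - 1, k - 1
    df_e = (n - 2) * (k - 1)
    return {
        "group": (ss_group / df_g) / (ss_subj_within / df_sw),
        "component": (ss_comp / df_c) / (ss_err / df_e),
        "interaction": (ss_inter / df_i) / (ss_err / df_e),
        "dfs": {"group": (df_g, df_sw), "component": (df_c, df_e),
                "interaction": (df_i, df_e)},
    }


class TestRmAnova:
    def test_published_interaction_dfs(self):
        """38 + 37 subjects, 8 components -> interaction dfs (7, 511)."""
        rng = np.random.default_rng(0)
        le = rng.normal(size=(75, 8))
        groups = np.array(["young"] * 38 + ["old"] * 37)
        res = rm_anova(le, groups)
        inter = next(r for r in res if r.effect == "Interaction")
        assert (inter.df_num, inter.df_den) == (7, 511)

    def test_agrees_with_cell_means_oracle(self):
        rng = np.random.default_rng(1)
        le = rng.normal(size=(14, 4)) + rng.normal(size=(14, 1))
        groups = np.array(["young"] * 7 + ["old"] * 7)
        res = {r.effect: r for r in rm_anova(le, groups)}
        oracle = mixed_anova_oracle(le, groups)
        assert res["group"].F == pytest.approx(oracle["group"], abs=1e-8)
        assert res["component"].F == pytest.approx(oracle["component"],
                                                   abs=1e-8)
        assert res["Interaction"].F == pytest.approx(oracle["interaction"],
                                                     abs=1e-8)

    def test_null_interaction_type_one_error(self):
        """Rejection rate of the interaction at alpha = .05 under a null
        with no planted effects stays near the nominal level."""
        rng = np.random.default_rng(2)
        alpha, n_rep = 0.05, 400
        rejections = 0
        groups = np.array(["young"] * 10 + ["old"] * 10)
        for _ in range(n_rep):
            le = rng.normal(size=(20, 4))
            oracle = mixed_anova_oracle(le, groups)   # fast, same F exactly
            df_i, df_e = oracle["dfs"]["interaction"]
            p = sps.f.sf(oracle["interaction"], df_i, df_e)
            rejections += p < alpha
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_null_f_near_expectation(self):
        """Mean null F over replicates approaches df2/(df2 - 2)."""
        rng = np.random.default_rng(3)
        groups = np.array(["young"] * 12 + ["old"] * 12)
        fs = []
        for _ in range(300):
            le = rng.normal(size=(24, 3))
            fs.append(mixed_anova_oracle(le, groups)["interaction"])
        df_e = (24 - 2) * (3 - 1)
        expected = df_e / (df_e - 2)
        assert np.mean(fs) == pytest.approx(expected, abs=0.25)

    def test_missing_values_rejected(self):
        le = np.ones((6, 3))
        le[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(le, ["young"] * 3 + ["old"] * 3)

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(np.ones((3, 2)), ["young", "old", "old"])


class TestTTests:
    def test_matches_hand_computed_toy_values(self):
        """t on the 6-value set {1,2,3} vs {4,5,7}: pooled t = -3.024."""
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 7])
        res = two_sample_t(x, y)
        sp2 = ((2 * 1.0) + (2 * 7 / 3)) / 4
        t_hand = (2.0 - 16 / 3) / np.sqrt(sp2 * (2 / 3))
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 4

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        res = two_sample_t(x, y)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(float(t_ref), abs=1e-12)
        assert res.p == pytest.approx(float(p_ref), abs=1e-12)

    def test_zero_variance_equal_means_flagged(self):
        res = two_sample_t(np.ones(3), np.ones(4))
        assert res.degenerate and np.isnan(res.t)

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(ValueError):
            two_sample_t(np.ones(2), np.full(2, 2.0))

    def test_power_with_planted_difference(self):
        """Planted group difference 1.0 (SD 1.0) at n = 40/40: empirical
        power at alpha = .05 matches the noncentral-t oracle (~0.994)."""
        rng = np.random.default_rng(5)
        n_rep, hits = 500, 0
        for _ in range(n_rep):
            x = rng.normal(0, 1, 40)
            y = rng.normal(1, 1, 40)
            hits += two_sample_t(x, y).p < 0.05
        assert 0.97 <= hits / n_rep <= 1.0

    def test_ttests_per_component_labels(self):
        rng = np.random.default_rng(6)
        le = rng.normal(size=(10, 2))
        groups = np.array(["young"] * 5 + ["old"] * 5)
        two, one = ttests(le, groups, component_labels=["vlpfc", "fpn"])
        assert len(two) == 2 and len(one) == 4
        assert two[0].label.startswith("vlpfc")


class TestInteractionRegression:
    def test_constant_outcome_zero_slopes(self):
        groups = np.array(["young"] * 6 + ["old"] * 6)
        pred = np.arange(12.0)
        res = interaction_regression(np.full(12, 3.0), groups, pred)
        slopes = res.coefficients[res.coefficients.predictor != "intercept"]
        np.testing.assert_allclose(slopes["beta"], 0.0, atol=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_outcome_perfect_fit(self):
        groups = np.array(["young"] * 6 + ["old"] * 6)
        rng = np.random.default_rng(7)
        pred = rng.normal(size=12)
        z = zscore_within_group(pred, groups)
        outcome = 2.0 + 3.0 * z
        res = interaction_regression(outcome, groups, pred)
        coef = res.coefficients.set_index("predictor")["beta"]
        assert res.r_squared == pytest.approx(1.0)
        assert coef["age*load_effect"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle_on_8_rows(self):
        groups = np.array(["young"] * 4 + ["old"] * 4)
        rng = np.random.default_rng(8)
        pred = rng.normal(size=8)
        outcome = rng.normal(size=8)
        res = interaction_regression(outcome, groups, pred)
        age = np.where(groups == "old", 1.0, -1.0)
        age -= age.mean()
        z = zscore_within_group(pred, groups)
        X = np.column_stack([np.ones(8), age, z, age * z])
        beta = np.linalg.solve(X.T @ X, X.T @ outcome)
        np.testing.assert_allclose(res.coefficients["beta"], beta,
                                   atol=1e-10)

    def test_invariant_to_affine_rescaling_of_predictor(self):
        groups = np.array(["young"] * 8 + ["old"] * 8)
        rng = np.random.default_rng(9)
        pred = rng.normal(size=16)
        outcome = rng.normal(size=16)
        a = interaction_regression(outcome, groups, pred)
        b = interaction_regression(outcome, groups, 100.0 * pred - 7.0)
        np.testing.assert_allclose(a.coefficients["beta"],
                                   b.coefficients["beta"], atol=1e-10)

    def test_collinear_design_raises(self):
        groups = np.array(["young", "young", "old", "old"])
        with pytest.raises(Exception):
            interaction_regression(np.ones(4), groups,
                                   np.array([1.0, 1.0, 2.0, 2.0]))


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            spearman(np.arange(3.0), np.arange(3.0))


class TestCompareCorrelations:
    def test_published_2back_comparison(self):
        """rho -.017 (n=38) vs .534 (n=37) -> z = -2.545, p = .011."""
        res = compare_correlations(-0.017, 38, 0.534, 37)
        assert res.z == pytest.approx(-2.545, abs=0.0005)
        assert res.p == pytest.approx(0.011, abs=0.0005)

    def test_published_0back_comparison(self):
        """rho .098 (n=38) vs .420 (n=37) -> z = -1.451, p = .147."""
        res = compare_correlations(0.098, 38, 0.420, 37)
        assert res.z == pytest.approx(-1.451, abs=0.0005)
        assert res.p == pytest.approx(0.147, abs=0.0005)

    def test_equal_correlations_give_zero(self):
        res = compare_correlations(0.3, 20, 0.3, 50)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_antisymmetry(self):
        a = compare_correlations(0.1, 30, 0.5, 40)
        b = compare_correlations(0.5, 40, 0.1, 30)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("bad", [(1.0, 30, 0.2, 30),
                                     (0.2, 3, 0.2, 30)])
    def test_invalid_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            compare_correlations(*bad)


class TestOneSample:
    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.3, 1, 25)
        res = one_sample_t(x)
        t_ref, p_ref = sps.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(float(t_ref))
        assert res.p == pytest.approx(float(p_ref))
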