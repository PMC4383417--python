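"""Inference procedures: residual regression, trend ANOVA, tallies, ranks."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from facestat.inference import (
    choice_tally,
    gg_epsilon,
    pearson_with_p,
    quadratic_weights,
    rank_tests,
    residualize,
    rm_anova_quadratic,
    second_level_regression,
)
from facestat.synthetic_data import CohortSpec, EffectSpec, synth_cohort, synth_ratings


class TestResidualize:
    def test_perfect_fit_zero_residuals(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(residualize(2 * x + 1, x), 0.0, atol=1e-12)

    def test_orthogonal_gives_centered_y(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])  # zero covariance with x
        assert np.allclose(residualize(y, x), y - y.mean())

    def test_four_point_normal_equations(self):
        """Frozen values from the closed-form normal equations:
        x = (0,1,2,4), y = (1,2,2,5); Sxy = 8.5, Sxx = 8.75, so
        b = 34/35 and residuals = (y - 2.5) - b (x - 1.75)."""
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        expected = (y - 2.5) - (34.0 / 35.0) * (x - 1.75)
        assert np.allclose(residualize(y, x), expected)
        assert abs(residualize(y, x).sum()) < 1e-12

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            residualize(np.arange(4.0), np.ones(4))


@pytest.fixture(scope="module")
def cohort_meta():
    meta, _ = synth_cohort(CohortSpec(seed=3), render=False)
    return meta


class TestSecondLevelRegression:
    def test_fwl_equivalence(self, cohort_meta):
        """The two-stage residual coefficient equals the partial property
        coefficient of the joint regression of rating on (age, property)."""
        table = synth_ratings(cohort_meta,
                              EffectSpec(prop_coefs={"complexity": -0.2},
                                         discretize=False, seed=8),
                              n_participants=5, design="study1")
        res = second_level_regression(table, "complexity")
        for pid, sub in table.groupby("participant_id"):
            x = np.column_stack([np.ones(len(sub)), sub["face_age"],
                                 sub["complexity"]])
            joint = np.linalg.lstsq(x, sub["rating"].to_numpy(), rcond=None)[0][2]
            assert abs(res.betas.loc[pid, "property"] - joint) < 1e-10

    def test_null_property_not_significant(self, cohort_meta):
        """Pure age effect: the property coefficient stays near zero."""
        ps = []
        for rep in range(10):
            table = synth_ratings(cohort_meta, EffectSpec(seed=100 + rep),
                                  n_participants=20, design="study1")
            ps.append(second_level_regression(table,
                                              "fourier_slope").property_test.p)
        assert min(ps) > 0.001 and np.mean(np.array(ps) < 0.05) <= 0.3

    def test_injected_coefficient_recovered(self, cohort_meta):
        betas = []
        for rep in range(10):
            table = synth_ratings(
                cohort_meta,
                EffectSpec(prop_coefs={"fourier_slope": -0.3}, seed=200 + rep),
                n_participants=20, design="study1")
            betas.append(second_level_regression(
                table, "fourier_slope").property_test.mean_beta)
        assert abs(np.mean(betas) + 0.3) < 0.06

    def test_gender_terms(self, cohort_meta):
        table = synth_ratings(cohort_meta, EffectSpec(seed=4),
                              n_participants=5, design="study1")
        res = second_level_regression(table, "complexity", with_gender=True)
        assert set(res.tests) == {"property", "gender", "interaction"}
        assert res.property_test.df == 4

    def test_incomplete_participant_dropped(self, cohort_meta):
        table = synth_ratings(cohort_meta, EffectSpec(seed=5),
                              n_participants=5, design="study1")
        # p00 loses 60% of its rows -> dropped with a warning
        drop = table[table.participant_id == "p00"].index[:66]
        table = table.drop(drop)
        with pytest.warns(UserWarning, match="dropped"):
            res = second_level_regression(table, "complexity")
        assert "p00" not in res.betas.index

    def test_too_few_participants(self, cohort_meta):
        table = synth_ratings(cohort_meta, EffectSpec(seed=6),
                              n_participants=2, design="study1")
        with pytest.raises(ValueError):
            second_level_regression(table, "complexity")


def brute_force_rm_f(data):
    """Textbook sums-of-squares decomposition with explicit loops."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (data[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def long_table(data, conditions):
    n, k = data.shape
    return pd.DataFrame({
        "participant_id": np.repeat([f"p{i}" for i in range(n)], k),
        "condition": np.tile(conditions, n),
        "rating": data.ravel(),
    })


class TestRmAnovaQuadratic:
    TOY = np.array([[3.0, 4.0, 5.0],
                    [2.0, 4.0, 4.0],
                    [4.0, 5.0, 7.0],
                    [3.0, 3.0, 6.0]])

    def test_identical_conditions_f_zero(self):
        data = np.tile(np.array([[2.0], [3.0], [4.0]]), (1, 4))
        res = rm_anova_quadratic(long_table(data, list("abcd")), list("abcd"))
        assert res.f == 0.0

    def test_toy_matrix_vs_brute_force(self):
        conds = ["c1", "c2", "c3"]
        res = rm_anova_quadratic(long_table(self.TOY, conds), conds)
        assert np.isclose(res.f, brute_force_rm_f(self.TOY), rtol=1e-12)
        assert (res.df_num, res.df_den) == (2, 6)

    def test_against_pingouin(self):
        """Independent oracle: pingouin's rm_anova on the same toy data."""
        pingouin = pytest.importorskip("pingouin")
        conds = ["c1", "c2", "c3"]
        tab = long_table(self.TOY, conds)
        tab["participant_id"] = tab["participant_id"].astype("category")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pg = pingouin.rm_anova(data=tab, dv="rating", within="condition",
                                   subject="participant_id", correction=True)
        res = rm_anova_quadratic(tab, conds)
        assert np.isclose(res.f, pg["F"].iloc[0], rtol=1e-8)
        assert np.isclose(res.gg_epsilon, pg["eps"].iloc[0], rtol=1e-8)

    def test_quadratic_contrast_equals_t_squared(self):
        conds = ["c1", "c2", "c3"]
        res = rm_anova_quadratic(long_table(self.TOY, conds), conds)
        w = quadratic_weights(3)
        scores = self.TOY @ w
        t = stats.ttest_1samp(scores, 0.0)
        assert np.isclose(res.quad_f, t.statistic**2, rtol=1e-12)
        assert np.isclose(res.quad_p, t.pvalue, rtol=1e-12)

    def test_missing_cells_rejected(self):
        conds = ["c1", "c2", "c3"]
        tab = long_table(self.TOY, conds).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_quadratic(tab, conds)

    def test_detects_middle_dip(self, cohort_meta):
        table = synth_ratings(cohort_meta,
                              EffectSpec(condition_profile={"-2": -0.3}, seed=9),
                              n_participants=20, design="study2A")
        res = rm_anova_quadratic(table[table.condition != "grey"],
                                 ["-4", "-3", "-2", "-1", "0"])
        assert res.quad_p < 0.01
        assert res.condition_means["-2"] == res.condition_means.min()


class TestQuadraticWeightsAndEpsilon:
    def test_k5_integer_weights(self):
        assert np.array_equal(quadratic_weights(5),
                              np.array([2.0, -1.0, -2.0, -1.0, 2.0]))

    @given(k=st.integers(3, 8))
    @settings(max_examples=6, deadline=None)
    def test_orthogonality(self, k):
        w = quadratic_weights(k)
        x = np.arange(k) - (k - 1) / 2
        assert abs(w.sum()) < 1e-9
        assert abs(w @ x) < 1e-9

    def test_epsilon_exact_one_for_two_conditions(self, rng):
        data = rng.normal(size=(12, 2))
        assert gg_epsilon(data) == 1.0

    @given(seed=st.integers(0, 10_000), k=st.integers(3, 6))
    @settings(max_examples=20, deadline=None)
    def test_epsilon_bounds(self, seed, k):
        data = np.random.default_rng(seed).normal(size=(10, k))
        eps = gg_epsilon(data)
        assert 1.0 / (k - 1) <= eps <= 1.0


def make_trials(rows):
    return pd.DataFrame(rows, columns=["participant_id", "category_left",
                                       "category_right", "chosen_side"])


class TestChoiceTally:
    def test_all_left_chosen(self):
        trials = make_trials([
            ("p0", "steep", "original", "left"),
            ("p0", "original", "shallow", "left"),
            ("p0", "shallow", "steep", "left"),
        ] * 4)
        res = choice_tally(trials)
        assert res.counts["steep"] == 4 and res.counts["original"] == 4
        assert np.isclose(res.percent.sum(), 100.0)

    def test_conditional_percentages_sum_to_100(self, cohort_meta):
        trials = synth_ratings(cohort_meta,
                               EffectSpec(condition_profile={"steep": -0.2},
                                          seed=10),
                               n_participants=8, design="study2B")
        res = choice_tally(trials)
        for a in res.conditional.index:
            for b in res.conditional.columns:
                if a != b:
                    assert np.isclose(res.conditional.loc[a, b]
                                      + res.conditional.loc[b, a], 100.0)

    def test_penalized_category_chosen_least(self, cohort_meta):
        trials = synth_ratings(cohort_meta,
                               EffectSpec(condition_profile={"steep": -0.2},
                                          seed=11),
                               n_participants=10, design="study2B")
        res = choice_tally(trials)
        assert res.percent.idxmin() == "steep"

    def test_same_category_pairing_rejected(self):
        with pytest.raises(ValueError):
            choice_tally(make_trials([("p0", "steep", "steep", "left")]))

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            choice_tally(make_trials([("p0", "steep", "original", "middle")]))


class TestRankTests:
    def test_identical_columns_chi2_zero(self):
        """Fully tied ranks carry no information: chi2 = 0."""
        m = pd.DataFrame(np.tile(np.arange(6.0)[:, None], (1, 3)),
                         columns=list("abc"))
        res = rank_tests(m)
        assert res.friedman_chi2 == 0.0 and res.p == 1.0

    def test_friedman_matches_rank_formula(self, rng):
        """Hand-rolled Friedman statistic from within-row ranks."""
        data = rng.normal(size=(8, 4))
        m = pd.DataFrame(data, columns=list("abcd"))
        res = rank_tests(m)
        ranks = stats.rankdata(data, axis=1)
        n, k = data.shape
        rj = ranks.sum(axis=0)
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        assert np.isclose(res.friedman_chi2, chi2, rtol=1e-10)
        assert res.df == 3

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=10, deadline=None)
    def test_monotone_invariance(self, seed):
        """Friedman uses ranks only: exp() of the scores changes nothing."""
        data = np.random.default_rng(seed).normal(size=(7, 3))
        a = rank_tests(pd.DataFrame(data, columns=list("xyz")))
        b = rank_tests(pd.DataFrame(np.exp(data), columns=list("xyz")))
        assert np.isclose(a.friedman_chi2, b.friedman_chi2, rtol=1e-10)

    def test_sign_test_exact_small_n(self, rng):
        data = rng.normal(size=(10, 3))
        data[:, 0] += 2.0
        m = pd.DataFrame(data, columns=list("abc"))
        res = rank_tests(m)
        d = data[:, 0] - data[:, 1]
        pos = int((d > 0).sum())
        expected = stats.binomtest(pos, len(d), 0.5).pvalue
        assert np.isclose(res.sign.loc["a", ("p", "b")], expected)

    def test_missing_cells_rejected(self):
        m = pd.DataFrame(np.ones((6, 3)), columns=list("abc"))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            rank_tests(m)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert np.isclose(pearson_with_p(x, x)[0], 1.0)
        assert np.isclose(pearson_with_p(x, -x)[0], -1.0)

    def test_five_point_hand_example(self):
        """r from the definition on x=(1..5), y=(2,1,4,3,7)."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        r_def = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sqrt(np.sum((x - x.mean()) ** 2)
                           * np.sum((y - y.mean()) ** 2)))
        r, p = pearson_with_p(x, y)
        assert np.isclose(r, r_def, rtol=1e-12)
        t = r_def * np.sqrt(3 / (1 - r_def**2))
        assert np.isclose(p, 2 * stats.t.sf(abs(t), 3), rtol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p(np.ones(5), np.arange(5.0))
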