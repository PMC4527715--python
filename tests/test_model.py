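import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envepi.exceptions import ConfigError, InsufficientReplicationError
from envepi.model import (
    StimulusResponseModel,
    adjust_fdr_bh,
    call_responders,
    fit_feature_model,
    stimulus_de_calls,
)
from conftest import make_matrix


def bh_brute_force(p):
    """Step-up BH by direct definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestFitFeatureModel:
    def test_nine_point_closed_form(self):
        fit = fit_feature_model(
            {"A": [0.9, 1.0, 1.1], "B": [-0.1, 0.0, 0.1], "AB": [0.9, 1.0, 1.1]}
        )
        np.testing.assert_allclose(fit.beta, [1.0, 0.0, 1.0], atol=1e-12)
        # pooled s^2 = 0.06 / 6 = 0.01, se = 0.1/sqrt(3), t_A = sqrt(300)
        np.testing.assert_allclose(fit.se, 0.1 / np.sqrt(3), atol=1e-12)
        np.testing.assert_allclose(fit.beta[0] / fit.se[0], 17.320508, atol=1e-5)
        assert fit.df_resid == 6
        np.testing.assert_allclose(fit.anova_F, 200.0, atol=1e-9)

    def test_all_zero_degenerate(self):
        fit = fit_feature_model({"A": [0, 0, 0], "B": [0, 0, 0], "AB": [0, 0, 0]})
        np.testing.assert_array_equal(fit.beta, 0.0)
        assert fit.anova_p == 1.0
        assert fit.zero_variance

    def test_noiseless_nonzero_convention(self):
        fit = fit_feature_model({"A": [1, 1], "B": [0, 0], "AB": [1, 1]})
        assert fit.zero_variance
        np.testing.assert_array_equal(fit.coef_p, [0.0, 1.0, 0.0])
        assert fit.anova_p == 0.0

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            fit_feature_model({"A": [1.0], "B": [0, 0], "AB": [1, 1]})

    def test_unbalanced_df(self, rng):
        fit = fit_feature_model(
            {"A": rng.normal(size=3), "B": rng.normal(size=4),
             "AB": rng.normal(size=3)}
        )
        assert fit.df_resid == 10 - 3

    def test_equals_generic_least_squares(self, rng):
        """Cell-means fit == saturated main-effects+interaction OLS fit."""
        import statsmodels.api as sm

        for _ in range(25):
            n_c = rng.integers(2, 6, size=3)
            groups = {
                c: rng.normal(rng.uniform(-2, 2), 0.3, size=n)
                for c, n in zip(("A", "B", "AB"), n_c)
            }
            fit = fit_feature_model(groups)
            # design: intercept + a + b + a*b over the three test conditions
            y = np.concatenate([groups["A"], groups["B"], groups["AB"]])
            a = np.concatenate(
                [np.ones(n_c[0]), np.zeros(n_c[1]), np.ones(n_c[2])]
            )
            b = np.concatenate(
                [np.zeros(n_c[0]), np.ones(n_c[1]), np.ones(n_c[2])]
            )
            X = np.column_stack([np.ones_like(y), a, b, a * b])
            pred = X @ np.linalg.lstsq(X, y, rcond=None)[0]
            np.testing.assert_allclose(
                pred[: n_c[0]], fit.beta[0], atol=1e-10
            )
            np.testing.assert_allclose(
                pred[n_c[0]: n_c[0] + n_c[1]], fit.beta[1], atol=1e-10
            )
            np.testing.assert_allclose(pred[-n_c[2]:], fit.beta[2], atol=1e-10)
            # no-intercept cell-means OLS agrees on se, t, p and F
            D = np.column_stack([a * (1 - b), b * (1 - a), a * b])
            ols = sm.OLS(y, D).fit()
            np.testing.assert_allclose(ols.params, fit.beta, atol=1e-10)
            np.testing.assert_allclose(ols.bse, fit.se, atol=1e-10)
            np.testing.assert_allclose(ols.pvalues, fit.coef_p, atol=1e-10)
            joint = ols.f_test(np.eye(3))  # all three condition means zero
            np.testing.assert_allclose(
                float(joint.fvalue), fit.anova_F, rtol=1e-10
            )
            np.testing.assert_allclose(
                float(joint.pvalue), fit.anova_p, atol=1e-12
            )


class TestBH:
    def test_four_rank_example(self):
        np.testing.assert_allclose(
            adjust_fdr_bh([0.005, 0.01, 0.03, 0.04]),
            [0.02, 0.02, 0.04, 0.04],
            atol=1e-12,
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr_bh([0.03]), [0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(adjust_fdr_bh([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            adjust_fdr_bh([0.5, 1.5])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=20)
    )
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(
            adjust_fdr_bh(pvals), bh_brute_force(pvals), atol=1e-12
        )

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=50)
        q = adjust_fdr_bh(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestResponderCalls:
    def test_threshold_and_boundary(self):
        resp, counts = call_responders(np.array([0.01, 0.06, 0.05]))
        np.testing.assert_array_equal(resp, [True, False, True])  # q<=0.05
        assert counts == {"responders": 2, "non_responders": 1}

    def test_missing_q_rejected(self):
        with pytest.raises(ConfigError):
            call_responders(np.array([0.01, np.nan]))

    def test_de_gated_by_responder(self):
        coef_p = np.array([[0.01, 0.2, 0.03], [0.001, 0.001, 0.001]])
        de, totals = stimulus_de_calls(coef_p, np.array([True, False]))
        np.testing.assert_array_equal(de[0], [True, False, True])
        assert not de[1].any()  # non-responder: all false despite tiny p
        assert totals == {"A": 1, "B": 0, "AB": 1}


class TestStimulusResponseModel:
    def test_fit_shapes_and_summary(self, nine_point_matrix):
        res = StimulusResponseModel(nine_point_matrix).fit()
        assert len(res.fits) == 1
        assert "Stimulus-response factorial model" in res.summary()
        tables = res.tables()
        assert set(tables) == {
            "feature_models", "interaction_classes", "epistasis", "summary_counts"
        }

    def test_unbalanced_matrix_fits(self, rng):
        m = make_matrix(
            {"A": rng.normal(size=(6, 3)), "B": rng.normal(size=(6, 4)),
             "AB": rng.normal(size=(6, 3))}
        )
        res = StimulusResponseModel(m).fit()
        assert all(f.df_resid == 7 for f in res.fits)

    def test_null_anova_rate(self):
        """With all true means 0, ~5% of raw overall p-values fall under 0.05."""
        from envepi.simulate import simulate_additive_null

        m, _ = simulate_additive_null(10_000, 0.2, 3, seed=5,
                                      effect_range=(0, 0))
        res = StimulusResponseModel(m).fit()
        frac = np.mean([f.anova_p < 0.05 for f in res.fits])
        assert abs(frac - 0.05) < 0.01
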