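"""Likelihood building blocks and posterior behaviour of the GLMM engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from igc_induction import (
    BernoulliGLMM,
    OrdinalGLMM,
    PosteriorResult,
    bernoulli_loglik,
    monotonic_transform,
    ordinal_likelihood,
)
from igc_induction.errors import DataError
from igc_induction.glmm import _softmax_anchor


class TestMonotonicTransform:
    def test_endpoints_for_any_simplex(self, rng):
        for _ in range(20):
            zeta = rng.dirichlet(np.ones(4))
            assert monotonic_transform(0, zeta) == 0.0
            assert monotonic_transform(4, zeta) == pytest.approx(4.0, abs=1e-9)

    def test_all_effect_at_first_step(self):
        zeta = (1.0, 0.0, 0.0, 0.0)
        assert monotonic_transform(1, zeta) == pytest.approx(4.0)
        assert monotonic_transform(4, zeta) == pytest.approx(4.0)

    def test_uniform_simplex_contribution(self):
        # beta_mo = 0.5, D = 4, level 2, uniform increments -> 0.5 * 4 * 0.5 = 1
        zeta = (0.25, 0.25, 0.25, 0.25)
        assert 0.5 * monotonic_transform(2, zeta) == pytest.approx(1.0)

    def test_nondecreasing_in_level(self, rng):
        zeta = rng.dirichlet(np.ones(5))
        vals = [monotonic_transform(x, zeta) for x in range(6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_negative_simplex_entry_rejected(self):
        with pytest.raises(DataError):
            monotonic_transform(1, [-0.1, 0.6, 0.5])

    def test_d_equal_one_degenerates_to_dummy(self):
        assert monotonic_transform(0, [1.0]) == 0.0
        assert monotonic_transform(1, [1.0]) == 1.0


class TestOrdinalLikelihood:
    def test_quartile_thresholds_give_equal_categories(self):
        tau = [logit(0.25), logit(0.5), logit(0.75)]
        for k in range(1, 5):
            assert ordinal_likelihood(k, 0.0, tau) == pytest.approx(0.25, abs=1e-12)

    def test_large_eta_concentrates_top_category(self):
        tau = [-1.0, 0.0, 1.0]
        assert ordinal_likelihood(4, 40.0, tau) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(eta=st.floats(-20, 20),
           gaps=st.lists(st.floats(0.05, 3), min_size=1, max_size=6),
           t0=st.floats(-5, 5))
    def test_category_probabilities_sum_to_one(self, eta, gaps, t0):
        tau = t0 + np.concatenate([[0], np.cumsum(gaps)])
        total = sum(ordinal_likelihood(k, eta, tau) for k in range(1, len(tau) + 2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(DataError):
            ordinal_likelihood(1, 0.0, [1.0, 0.5])


def _single_draw_result(model, theta):
    return PosteriorResult(model, np.asarray(theta, float)[None, None, :])


class TestLinearPredictor:
    def _panel(self):
        return pd.DataFrame({
            "x1": [2.0, 0.0], "x2": [3.0, 1.0], "y": [1, 0],
            "lev": [2, 0], "g": ["a", "b"],
        })

    def test_zero_parameters_give_zero_eta(self):
        m = BernoulliGLMM(self._panel(), "y", fixed=("x1", "x2"),
                          interactions=(("x1", "x2"),), monotonic=(("lev", 4),),
                          random_intercepts=("g",))
        theta = np.zeros(m.logdensity.dim)
        eta = _single_draw_result(m, theta).linear_predictor("conditional")
        np.testing.assert_allclose(eta, 0.0)

    def test_pure_interaction_term(self):
        m = BernoulliGLMM(self._panel(), "y", fixed=("x1", "x2"),
                          interactions=(("x1", "x2"),))
        theta = np.zeros(m.logdensity.dim)
        theta[m.design.xnames.index("x1:x2")] = 1.0
        eta = _single_draw_result(m, theta).linear_predictor()[0]
        assert eta[0] == pytest.approx(6.0)  # x1=2, x2=3
        assert eta[1] == pytest.approx(0.0)

    def test_monotonic_contribution_with_uniform_simplex(self):
        m = BernoulliGLMM(self._panel(), "y", fixed=("x1",), monotonic=(("lev", 4),))
        lay = m.logdensity.lay
        theta = np.zeros(m.logdensity.dim)
        theta[lay["beta_mo"]] = 0.5
        # u = 0 -> anchored softmax gives the uniform simplex
        eta = _single_draw_result(m, theta).linear_predictor()[0]
        assert eta[0] == pytest.approx(1.0)  # 0.5 * 4 * (1/4 + 1/4)
        assert eta[1] == pytest.approx(0.0)

    def test_unseen_factor_level_predicts_with_zero_intercept(self):
        m = BernoulliGLMM(self._panel(), "y", fixed=("x1",), random_intercepts=("g",))
        lay = m.logdensity.lay
        theta = np.zeros(m.logdensity.dim)
        theta[lay["z_g"]] = [2.0, -2.0]
        theta[lay["logsd_g"]] = 0.0
        new = pd.DataFrame({"x1": [0.0], "g": ["unseen"]})
        with pytest.warns(UserWarning, match="unseen"):
            eta = _single_draw_result(m, theta).linear_predictor("conditional", panel=new)
        assert eta[0, 0] == pytest.approx(0.0)


class TestLoglikOracle:
    def test_bernoulli_loglik_matches_naive_per_row_sum(self, rng):
        """Full-model log likelihood vs an independent pure-python evaluation."""
        n = 100
        panel = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "lev": rng.integers(0, 4, n), "g": rng.choice(list("abcd"), n),
            "y": rng.integers(0, 2, n),
        })
        m = BernoulliGLMM(panel, "y", fixed=("x1", "x2"), interactions=(("x1", "x2"),),
                          monotonic=(("lev", 3),), random_intercepts=("g",))
        theta = rng.normal(size=m.logdensity.dim)
        lay = m.logdensity.lay
        beta = theta[lay["beta"]]
        bmo = theta[lay["beta_mo"]][0]
        zeta = _softmax_anchor(theta[lay["u_lev"]])
        sd = float(np.exp(theta[lay["logsd_g"]][0]))
        z = theta[lay["z_g"]]
        glabels = list(pd.factorize(panel["g"])[1])
        total = 0.0
        for _, row in panel.iterrows():
            eta = beta[0] + beta[1] * row.x1 + beta[2] * row.x2 + beta[3] * row.x1 * row.x2
            eta += bmo * 3 * sum(zeta[: int(row.lev)])
            eta += sd * z[glabels.index(row.g)]
            p = 1 / (1 + np.exp(-eta))
            total += np.log(p) if row.y else np.log(1 - p)
        assert m.loglik(theta) == pytest.approx(total, abs=1e-10)

    def test_bernoulli_loglik_helper(self):
        assert bernoulli_loglik([1, 0], [0.0, 0.0]) == pytest.approx(2 * np.log(0.5))


class TestFitting:
    def test_intercept_only_posterior_matches_conjugate_oracle(self, rng):
        """p ~ 60 % at n = 1000: posterior mean of expit(intercept) near 0.6."""
        y = (rng.random(1000) < 0.6).astype(int)
        panel = pd.DataFrame({"y": y})
        m = BernoulliGLMM(panel, "y")
        res = m.fit(seed=0, chains=2, iterations=600)
        p_post = expit(res.draws_flat("b_Intercept")).mean()
        assert p_post == pytest.approx(y.mean(), abs=0.04)

    def test_ordinal_with_two_categories_matches_bernoulli(self, rng):
        """K = 2 cumulative model reproduces the Bernoulli posterior."""
        n = 400
        x = rng.normal(size=n)
        p = expit(-0.4 + 0.9 * x)
        y = (rng.random(n) < p).astype(int)
        panel = pd.DataFrame({"x": x, "yb": y, "yo": y + 1})
        mb = BernoulliGLMM(panel, "yb", fixed=("x",))
        mo = OrdinalGLMM(panel, "yo", n_categories=2, fixed=("x",),
                         prior_scale_threshold=1.0)
        rb = mb.fit(seed=1, chains=2, iterations=600)
        ro = mo.fit(seed=2, chains=2, iterations=600)
        slope_b = rb.draws_flat("b_x").mean()
        slope_o = ro.draws_flat("b_x").mean()
        assert slope_o == pytest.approx(slope_b, abs=0.12)
        # P(Y=2) = expit(eta - tau1) <-> intercept = -tau1
        int_b = rb.draws_flat("b_Intercept").mean()
        tau_o = ro.draws_flat("tau[1]").mean()
        assert -tau_o == pytest.approx(int_b, abs=0.12)
        pb = rb.fitted_probability("marginal").mean(axis=0)
        po = ro.category_probabilities("marginal").mean(axis=0)[:, 1]
        assert np.max(np.abs(pb - po)) < 0.03

    def test_monotonic_d1_equals_binary_dummy(self, rng):
        n = 400
        b = rng.integers(0, 2, n)
        p = expit(-0.2 + 0.8 * b)
        y = (rng.random(n) < p).astype(int)
        panel = pd.DataFrame({"b": b.astype(float), "lev": b, "y": y})
        m_dummy = BernoulliGLMM(panel, "y", fixed=("b",))
        m_mono = BernoulliGLMM(panel, "y", monotonic=(("lev", 1),))
        r1 = m_dummy.fit(seed=3, chains=2, iterations=600)
        r2 = m_mono.fit(seed=4, chains=2, iterations=600)
        assert r2.draws_flat("bmo_lev").mean() == pytest.approx(
            r1.draws_flat("b_b").mean(), abs=0.12)

    def test_zero_sd_random_factor_leaves_fitted_probabilities_unchanged(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.7 * x)).astype(int)
        panel = pd.DataFrame({"x": x, "y": y, "g": rng.choice(list("abcdef"), n)})
        with_re = BernoulliGLMM(panel, "y", fixed=("x",), random_intercepts=("g",))
        without = BernoulliGLMM(panel, "y", fixed=("x",))
        p1 = with_re.fit(seed=5, chains=2, iterations=600).fitted_probability(
            "conditional").mean(axis=0)
        p2 = without.fit(seed=6, chains=2, iterations=600).fitted_probability(
            "conditional").mean(axis=0)
        # half-normal shrinkage leaves a little posterior mass above 0
        assert np.mean(np.abs(p1 - p2)) < 0.03

    def test_constant_covariate_dropped_with_warning(self):
        panel = pd.DataFrame({"x": [1.0] * 10, "y": [0, 1] * 5})
        with pytest.warns(UserWarning, match="constant"):
            m = BernoulliGLMM(panel, "y", fixed=("x",))
        assert "x" not in m.design.xnames

    def test_summary_reports_rhat_for_every_parameter(self, small_panel):
        sub = small_panel.head(200)
        m = BernoulliGLMM(sub, "participation", fixed=("age", "rank"),
                          random_intercepts=("focal_group",))
        res = m.fit(seed=7, chains=2, iterations=400)
        s = res.summary()
        assert set(s.index) == set(res.parameter_names)
        assert s["rhat"].notna().all()
        assert (s["ess"] > 0).all()
        assert s["pd"].between(0.5, 1).all()
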