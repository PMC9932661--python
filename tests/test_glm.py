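"""Gamma-family GLM: fitting, family selection, intervals, coverage."""

import numpy as np
import pytest
import scipy.stats

from drpred import (
    fit_glm,
    picp,
    prediction_interval,
    prediction_intervals,
    select_family_by_aic,
    simulate_dataset,
)


def _simulate_glm(n, beta, intercept, shape_k, seed, n_features=5):
    """Gamma GLM data with log link and known coefficients."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_features))
    eta = intercept + x[:, : len(beta)] @ np.asarray(beta)
    mu = np.exp(eta)
    y = rng.gamma(shape=shape_k, scale=mu / shape_k)
    return x, y, mu


class TestFitGLM:
    def test_intercept_only_gamma_mean_is_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(3.0, 2.0, size=200)
        fit = fit_glm(np.empty((200, 0)), y, family="gamma")
        assert np.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_beta_recovery_within_three_mc_standard_errors(self):
        """n=2000, shape 5: IRLS recovers the generating coefficients."""
        beta_true = [0.5, -0.4, 0.3]
        x, y, _ = _simulate_glm(2000, beta_true, intercept=1.0, shape_k=5.0, seed=1)
        fit = fit_glm(x, y, family="gamma")
        # asymptotic se for gamma GLM with log link: sqrt(1/(k n)) per unit-var column
        se = np.sqrt(1.0 / (5.0 * 2000))
        for b_hat, b in zip(fit.beta[1:4], beta_true):
            assert abs(b_hat - b) < 3 * se * 1.5  # conservative design-factor slack
        assert fit.shape_k == pytest.approx(5.0, rel=0.2)
        assert fit.converged

    def test_exponential_is_gamma_at_shape_one(self):
        """Nesting identity: same beta, loglik_exp = gamma loglik at k=1."""
        x, y, _ = _simulate_glm(300, [0.5], intercept=0.5, shape_k=1.0, seed=2)
        fit_exp = fit_glm(x, y, family="exponential")
        fit_gam = fit_glm(x, y, family="gamma")
        assert fit_exp.shape_k == 1.0
        assert fit_exp.beta == pytest.approx(fit_gam.beta, abs=1e-6)
        mu = fit_exp.predict_mu(x)
        ll_k1 = scipy.stats.gamma.logpdf(y, a=1.0, scale=mu).sum()
        assert fit_exp.loglik == pytest.approx(ll_k1, abs=1e-8)

    def test_aic_counts_estimated_shape(self):
        x, y, _ = _simulate_glm(200, [0.5], intercept=0.5, shape_k=5.0, seed=3,
                                n_features=1)
        fit_exp = fit_glm(x, y, family="exponential")
        fit_gam = fit_glm(x, y, family="gamma")
        assert fit_exp.aic == pytest.approx(2 * 2 - 2 * fit_exp.loglik)
        assert fit_gam.aic == pytest.approx(2 * 3 - 2 * fit_gam.loglik)

    def test_nonpositive_response_named(self):
        x = np.random.default_rng(4).normal(size=(5, 2))
        y = np.array([1.0, -2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="positive"):
            fit_glm(x, y, family="gamma")

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=100)
        x = np.column_stack([col, col])
        y = np.exp(col) + 1.0
        with pytest.raises(ValueError, match="rank"):
            fit_glm(x, y, family="gamma")

    def test_irls_bitwise_deterministic(self):
        x, y, _ = _simulate_glm(300, [0.4], intercept=1.0, shape_k=5.0, seed=6)
        a = fit_glm(x, y, family="gamma")
        b = fit_glm(x, y, family="gamma")
        assert np.array_equal(a.beta, b.beta)
        assert a.loglik == b.loglik


class TestFamilySelection:
    def test_gamma_data_selects_gamma(self):
        """Data from gamma with k=5, n=1000: gamma chosen in >= 80% of reps."""
        wins = 0
        n_reps = 10
        for seed in range(n_reps):
            x, y, _ = _simulate_glm(1000, [0.5, -0.3], intercept=1.0,
                                    shape_k=5.0, seed=100 + seed)
            fit = select_family_by_aic(x, y)
            if fit.family == "gamma":
                wins += 1
        assert wins >= 0.8 * n_reps

    def test_exponential_data_yields_nested_aic(self):
        """Data from k=1: exponential or gamma chosen, AICs within ~2."""
        ok = 0
        n_reps = 10
        for seed in range(n_reps):
            x, y, _ = _simulate_glm(1000, [0.5], intercept=1.0,
                                    shape_k=1.0, seed=200 + seed)
            fit = select_family_by_aic(x, y, candidates=("exponential", "gamma"))
            if fit.family in ("exponential", "gamma") and (
                abs(fit.all_aic["exponential"] - fit.all_aic["gamma"]) < 4.0
            ):
                ok += 1
        assert ok >= 0.9 * n_reps

    def test_single_candidate_returned_unconditionally(self):
        x, y, _ = _simulate_glm(100, [0.5], intercept=1.0, shape_k=5.0, seed=7)
        fit = select_family_by_aic(x, y, candidates=("gamma",))
        assert fit.family == "gamma"

    def test_noise_column_aic_penalty(self):
        """Adding a pure-noise column does not drop AIC by more than ~2
        on average over replicates."""
        deltas = []
        for seed in range(30):
            rng = np.random.default_rng(300 + seed)
            x, y, _ = _simulate_glm(300, [0.5], intercept=1.0, shape_k=5.0,
                                    seed=301 + seed, n_features=1)
            noise = rng.normal(size=(300, 1))
            aic0 = fit_glm(x, y, family="gamma").aic
            aic1 = fit_glm(np.column_stack([x, noise]), y, family="gamma").aic
            deltas.append(aic0 - aic1)
        assert np.mean(deltas) < 2.0


@pytest.fixture(scope="module")
def gamma_fit():
    x, y, _ = _simulate_glm(500, [0.5, -0.3], intercept=1.0, shape_k=5.0, seed=8)
    return fit_glm(x, y, family="gamma"), x


class TestPredictionIntervals:
    def test_exponential_closed_form_bounds(self):
        x, y, _ = _simulate_glm(400, [0.5], intercept=1.0, shape_k=1.0, seed=9)
        fit = fit_glm(x, y, family="exponential")
        row = np.zeros(x.shape[1])
        iv = prediction_interval(fit, row, level=0.95)
        mu = float(fit.predict_mu(row[None, :])[0])
        assert iv.lower == pytest.approx(-mu * np.log(0.975), rel=1e-10)
        assert iv.upper == pytest.approx(-mu * np.log(0.025), rel=1e-10)

    def test_bounds_match_cdf_bisection_oracle(self):
        """k=5, mu=2: quantiles agree with bisection on the gamma CDF."""
        from drpred.glm import GLMFit

        fit = GLMFit(
            family="gamma", link="log", beta=np.array([np.log(2.0)]),
            feature_ids=[], shape_k=5.0, loglik=0.0, aic=0.0,
            converged=True, iterations=1,
        )
        iv = prediction_interval(fit, np.empty(0), level=0.95)

        def cdf(x):
            return scipy.stats.gamma.cdf(x, a=5.0, scale=2.0 / 5.0)

        for target, bound in ((0.025, iv.lower), (0.975, iv.upper)):
            lo, hi = 1e-9, 50.0
            for _ in range(200):
                mid = (lo + hi) / 2
                if cdf(mid) < target:
                    lo = mid
                else:
                    hi = mid
            assert bound == pytest.approx((lo + hi) / 2, rel=1e-6)

    def test_width_increases_with_level(self, gamma_fit):
        fit, x = gamma_fit
        widths = []
        for level in (0.5, 0.8, 0.95, 0.99):
            iv = prediction_interval(fit, x[0], level=level)
            widths.append(iv.width)
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_level_limits(self, gamma_fit):
        """As level -> 1 the interval approaches the full (0, inf) support."""
        fit, x = gamma_fit
        iv95 = prediction_interval(fit, x[0], level=0.95)
        iv_hi = prediction_interval(fit, x[0], level=1 - 1e-10)
        assert iv_hi.lower < 0.2 * iv95.lower
        assert iv_hi.upper > 2.0 * iv95.upper
        with pytest.raises(ValueError):
            prediction_interval(fit, x[0], level=1.0)

    def test_coverage_on_correctly_specified_simulation(self):
        """PICP at 95% on held-out data: within ~3 binomial SEs of 0.95."""
        x_tr, y_tr, _ = _simulate_glm(500, [0.5, -0.3], 1.0, 5.0, seed=10)
        fit = fit_glm(x_tr, y_tr, family="gamma")
        rng = np.random.default_rng(11)
        x_te = rng.standard_normal((500, 5))
        mu_te = np.exp(1.0 + x_te[:, :2] @ np.array([0.5, -0.3]))
        y_te = rng.gamma(5.0, mu_te / 5.0)
        _, lo, hi = prediction_intervals(fit, x_te, level=0.95)
        cov = picp((lo, hi), y_te)
        assert cov == pytest.approx(0.95, abs=0.03)

    def test_coverage_calibrated_across_levels(self):
        """PICP tracks the nominal level at 0.5, 0.8 and 0.95."""
        x_tr, y_tr, _ = _simulate_glm(800, [0.5], 1.0, 5.0, seed=12, n_features=2)
        fit = fit_glm(x_tr, y_tr, family="gamma")
        rng = np.random.default_rng(13)
        x_te = rng.standard_normal((800, 2))
        mu_te = np.exp(1.0 + 0.5 * x_te[:, 0])
        y_te = rng.gamma(5.0, mu_te / 5.0)
        for level in (0.5, 0.8, 0.95):
            _, lo, hi = prediction_intervals(fit, x_te, level=level)
            se = np.sqrt(level * (1 - level) / 800)
            assert abs(picp((lo, hi), y_te) - level) < 3 * se + 0.01


class TestPICP:
    def test_full_support_intervals_cover_everything(self):
        y = np.array([0.1, 5.0, 100.0])
        assert picp((np.zeros(3), np.full(3, np.inf)), y) == 1.0

    def test_empty_intervals_cover_nothing(self):
        y = np.array([1.0, 2.0])
        assert picp((np.full(2, 10.0), np.full(2, 11.0)), y) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            picp((np.array([]), np.array([])), np.array([]))
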