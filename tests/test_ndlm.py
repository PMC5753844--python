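"""NDLM sampler: oracle equivalence, parameter recovery, posterior summaries."""

import numpy as np
import pytest

from doseadapt import (
    DoseData,
    MCMCSettings,
    PosteriorFit,
    ed95_index,
    estimate_ed95,
    fit_ndlm,
    prob_efficacy,
    response_posterior_at,
)
from conftest import SHORT_MCMC, make_dose_data


def exact_state_posterior(y, arm, J, s2, W, v0=1e4):
    """Closed-form Gaussian posterior of the NDLM states with fixed variances.

    Builds the joint state prior by propagating the evolution recursion
    through a linear map of iid standard normals, then conditions on the
    observations by direct linear algebra.  Independent of the sampler.
    """
    q = W * s2
    G = np.array([[1.0, 1.0], [0.0, 1.0]])
    nstate = 2 * (J + 1)
    A = np.zeros((nstate, nstate))
    A[0:2, 0:2] = np.sqrt(v0) * np.eye(2)
    for k in range(1, J + 1):
        A[2 * k : 2 * k + 2, :] = G @ A[2 * (k - 1) : 2 * k, :]
        A[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] += np.sqrt(q) * np.eye(2)
    Sig = A @ A.T
    H = np.zeros((len(y), nstate))
    for i, a in enumerate(arm):
        H[i, 2 * (a + 1)] = 1.0
    post_cov = np.linalg.inv(np.linalg.inv(Sig) + H.T @ H / s2)
    post_mean = post_cov @ (H.T @ y / s2)
    theta_ix = [2 * (k + 1) for k in range(J)]
    return post_mean[theta_ix], post_cov[np.ix_(theta_ix, theta_ix)]


def _toy_data(seed=7):
    g = np.random.default_rng(seed)
    arm = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 1, 0])
    y = np.array([0.0, 2.0, -1.0, 5.0, 7.0, 6.0, 9.0, 11.0, 10.0, 8.0, 6.0, 1.0])
    y = y + 0.5 * g.normal(size=arm.size)
    return DoseData(y=y, ybl=np.full(arm.size, 80.0), arm=arm, dose_grid=(0.4, 0.8))


class TestSamplerOracles:
    @pytest.mark.parametrize("w_val", [0.001, 0.5])
    def test_fixed_variance_draws_match_exact_gaussian(self, w_val):
        """With variances fixed, FFBS draws are exact Gaussian conditionals."""
        data = _toy_data()
        s2 = 4.0
        fit = fit_ndlm(
            data,
            mcmc=MCMCSettings(20000, 100),
            seed=3,
            fix_sigma_nu=np.sqrt(s2),
            fix_w=w_val,
            fix_beta=0.0,
        )
        mean, cov = exact_state_posterior(data.y, data.arm, 3, s2, w_val)
        sd = np.sqrt(np.diag(cov))
        assert np.allclose(fit.theta.mean(axis=0), mean, atol=4 * sd.max() / np.sqrt(20000) + 0.05)
        assert np.allclose(fit.theta.std(axis=0), sd, rtol=0.05)
        # one off-diagonal element of the posterior covariance
        assert np.cov(fit.theta[:, 0], fit.theta[:, 2])[0, 1] == pytest.approx(
            cov[0, 2], abs=0.06
        )

    def test_small_w_limit_approaches_straight_line(self):
        """W at its lower bound collapses the fit to a line in dose index."""
        data = make_dose_data(10, theta=np.array([0.0, 3.0, 9.0, 10.0]), seed=5)
        fit = fit_ndlm(
            data, mcmc=SHORT_MCMC, seed=2, fix_w=0.001, fix_sigma_nu=17.9, fix_beta=0.0
        )
        tm = fit.theta.mean(axis=0)
        curvature = np.diff(tm, 2)
        assert np.all(np.abs(curvature) < 0.5)

    def test_beta_recovery_on_synthetic_data(self):
        """Posterior for the baseline coefficient covers its true value 0.5."""
        data = make_dose_data(
            500, theta=np.array([0.0, 8.0, 12.0, 16.0]), beta=0.5, seed=8
        )
        fit = fit_ndlm(data, mcmc=MCMCSettings(2000, 1000), seed=4)
        lo, hi = np.quantile(fit.beta, [0.025, 0.975])
        assert lo < 0.5 < hi
        assert fit.beta.mean() == pytest.approx(0.5, abs=0.1)

    def test_sigma_nu_recovery(self):
        data = make_dose_data(100, theta=np.zeros(4), sigma=17.9, seed=9)
        fit = fit_ndlm(data, mcmc=MCMCSettings(2000, 1000), seed=5)
        assert np.sqrt(fit.sigma2_nu.mean()) == pytest.approx(17.9, rel=0.15)


class TestFitBehaviour:
    def test_empty_arm_is_informed_by_neighbours(self):
        g = np.random.default_rng(3)
        arm = np.repeat([0, 1, 3], 15)  # arm 2 has no subjects
        y = np.array([0.0, 6.0, 0.0, 14.0])[arm] + g.normal(0, 5, arm.size)
        data = DoseData(y=y, ybl=np.full(arm.size, 80.0), arm=arm, dose_grid=(0.4, 0.8, 1.2))
        fit = fit_ndlm(data, mcmc=SHORT_MCMC, seed=6)
        sds = fit.theta.std(axis=0)
        assert sds[2] > sds[1] and sds[2] > sds[3]

    def test_single_level_unidentifiable(self):
        data = DoseData(
            y=np.ones(5), ybl=np.full(5, 80.0), arm=np.zeros(5, int), dose_grid=(0.4,)
        )
        with pytest.raises(ValueError, match="distinct dose levels"):
            fit_ndlm(data)

    def test_non_finite_data_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            DoseData(
                y=np.array([1.0, np.nan]),
                ybl=np.array([80.0, 80.0]),
                arm=np.array([0, 1]),
                dose_grid=(0.4,),
            )

    def test_subject_order_invariance(self):
        """Permuting subject order leaves posterior summaries unchanged (MC error)."""
        data = make_dose_data(25, theta=np.array([0.0, 5.0, 10.0, 12.0]), seed=12)
        perm = np.random.default_rng(0).permutation(data.y.size)
        data_p = DoseData(
            y=data.y[perm], ybl=data.ybl[perm], arm=data.arm[perm], dose_grid=data.dose_grid
        )
        f1 = fit_ndlm(data, mcmc=MCMCSettings(4000, 1000), seed=1)
        f2 = fit_ndlm(data_p, mcmc=MCMCSettings(4000, 1000), seed=2)
        assert np.allclose(f1.gamma_mean(), f2.gamma_mean(), atol=1.0)

    def test_prior_support_respected(self, small_fit):
        fit, _ = small_fit
        assert np.all(fit.W >= 0.001) and np.all(fit.W <= 100.0)
        assert np.all(fit.sigma2_nu > 0)

    def test_split_rhat_converged(self, small_fit):
        fit, _ = small_fit
        assert max(fit.rhat.values()) < 1.1

    def test_posterior_variance_shrinks_with_sample_size(self):
        theta = np.array([0.0, 5.0, 10.0, 12.0])
        var_small = np.mean([
            response_posterior_at(
                fit_ndlm(make_dose_data(8, theta, seed=s), mcmc=SHORT_MCMC, seed=s), 2
            )[1]
            for s in range(4)
        ])
        var_big = np.mean([
            response_posterior_at(
                fit_ndlm(make_dose_data(60, theta, seed=s), mcmc=SHORT_MCMC, seed=s), 2
            )[1]
            for s in range(4)
        ])
        assert var_big < var_small


def _fake_fit(gamma_actives: np.ndarray, dose_grid=(0.4, 0.8, 1.2)) -> PosteriorFit:
    """PosteriorFit with prescribed active-contrast draws (placebo at 0)."""
    n, j = gamma_actives.shape
    theta = np.concatenate([np.zeros((n, 1)), gamma_actives], axis=1)
    return PosteriorFit(
        theta=theta,
        delta=np.zeros_like(theta),
        beta=np.zeros(n),
        sigma2_nu=np.ones(n),
        W=np.ones(n),
        dose_grid=dose_grid,
    )


class TestSummaries:
    def test_prob_efficacy_all_positive(self):
        fit = _fake_fit(np.ones((100, 3)))
        assert prob_efficacy(fit, 1) == 1.0

    def test_prob_efficacy_symmetric_draws(self):
        g = np.random.default_rng(0)
        fit = _fake_fit(g.normal(0, 1, (20000, 3)))
        assert prob_efficacy(fit, 2) == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(20000))

    def test_prob_efficacy_zero_draws_strict(self):
        fit = _fake_fit(np.zeros((50, 3)))
        assert prob_efficacy(fit, 1) == 0.0

    def test_prob_efficacy_placebo_rejected(self):
        fit = _fake_fit(np.ones((10, 3)))
        with pytest.raises(ValueError):
            prob_efficacy(fit, 0)

    @pytest.mark.parametrize(
        "effects, expected",
        [
            ((0.0, 4.0, 9.6, 10.0), 2),   # threshold 9.5 -> third dose
            ((10.0, 10.0, 10.0), 0),      # ties -> smallest dose
            ((-1.0, -3.0, -2.0), 0),      # degenerate: argmax, ties smallest
            ((0.0, 0.0, 0.0), 0),
        ],
    )
    def test_ed95_definition(self, effects, expected):
        assert ed95_index(effects) == expected

    def test_ed95_from_fit_mean_curve(self):
        gam = np.tile(np.array([0.0, 4.0, 9.6, 10.0]), (200, 1))
        fit = _fake_fit(gam, dose_grid=(0.4, 0.8, 1.2, 1.8))
        assert estimate_ed95(fit) == 3  # arm index of 1.2 mg
        per_draw = estimate_ed95(fit, per_draw=True)
        assert np.all(per_draw == 3)

    def test_response_posterior_matches_draws(self):
        g = np.random.default_rng(1)
        gam = g.normal(5, 2, (5000, 3))
        fit = _fake_fit(gam)
        mean, var, draws = response_posterior_at(fit, 2)
        assert mean == pytest.approx(gam[:, 1].mean())
        assert var == pytest.approx(gam[:, 1].var())
        assert draws.shape == (5000,)

    def test_response_posterior_placebo_degenerate(self):
        fit = _fake_fit(np.ones((10, 3)))
        mean, var, draws = response_posterior_at(fit, 0)
        assert mean == 0.0 and var == 0.0 and np.all(draws == 0)
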