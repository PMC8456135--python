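import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import multivariate_normal, norm

from cladelink.evidence import stepping_stone
from cladelink.sde import (
    LinkPriors,
    LinkSDE,
    OUParams,
    alpha_from_halflife,
    compare_models,
    halflife,
    kalman_loglik,
    log_prior,
    marginal_likelihood,
    ou_transition,
    prepare_series,
    sample_posterior,
    sample_prior,
    stationary_cov,
)
from cladelink.series import RateSeries, TimeSeriesObs
from cladelink.synthetic import simulate_linked_series


def biv(mu1=0.0, h1=2.0, s1=1.0, mu2=0.0, h2=3.0, s2=0.5, **kw):
    return OUParams(mu1=mu1, halflife1=h1, s1=s1, mu2=mu2, halflife2=h2,
                    s2=s2, **kw)


class TestHalflife:
    def test_known_values(self):
        assert halflife(np.log(2)) == pytest.approx(1.0)
        assert halflife(np.log(2) / 10) == pytest.approx(10.0)
        assert alpha_from_halflife(halflife(0.3)) == pytest.approx(0.3)

    def test_strictly_decreasing_in_alpha(self):
        alphas = np.linspace(0.01, 5, 50)
        hs = [halflife(a) for a in alphas]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            halflife(0.0)


class TestOUTransition:
    def test_zero_step_is_identity_with_no_dispersion(self):
        phi, c, Q = ou_transition("D", biv(beta12=0.5, beta21=0.3), 0.0)
        assert np.allclose(phi, np.eye(2))
        assert np.allclose(c, 0.0)
        assert np.allclose(Q, 0.0)

    def test_univariate_long_horizon_reaches_the_stationary_law(self):
        p = OUParams(mu1=1.7, halflife1=2.0, s1=0.6)
        phi, c, Q = ou_transition("A", p, 1e4)
        assert phi[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert c[0] == pytest.approx(1.7)
        assert Q[0, 0] == pytest.approx(0.36)

    def test_unstable_feedback_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            ou_transition("D", biv(beta12=1.3, beta21=1.0), 1.0)

    @given(
        hst.floats(0.5, 20), hst.floats(0.5, 20),
        hst.floats(0.1, 2), hst.floats(0.1, 2),
        hst.floats(-0.95, 0.95), hst.floats(-0.95, 0.95),
        hst.floats(0.01, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_dispersion_always_symmetric_psd(self, h1, h2, s1, s2, b12, b21,
                                             dt):
        p = biv(h1=h1, s1=s1, h2=h2, s2=s2, beta12=b12, beta21=b21)
        phi, c, Q = ou_transition("D", p, dt)
        assert np.allclose(Q, Q.T)
        assert np.linalg.eigvalsh(Q).min() > -1e-9


class TestKalman:
    def test_univariate_matches_direct_joint_gaussian(self):
        t = np.array([0.0, 1.3, 2.1, 5.0])
        y = np.array([0.5, -0.2, 0.1, 0.9])
        se = np.array([0.2, 0.3, 0.25, 0.2])
        p = OUParams(mu1=0.3, halflife1=2.0, s1=0.8)
        obs = TimeSeriesObs(times=t, values=y, ses=se)
        # oracle: assemble the joint covariance s^2 e^{-a|ti-tj|} + diag(se^2)
        a = alpha_from_halflife(2.0)
        C = 0.64 * np.exp(-a * np.abs(t[:, None] - t[None, :])) + np.diag(se**2)
        expected = multivariate_normal(mean=np.full(4, 0.3), cov=C).logpdf(y)
        assert kalman_loglik("A", p, obs) == pytest.approx(expected, abs=1e-8)

    def test_model_a_factorizes_into_univariate_likelihoods(self, rng):
        p = biv(mu1=0.3, mu2=-1.0)
        o1 = TimeSeriesObs(times=np.array([0.0, 1.0, 2.5, 4.0]),
                           values=rng.normal(0, 1, 4), ses=np.full(4, 0.2))
        o2 = TimeSeriesObs(times=np.array([0.5, 1.5, 3.3, 4.4, 6.0]),
                           values=rng.normal(-1, 0.5, 5), ses=np.full(5, 0.15))
        ll = kalman_loglik("A", p, o1, o2)
        ll1 = kalman_loglik("A", OUParams(mu1=0.3, halflife1=2.0, s1=1.0), o1)
        ll2 = kalman_loglik("A", OUParams(mu1=-1.0, halflife1=3.0, s1=0.5), o2)
        assert ll == pytest.approx(ll1 + ll2, abs=1e-10)

    def test_bivariate_matches_direct_joint_gaussian_with_partial_obs(self):
        # oracle: build the full joint Gaussian of all observations from the
        # exact transition quantities, including a time where only one
        # component is observed
        p = biv(mu1=0.2, mu2=-0.4, s2=0.8, beta12=0.6)
        kind = "B"
        t_all = np.array([0.0, 1.0, 2.2, 3.1])
        S = stationary_cov(kind, p)
        # joint covariance of the latent states at t_all (2 per time)
        n = t_all.size
        big = np.zeros((2 * n, 2 * n))
        from cladelink.sde import drift_matrix
        from scipy.linalg import expm

        A = drift_matrix(kind, p)
        for i in range(n):
            for j in range(n):
                dt = abs(t_all[i] - t_all[j])
                blk = expm(-A * dt) @ S if t_all[i] >= t_all[j] else (
                    S @ expm(-A * dt).T)
                big[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = blk
        mu = np.tile([p.mu1, p.mu2], n)
        # observe both components except component 2 at time index 2
        keep = [0, 1, 2, 3, 4, 6, 7]
        rng = np.random.default_rng(1)
        se = np.full(len(keep), 0.1)
        y = mu[keep] + rng.normal(0, 0.3, len(keep))
        cov = big[np.ix_(keep, keep)] + np.diag(se**2)
        expected = multivariate_normal(mean=mu[keep], cov=cov).logpdf(y)

        o1 = TimeSeriesObs(times=t_all, values=y[[0, 2, 4, 5]],
                           ses=np.full(4, 0.1))
        o2 = TimeSeriesObs(times=t_all[[0, 1, 3]], values=y[[1, 3, 6]],
                           ses=np.full(3, 0.1))
        assert kalman_loglik(kind, p, o1, o2) == pytest.approx(expected,
                                                               abs=1e-8)

    def test_shift_invariance_of_the_likelihood(self, rng):
        p = biv()
        t = np.sort(rng.uniform(0, 20, 8))
        y = rng.normal(0, 1, 8)
        o1 = TimeSeriesObs(times=t, values=y, ses=np.full(8, 0.2))
        o2 = TimeSeriesObs(times=t, values=rng.normal(0, 1, 8),
                           ses=np.full(8, 0.2))
        ll = kalman_loglik("E", biv(rho=0.4), o1, o2)
        shift = 5.0
        o1s = TimeSeriesObs(times=t, values=y + shift, ses=np.full(8, 0.2))
        lls = kalman_loglik("E", biv(mu1=shift, rho=0.4), o1s, o2)
        assert ll == pytest.approx(lls, abs=1e-10)


class TestPrepareSeries:
    def test_proportion_offset_log_transform(self):
        rs = RateSeries(times=np.array([1.0, 2.0]),
                        values=np.array([0.0, 0.5]),
                        ses=np.array([0.05, 0.05]), label="proportion")
        obs = prepare_series(rs, kind="proportion")
        assert obs.values[0] == pytest.approx(np.log(1e-4))
        assert obs.values[1] == pytest.approx(np.log(0.5001))

    def test_se_propagation_matches_finite_differences(self):
        p0, se_p = 0.3, 0.04
        rs = RateSeries(times=np.array([0.0]), values=np.array([p0]),
                        ses=np.array([se_p]), label="proportion")
        obs = prepare_series(rs, kind="proportion")
        eps = 1e-7
        deriv = (np.log(p0 + eps + 1e-4) - np.log(p0 - eps + 1e-4)) / (2 * eps)
        assert obs.ses[0] == pytest.approx(abs(deriv) * se_p, rel=1e-6)

    def test_rates_pass_through_unchanged(self):
        rs = RateSeries(times=np.array([1.0, 2.0]),
                        values=np.array([-2.0, -2.5]),
                        ses=np.array([0.1, 0.2]), label="c:extinction")
        obs = prepare_series(rs, kind="rate")
        assert np.array_equal(obs.values, rs.values)
        assert np.array_equal(obs.ses, rs.ses)


class TestCompareModels:
    def test_equal_evidences_give_uniform_weights(self):
        comp = compare_models({k: -10.0 for k in "ABCDE"})
        for k in "ABCDE":
            assert comp.probabilities[k] == pytest.approx(0.2)

    def test_printed_percent_ratio_gives_bayes_factor(self):
        # posterior supports 44% and 11.4% -> Bayes factor 3.9 (1 d.p.)
        probs = {"D": 0.44, "A": 0.114, "B": 0.2, "C": 0.1, "E": 0.146}
        logz = {k: np.log(v) for k, v in probs.items()}
        comp = compare_models(logz)
        assert round(comp.bayes_factor("D", "A"), 1) == 3.9

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            comp = compare_models(
                {k: rng.normal(-50, 5) for k in "ABCDE"})
            assert sum(comp.probabilities.values()) == pytest.approx(1.0)
        assert comp.summary().shape[0] == 5


class TestPosterior:
    def make_b_data(self):
        p = biv(h1=5.0, s1=1.0, h2=5.0, s2=1.0, beta12=0.8)
        times = np.arange(300) * 2.0
        return simulate_linked_series("B", p, times, obs_se=0.1, seed=8)

    def test_recovers_a_strong_causal_coupling(self):
        o1, o2 = self.make_b_data()
        res = sample_posterior("B", o1, o2, n_draws=3000, seed=0)
        beta_col = [c for c in res.natural.columns if c.startswith("beta")][0]
        draws = res.natural[beta_col]
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo < 0.8 < hi
        assert abs(draws.mean() - 0.8) < 0.15
        assert res.converged

    def test_two_seeds_agree_within_monte_carlo_error(self):
        o1, o2 = self.make_b_data()
        r1 = sample_posterior("B", o1, o2, n_draws=2000, seed=1)
        r2 = sample_posterior("B", o1, o2, n_draws=2000, seed=2)
        for col in r1.natural.columns:
            d1, d2 = r1.natural[col], r2.natural[col]
            ess = min(min(r1.ess.values()), min(r2.ess.values()))
            mcse = np.sqrt(d1.var() / ess + d2.var() / ess)
            assert abs(d1.mean() - d2.mean()) < 4 * mcse

    def test_prior_only_posterior_matches_prior_moments(self):
        # with no informative data the summaries must reproduce the prior
        rng = np.random.default_rng(0)
        pri = LinkPriors(mu_loc=(0.0, 0.0), mu_scale=(1.0, 1.0),
                         logs_loc=(0.0, 0.0))
        draws = sample_prior("A", pri, rng, 20000)
        # check the declared prior shapes by their analytic moments
        assert abs(draws[:, 0].mean()) < 0.03
        assert draws[:, 0].std() == pytest.approx(1.0, abs=0.03)
        lh = draws[:, 1]
        assert lh.min() >= np.log(0.1) and lh.max() <= np.log(1000)
        assert lh.mean() == pytest.approx(
            (np.log(0.1) + np.log(1000)) / 2, abs=0.05)
        assert np.isfinite(log_prior("A", draws[0], pri))


class TestEvidence:
    def test_conjugate_gaussian_toy_within_tolerance(self):
        rng = np.random.default_rng(0)
        sig, m0, v0 = 1.0, 0.0, 4.0
        y = rng.normal(1.5, sig, 25)

        def log_lik(th):
            return float(np.sum(norm.logpdf(y, th[0], sig)))

        def log_pr(th):
            return float(norm.logpdf(th[0], m0, np.sqrt(v0)))

        C = sig**2 * np.eye(25) + v0 * np.ones((25, 25))
        truth = multivariate_normal(mean=np.full(25, m0), cov=C).logpdf(y)
        est, se = stepping_stone(log_lik, log_pr,
                                 lambda r, m: r.normal(m0, 2.0, (m, 1)),
                                 1, np.random.default_rng(1),
                                 n_rungs=16, n_draws=2000)
        assert est == pytest.approx(truth, abs=0.05)

    def test_model_a_evidence_factorizes(self):
        # bivariate null evidence = product of the two univariate evidences
        p = biv(mu1=0.5, mu2=-0.5)
        times = np.arange(40) * 3.0
        o1, o2 = simulate_linked_series("A", p, times, obs_se=0.2, seed=3)
        pri = LinkPriors.from_obs(o1, o2)
        biv_est, biv_se = marginal_likelihood("A", o1, o2, pri, seed=0,
                                              n_rungs=12, n_draws=2000)

        def uni_evidence(obs, idx, seed):
            pri1 = LinkPriors(mu_loc=(pri.mu_loc[idx],) * 2,
                              mu_scale=(pri.mu_scale[idx],) * 2,
                              logs_loc=(pri.logs_loc[idx],) * 2)

            def ll(th):
                q = OUParams(mu1=th[0], halflife1=np.exp(th[1]),
                             s1=np.exp(th[2]))
                try:
                    return kalman_loglik("A", q, obs)
                except ValueError:
                    return -np.inf

            return stepping_stone(
                ll, lambda th: log_prior("A", th, pri1, bivariate=False),
                lambda r, m: sample_prior("A", pri1, r, m, bivariate=False),
                3, np.random.default_rng(seed), n_rungs=12, n_draws=2000)

        e1, se1 = uni_evidence(o1, 0, 10)
        e2, se2 = uni_evidence(o2, 1, 11)
        comb_se = np.sqrt(biv_se**2 + se1**2 + se2**2)
        assert biv_est == pytest.approx(e1 + e2, abs=max(4 * comb_se, 0.3))

    def test_two_seeds_agree_within_reported_error(self):
        p = biv()
        times = np.arange(30) * 4.0
        o1, o2 = simulate_linked_series("E", biv(rho=0.5), times,
                                        obs_se=0.2, seed=5)
        e1, s1 = marginal_likelihood("E", o1, o2, seed=1, n_rungs=10,
                                     n_draws=1000)
        e2, s2 = marginal_likelihood("E", o1, o2, seed=2, n_rungs=10,
                                     n_draws=1000)
        assert abs(e1 - e2) < 4 * np.sqrt(s1**2 + s2**2) + 0.2


class TestLinkSDEInterface:
    def test_needs_five_points_per_series(self):
        t = np.arange(3.0)
        o = TimeSeriesObs(times=t, values=np.zeros(3), ses=np.ones(3))
        with pytest.raises(ValueError, match="5 points"):
            LinkSDE(o, o, "A")

    def test_unknown_kind_rejected(self):
        t = np.arange(6.0)
        o = TimeSeriesObs(times=t, values=np.zeros(6), ses=np.ones(6))
        with pytest.raises(ValueError, match="kind"):
            LinkSDE(o, o, "F")

    def test_summary_reports_stationary_variance_scale(self):
        p = biv()
        o1, o2 = simulate_linked_series("A", p, np.arange(20.0), obs_se=0.2,
                                        seed=0)
        res = LinkSDE(o1, o2, "A").fit(n_draws=500, seed=0, burn=300)
        summ = res.summary()
        names = set(summ["parameter"])
        assert any(n.startswith("sigma2.") for n in names)
        assert any(n.startswith("t_half.") for n in names)
        assert (summ["lower95"] <= summ["median"]).all()
        assert (summ["median"] <= summ["upper95"]).all()
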