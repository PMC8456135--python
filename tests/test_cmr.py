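import itertools

import numpy as np
import pytest
from scipy import stats

from cladelink.cmr import (
    JollySeber,
    PradelSeniority,
    jolly_seber_direct,
    poisson_ci,
    pradel_loglik,
    to_instantaneous_rates,
)
from cladelink.stages import StageTable
from cladelink.synthetic import (BDSimConfig, simulate_fossil_record,
                                 simulate_pradel_histories)


class TestJollySeber:
    def test_perfect_detection_recovers_exact_richness(self, matrix_factory):
        m = matrix_factory(np.ones((10, 4), dtype=int))
        res = JollySeber(m).fit()
        assert np.allclose(res.nhat[1:3], 10.0)
        assert np.allclose(res.phi[:2], 1.0)

    def test_hand_worked_four_occasion_matrix(self, matrix_factory):
        data = np.array([
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 1, 1],
            [0, 1, 1, 0],
            [0, 1, 0, 1],
            [0, 1, 1, 1],
            [0, 0, 1, 1],
            [0, 0, 1, 0],
            [1, 0, 0, 1],
            [0, 1, 0, 0],
        ])
        res = jolly_seber_direct(matrix_factory(data))
        # oracle: tabulate n, m, z, r by hand and apply the direct formulas
        n = data.sum(axis=0)
        m_t, z_t, r_t = [], [], []
        for t in range(4):
            before = data[:, :t].any(axis=1)
            after = data[:, t + 1:].any(axis=1)
            at = data[:, t].astype(bool)
            m_t.append(int((at & before).sum()))
            z_t.append(int((~at & before & after).sum()))
            r_t.append(int((at & after).sum()))
        m_t, z_t, r_t = np.array(m_t), np.array(z_t), np.array(r_t)
        assert res.n.tolist() == n.tolist()
        assert res.m.tolist() == m_t.tolist()
        assert res.z.tolist() == z_t.tolist()
        assert res.r.tolist() == r_t.tolist()
        for t in (1, 2):
            mhat = m_t[t] + n[t] * z_t[t] / r_t[t]
            nhat = n[t] * mhat / m_t[t]
            assert res.mhat[t] == pytest.approx(mhat)
            assert res.nhat[t] == pytest.approx(nhat)
        # survival across boundary 1->2 from the hand-computed Mhats
        mhat1 = m_t[1] + n[1] * z_t[1] / r_t[1]
        mhat2 = m_t[2] + n[2] * z_t[2] / r_t[2]
        assert res.phi[1] == pytest.approx(mhat2 / (mhat1 - m_t[1] + n[1]))
        nhat1 = n[1] * mhat1 / m_t[1]
        nhat2 = n[2] * mhat2 / m_t[2]
        b1 = nhat2 - res.phi[1] * (nhat1 - n[1] + n[1])
        assert res.births[1] == pytest.approx(b1)
        # terminal occasions are flagged inestimable
        assert not res.nhat_ok[0] and not res.nhat_ok[3]

    def test_invariant_to_row_order(self, matrix_factory, rng):
        data = (rng.random((40, 6)) < 0.4).astype(int)
        data[data.sum(axis=1) == 0, 0] = 1
        r1 = JollySeber(matrix_factory(data)).fit()
        r2 = JollySeber(matrix_factory(data[rng.permutation(40)])).fit()
        assert np.allclose(r1.nhat, r2.nhat, equal_nan=True)
        assert np.allclose(r1.phi, r2.phi, equal_nan=True)

    def test_fewer_than_three_occasions_rejected(self, matrix_factory):
        with pytest.raises(ValueError, match="3 occasions"):
            JollySeber(matrix_factory(np.ones((5, 2), dtype=int)))

    def test_simulated_record_median_richness_error_under_ten_percent(self):
        # constant rates, detection ~0.7/stage, 300 genera, 12 stages.
        # Turnover is kept low relative to stage length because the direct
        # estimator assumes equal catchability: genera resident for only part
        # of a stage have lower exposure, and heavy turnover would mix a
        # known model bias into what is an implementation check.
        T, reps = 12, 100
        older = np.arange(T, 0, -1) * 5.0
        st = StageTable(names=tuple(f"s{i}" for i in range(T)),
                        older=tuple(older), younger=tuple(older - 5.0))
        r = -np.log(1 - 0.7) / 5.0
        rel_errs = []
        for rep in range(reps):
            cfg = BDSimConfig(
                origination={"c": np.full(T, 0.01)},
                extinction={"c": np.full(T, 0.01)},
                sampling={"c": np.full(T, r)},
                n0={"c": 300}, stage_table=st, seed=rep,
            )
            sim = simulate_fossil_record(cfg)
            res = JollySeber(sim.matrices["c"]).fit()
            truth = sim.truth["c"].presence_richness
            ok = res.nhat_ok & (truth > 0)
            rel_errs.append(np.nanmedian(
                np.abs(res.nhat[ok] - truth[ok]) / truth[ok]))
        assert np.median(rel_errs) < 0.10


class TestPoissonCI:
    def test_zero_count_lower_bound_is_zero(self):
        lo, hi = poisson_ci(0.0)
        assert lo == 0.0 and hi > 0

    def test_matches_chi_square_quantile_identity(self):
        lo, hi = poisson_ci(100.0, level=0.95)
        assert lo == pytest.approx(0.5 * stats.chi2.ppf(0.025, 200))
        assert hi == pytest.approx(0.5 * stats.chi2.ppf(0.975, 202))

    def test_width_monotone_increasing_in_the_estimate(self):
        widths = [np.diff(poisson_ci(float(n)))[0] for n in range(1, 501)]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_interval_brackets_the_estimate(self):
        for n in (1.0, 7.5, 40.0, 300.0):
            lo, hi = poisson_ci(n)
            assert lo < n < hi
        lo, hi = poisson_ci(50.0, method="normal")
        assert lo < 50 < hi


class TestPradelLikelihood:
    def all_histories(self, T):
        return [h for h in itertools.product([0, 1], repeat=T) if any(h)]

    def test_observable_history_probabilities_sum_to_one(self, matrix_factory,
                                                         rng):
        T = 3
        for _ in range(20):
            phi = rng.uniform(0.05, 0.95, T - 1)
            gam = rng.uniform(0.05, 0.95, T - 1)
            p = rng.uniform(0.05, 0.95, T)
            total = sum(
                np.exp(pradel_loglik(phi, gam, p,
                                     matrix_factory(np.array([h]))))
                for h in self.all_histories(T)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_internal_gap_impossible_under_certain_detection(self,
                                                             matrix_factory):
        phi = np.full(2, 0.7)
        gam = np.full(2, 0.6)
        p = np.full(3, 1.0 - 1e-12)
        ll = pradel_loglik(phi, gam, p, matrix_factory(np.array([[1, 0, 1]])))
        assert ll < -20  # probability numerically zero

    def test_history_0110_matches_hand_expanded_product_form(self,
                                                             matrix_factory):
        # oracle: explicit chi/xi expansion for T = 4, history (0 1 1 0)
        phi = np.array([0.8, 0.7, 0.6])
        gam = np.array([0.5, 0.6, 0.7])
        p = np.array([0.3, 0.4, 0.5, 0.6])
        ll = pradel_loglik(phi, gam, p,
                           matrix_factory(np.array([[0, 1, 1, 0]])))
        # cohort sizes a_t (a_1 = 1) and entry masses b_t
        a = [1.0]
        for t in range(1, 4):
            a.append(a[-1] * phi[t - 1] / gam[t - 1])
        b = [a[0]] + [a[t] * (1 - gam[t - 1]) for t in range(1, 4)]
        # xi_2: not detected before occasion 2 (given alive there)
        xi2 = (1 - gam[0]) + gam[0] * (1 - p[0]) * 1.0
        # chi_3: not detected after occasion 3
        chi3 = (1 - phi[2]) + phi[2] * (1 - p[3]) * 1.0
        # eta_t: never detected from t on, given alive at t
        eta = [0.0] * 4
        eta[3] = 1 - p[3]
        for t in (2, 1, 0):
            eta[t] = (1 - p[t]) * ((1 - phi[t]) + phi[t] * eta[t + 1])
        denom = sum(b[t] * (1 - eta[t]) for t in range(4))
        expected = a[1] * xi2 * p[1] * phi[1] * p[2] * chi3 / denom
        assert ll == pytest.approx(np.log(expected), abs=1e-12)


class TestPradelFit:
    def test_perfect_detection_gives_observed_survival_fractions(
        self, matrix_factory
    ):
        # deterministic staircase: genus i spans stages 0..i, so one genus
        # drops out at every boundary; 8 more genera span everything
        data = np.tril(np.ones((8, 8), dtype=int))
        data = np.vstack([data, np.ones((8, 8), dtype=int)])
        res = PradelSeniority(matrix_factory(data)).fit(n_starts=3, seed=0)
        alive = data.sum(axis=0)
        observed_phi = alive[1:] / alive[:-1]
        assert np.allclose(res.p[1:-1], 1.0, atol=1e-3)
        assert np.allclose(res.phi[1:-1], observed_phi[1:-1], atol=1e-3)

    def test_mle_beats_generating_parameters(self, matrix_factory):
        X = simulate_pradel_histories(np.full(7, 0.8), np.full(7, 0.7),
                                      np.full(8, 0.5), 600, seed=4)
        model = PradelSeniority(matrix_factory(X))
        fit = model.fit(n_starts=3, seed=0)
        ll_truth = model.loglike_probs(np.full(7, 0.8), np.full(7, 0.7),
                                       np.full(8, 0.5))
        assert fit.loglik >= ll_truth

    def test_interior_estimates_recover_truth_in_aggregate(self,
                                                           matrix_factory):
        X = simulate_pradel_histories(np.full(9, 0.8), np.full(9, 0.7),
                                      np.full(10, 0.5), 2000, seed=0)
        fit = PradelSeniority(matrix_factory(X)).fit(n_starts=3, seed=0)
        errs = np.concatenate([
            np.abs(fit.phi[:-1] - 0.8),
            np.abs(fit.gamma[1:] - 0.7),
            np.abs(fit.p[1:-1] - 0.5),
        ])
        assert errs.mean() < 0.05

    def test_terminal_parameters_flagged_confounded(self, matrix_factory):
        X = simulate_pradel_histories(np.full(5, 0.8), np.full(5, 0.7),
                                      np.full(6, 0.5), 800, seed=1)
        fit = PradelSeniority(matrix_factory(X)).fit(n_starts=2, seed=0)
        assert not fit.phi_ok[-1]
        assert not fit.gamma_ok[0]
        assert not fit.p_ok[0] and not fit.p_ok[-1]


class TestRateTransforms:
    def stages(self, T=4, dt=2.0):
        older = np.arange(T, 0, -1) * dt
        return StageTable(names=tuple(f"s{i}" for i in range(T)),
                          older=tuple(older), younger=tuple(older - dt))

    def fake_results(self, phi, gamma, p, T):
        from cladelink.cmr import PradelResults

        ones = np.ones(T - 1)
        return PradelResults(
            phi=phi, gamma=gamma, p=p,
            se_phi=0.01 * ones, se_gamma=0.01 * ones, se_p=0.01 * np.ones(T),
            se_logit_phi=0.1 * ones, se_logit_gamma=0.1 * ones,
            se_logit_p=0.1 * np.ones(T),
            loglik=0.0, converged=True,
            phi_ok=np.ones(T - 1, bool), gamma_ok=np.ones(T - 1, bool),
            p_ok=np.ones(T, bool),
        )

    def test_unit_survival_means_zero_extinction_rate(self):
        T = 4
        st = self.stages(T)
        res = self.fake_results(np.full(T - 1, 1.0), np.full(T - 1, 0.5),
                                np.full(T, 0.5), T)
        out = to_instantaneous_rates(res, st)
        # the zero rate has no finite log: the points are dropped, not imputed
        assert len(out["extinction"]) == 0
        assert len(out["origination"]) == T - 1  # gamma points unaffected

    def test_survival_inverts_to_the_generating_rate(self):
        # phi = exp(-0.5 * dt) with dt = 2 -> extinction rate 0.5
        T = 4
        st = self.stages(T, dt=2.0)
        phi = np.exp(-0.5 * 2.0) * np.ones(T - 1)
        res = self.fake_results(phi, np.full(T - 1, 0.6), np.full(T, 0.5), T)
        out = to_instantaneous_rates(res, st)
        assert np.allclose(np.exp(out["extinction"].values), 0.5)

    def test_sampling_probability_inverts_to_unit_rate(self):
        # p = 1 - exp(-1 * dt) with dt = 1 -> sampling rate 1.0
        T = 4
        st = self.stages(T, dt=1.0)
        p = (1.0 - np.exp(-1.0)) * np.ones(T)
        res = self.fake_results(np.full(T - 1, 0.8), np.full(T - 1, 0.6), p, T)
        out = to_instantaneous_rates(res, st)
        assert np.allclose(np.exp(out["sampling"].values), 1.0)

    def test_rates_timestamped_at_boundaries_and_midpoints(self):
        T = 4
        st = self.stages(T, dt=2.0)
        res = self.fake_results(np.full(T - 1, 0.8), np.full(T - 1, 0.6),
                                np.full(T, 0.5), T)
        out = to_instantaneous_rates(res, st)
        assert np.allclose(-out["extinction"].times, st.boundary_ages)
        assert np.allclose(-out["sampling"].times, st.midpoints)


class TestSyntheticRoundTrip:
    def test_rates_recovered_from_birth_death_record(self):
        # low turnover so occasion-discretization bias stays well inside the
        # estimation uncertainty; checks the gamma/boundary convention too
        T = 14
        older = np.arange(T, 0, -1) * 6.0
        st = StageTable(names=tuple(f"s{i}" for i in range(T)),
                        older=tuple(older), younger=tuple(older - 6.0))
        lam, mu = 0.035, 0.03
        cfg = BDSimConfig(
            origination={"c": np.full(T, lam)},
            extinction={"c": np.full(T, mu)},
            sampling={"c": np.full(T, 0.4)},
            n0={"c": 1500}, stage_table=st, seed=2,
        )
        sim = simulate_fossil_record(cfg)
        fit = PradelSeniority(sim.matrices["c"]).fit(n_starts=3, seed=0)
        rates = to_instantaneous_rates(fit, st, clade_label="c")
        ext = np.exp(rates["extinction"].values)
        orig = np.exp(rates["origination"].values)
        samp = np.exp(rates["sampling"].values)
        assert np.median(np.abs(ext - mu) / mu) < 0.35
        assert np.median(np.abs(orig - lam) / lam) < 0.35
        assert np.median(np.abs(samp - 0.4) / 0.4) < 0.25
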