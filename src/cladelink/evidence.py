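"""Stepping-stone estimation of marginal likelihoods.

The marginal likelihood Z = ∫ prior(θ) L(θ) dθ is estimated along a ladder
of power posteriors p_k(θ) ∝ prior(θ) L(θ)^{β_k}, 0 = β_0 < ... < β_K = 1,
as log Z = Σ_k log E_k[L^{β_{k+1}-β_k}], each expectation over samples from
rung k.  The ladder follows the usual β_k = (k/K)^{1/0.3} schedule that
concentrates rungs near the prior, where the integrand varies fastest.
Rung 0 is sampled iid from the prior; higher rungs run an adaptive
random-walk Metropolis chain seeded from the previous rung.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stepping_stone"]


def _ess_factor(w: np.ndarray) -> float:
    """Crude effective-sample-size deflation from the lag autocorrelation."""
    n = w.size
    if n < 10 or np.var(w) == 0:
        return float(n)
    x = w - w.mean()
    var = float(x @ x) / n
    tau = 1.0
    for lag in range(1, min(n // 4, 100)):
        rho = float(x[:-lag] @ x[lag:]) / ((n - lag) * var)
        if rho <= 0.0:
            break
        tau += 2.0 * rho
    return max(n / tau, 2.0)


def stepping_stone(
    log_lik,
    log_prior,
    sample_prior,
    ndim: int,
    rng: np.random.Generator,
    n_rungs: int = 16,
    n_draws: int = 2000,
    burn: int | None = None,
    ladder_exponent: float = 1.0 / 0.3,
    target_accept: float = 0.3,
) -> tuple[float, float]:
    """Estimate log Z and an approximate Monte-Carlo SE.

    Parameters
    ----------
    log_lik, log_prior : callables
        Log density terms on the sampling scale; may return -inf.
    sample_prior : callable
        ``sample_prior(rng, m) -> (m, ndim)`` iid prior draws.
    n_rungs : int
        Number of ladder intervals K; K+1 temperatures including 0 and 1.
    n_draws : int
        Retained draws per rung.
    """
    if n_rungs < 2:
        raise ValueError("need at least 2 rungs")
    burn = burn if burn is not None else max(n_draws // 4, 50)
    betas = (np.arange(n_rungs + 1) / n_rungs) ** ladder_exponent

    # rung 0: iid prior draws.  The prior-to-first-rung ratio dominates the
    # estimator variance under diffuse priors, and iid draws are cheap, so
    # this rung gets 4x the budget.
    theta0 = sample_prior(rng, 4 * n_draws)
    ll0 = np.array([log_lik(t) for t in theta0])
    scale = np.std(theta0, axis=0)
    scale[scale == 0] = 1.0

    log_ratios = np.empty(n_rungs)
    var_terms = np.empty(n_rungs)

    def ratio(ll: np.ndarray, dbeta: float, iid: bool) -> tuple[float, float]:
        logw = dbeta * ll
        m = logw[np.isfinite(logw)].max() if np.isfinite(logw).any() else 0.0
        w = np.exp(np.where(np.isfinite(logw), logw - m, -np.inf))
        wbar = w.mean()
        if wbar <= 0:
            raise RuntimeError("stepping-stone rung collapsed (all -inf)")
        n_eff = w.size if iid else _ess_factor(w)
        var_log = float(np.var(w) / (wbar * wbar * n_eff))
        return m + float(np.log(wbar)), var_log

    log_ratios[0], var_terms[0] = ratio(ll0, betas[1] - betas[0], iid=True)

    # initialize the chain at the prior draw most favored by the first rung
    post0 = np.where(np.isfinite(ll0), betas[1] * ll0, -np.inf)
    theta = theta0[int(np.argmax(post0))].copy()
    ll_cur = ll0[int(np.argmax(post0))]
    lp_cur = log_prior(theta)
    step = 2.4 / np.sqrt(ndim)

    for k in range(1, n_rungs):
        beta = betas[k]
        dbeta = betas[k + 1] - betas[k]
        lls = np.empty(n_draws)
        n_acc = 0
        n_tot = 0
        for i in range(-burn, n_draws):
            prop = theta + step * scale * rng.standard_normal(ndim)
            lp_p = log_prior(prop)
            if np.isfinite(lp_p):
                ll_p = log_lik(prop)
                if np.isfinite(ll_p):
                    log_alpha = (lp_p + beta * ll_p) - (lp_cur + beta * ll_cur)
                    if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
                        theta, ll_cur, lp_cur = prop, ll_p, lp_p
                        n_acc += 1
            n_tot += 1
            if i < 0:
                # adapt the global step toward the target acceptance rate
                if n_tot % 25 == 0:
                    acc = n_acc / n_tot
                    step *= np.exp(0.5 * (acc - target_accept))
            else:
                lls[i] = ll_cur
        log_ratios[k], var_terms[k] = ratio(lls, dbeta, iid=False)

    return float(log_ratios.sum()), float(np.sqrt(var_terms.sum()))
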