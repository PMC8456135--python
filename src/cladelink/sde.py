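"""Linear stochastic differential equation link models for paired series.

Five model classes relate two irregularly sampled, noisily observed time
series X1, X2, each marginally an Ornstein-Uhlenbeck (mean-reverting) process
dX = -alpha (X - mu) dt + sigma dB:

* ``A`` — independent processes (the null);
* ``B`` — X1 Granger-causes X2: X2's drift tracks mu2 + beta12 (X1 - mu1);
* ``C`` — X2 Granger-causes X1 (the mirror of B);
* ``D`` — bidirectional feedback (both couplings free);
* ``E`` — correlated noise: shared Brownian shocks with correlation rho but
  no drift coupling (contemporaneous correlation, not causation).

Mean reversion is reported as a half-life t1/2 = ln 2 / alpha (Myr) and the
noise as the stationary standard deviation s, with diffusion intensity
sigma = s * sqrt(2 alpha).  Inference is exact: the transition law on any
irregular grid is Gaussian (matrix exponential mean, integrated Lyapunov
covariance), observation error with known per-point SEs is folded in by a
Kalman filter started from the stationary law, posteriors are sampled with
an affine-invariant ensemble sampler, and marginal likelihoods for model
comparison come from stepping-stone sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov

from . import _sde_core as core
from .evidence import stepping_stone
from .series import RateSeries, TimeSeriesObs

__all__ = [
    "MODEL_KINDS",
    "OUParams",
    "LinkPriors",
    "LinkSDE",
    "LinkSDEResults",
    "ModelComparison",
    "halflife",
    "alpha_from_halflife",
    "ou_transition",
    "kalman_loglik",
    "sample_posterior",
    "marginal_likelihood",
    "compare_models",
    "compare_link_models",
    "prepare_series",
]

MODEL_KINDS = ("A", "B", "C", "D", "E")
LOG_OFFSET = 1e-4  # added to proportions before the log transform
_HL_BOUNDS = (0.1, 1000.0)  # half-life prior support, Myr


def halflife(alpha: float) -> float:
    """Half-life t1/2 = ln(2)/alpha of the mean reversion, in Myr."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return math.log(2.0) / alpha


def alpha_from_halflife(t_half: float) -> float:
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / t_half


@dataclass(frozen=True)
class OUParams:
    """Parameters of a (paired) OU system.

    Per series: mean ``mu`` (logged-rate units), half-life (Myr), stationary
    sd ``s``.  Couplings: ``beta12`` (series 1 -> series 2), ``beta21``
    (2 -> 1), noise correlation ``rho``.  Leave the second series as None
    for a univariate process.
    """

    mu1: float
    halflife1: float
    s1: float
    mu2: float | None = None
    halflife2: float | None = None
    s2: float | None = None
    beta12: float = 0.0
    beta21: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.halflife1 <= 0 or self.s1 <= 0:
            raise ValueError("half-life and stationary sd must be positive")
        if self.bivariate and (self.halflife2 <= 0 or self.s2 <= 0):
            raise ValueError("half-life and stationary sd must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def bivariate(self) -> bool:
        return self.mu2 is not None

    @property
    def alpha1(self) -> float:
        return alpha_from_halflife(self.halflife1)

    @property
    def alpha2(self) -> float:
        return alpha_from_halflife(self.halflife2)

    @property
    def sigma1(self) -> float:
        return self.s1 * math.sqrt(2.0 * self.alpha1)

    @property
    def sigma2(self) -> float:
        return self.s2 * math.sqrt(2.0 * self.alpha2)


def _check_kind(kind: str) -> str:
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown link-model kind {kind!r}")
    return kind


def drift_matrix(kind: str, params: OUParams) -> np.ndarray:
    """A in dX = -A (X - mu) dt for the given model class."""
    _check_kind(kind)
    a1, a2 = params.alpha1, params.alpha2
    b12 = params.beta12 if kind in ("B", "D") else 0.0
    b21 = params.beta21 if kind in ("C", "D") else 0.0
    return np.array([[a1, -a1 * b21], [-a2 * b12, a2]])


def diffusion_cov(kind: str, params: OUParams) -> np.ndarray:
    """Diffusion covariance matrix G G^T."""
    _check_kind(kind)
    s1, s2 = params.sigma1, params.sigma2
    off = params.rho * s1 * s2 if kind == "E" else 0.0
    return np.array([[s1 * s1, off], [off, s2 * s2]])


def is_stable(kind: str, params: OUParams) -> bool:
    """Both drift eigenvalues have positive real part (stationarity)."""
    if not params.bivariate:
        return params.alpha1 > 0
    A = drift_matrix(kind, params)
    return bool(np.trace(A) > 0 and np.linalg.det(A) > 0)


def stationary_cov(kind: str, params: OUParams) -> np.ndarray:
    """Solution S of A S + S A^T = C (the stationary covariance)."""
    if not params.bivariate:
        return np.array([[params.s1 ** 2]])
    A = drift_matrix(kind, params)
    return solve_continuous_lyapunov(A, diffusion_cov(kind, params))


def ou_transition(kind: str, params: OUParams, dt: float):
    """Exact conditional Gaussian law of the state after ``dt`` Myr.

    Returns ``(Phi, c, Q)`` with ``x(t+dt) | x(t) ~ N(Phi x + c, Q)``;
    ``c = (I - Phi) mu`` and ``Q = S - Phi S Phi^T`` with S the stationary
    covariance.  Raises for an unstable drift.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not is_stable(kind, params):
        raise ValueError("drift matrix is not stable; no stationary law")
    if not params.bivariate:
        a = params.alpha1
        phi = np.array([[math.exp(-a * dt)]])
        S = np.array([[params.s1 ** 2]])
        mu = np.array([params.mu1])
    else:
        A = drift_matrix(kind, params)
        phi = expm(-A * dt)
        S = stationary_cov(kind, params)
        mu = np.array([params.mu1, params.mu2])
    Q = S - phi @ S @ phi.T
    Q = (Q + Q.T) / 2.0
    return phi, (np.eye(len(mu)) - phi) @ mu, Q


# ---------------------------------------------------------------------------
# merged observation grid


@dataclass(frozen=True)
class _MergedObs:
    times: np.ndarray
    code: np.ndarray  # 1 = series1 only, 2 = series2 only, 3 = both
    y1: np.ndarray
    y2: np.ndarray
    se1: np.ndarray
    se2: np.ndarray


def _merge(obs1: TimeSeriesObs, obs2: TimeSeriesObs, tol: float = 1e-9
           ) -> _MergedObs:
    t_all = np.sort(np.concatenate([obs1.times, obs2.times]))
    keep = np.concatenate([[True], np.diff(t_all) > tol])
    times = t_all[keep]
    n = times.size
    code = np.zeros(n, dtype=np.int64)
    y1 = np.zeros(n)
    y2 = np.zeros(n)
    se1 = np.ones(n)
    se2 = np.ones(n)
    for obs, bit, y, se in ((obs1, 1, y1, se1), (obs2, 2, y2, se2)):
        idx = np.searchsorted(times, obs.times - tol)
        if not np.allclose(times[idx], obs.times, atol=tol, rtol=0):
            raise RuntimeError("grid merge failed")  # pragma: no cover
        code[idx] |= bit
        y[idx] = obs.values
        se[idx] = obs.ses
    return _MergedObs(times=times, code=code, y1=y1, y2=y2, se1=se1, se2=se2)


def kalman_loglik(kind: str, params: OUParams,
                  obs1: TimeSeriesObs, obs2: TimeSeriesObs | None = None
                  ) -> float:
    """Exact log-likelihood of the observed pair under the link model.

    At each merged time point either one or both components are observed;
    observations are state + independent N(0, se^2) noise.  With ``obs2``
    None the univariate OU likelihood of ``obs1`` is returned.
    """
    if obs2 is None:
        ll = core.kalman1(params.mu1, params.alpha1, params.sigma1 ** 2,
                          obs1.times, obs1.values, obs1.ses)
    else:
        m = _merge(obs1, obs2)
        A = drift_matrix(kind, params)
        C = diffusion_cov(kind, params)
        ll = core.kalman2(A[0, 0], A[0, 1], A[1, 0], A[1, 1],
                          C[0, 0], C[0, 1], C[1, 1],
                          params.mu1, params.mu2,
                          m.times, m.code, m.y1, m.y2, m.se1, m.se2)
    if ll <= core.NEG_INF:
        raise ValueError("non-stationary parameters or numerical breakdown")
    return float(ll)


# ---------------------------------------------------------------------------
# priors and the sampling-scale parameterization
#
# theta layout: [mu1, log t_half1, log s1, mu2, log t_half2, log s2] plus,
# depending on the model class, beta12 (B), beta21 (C), beta12+beta21 (D) or
# atanh(rho) (E).  Univariate: [mu, log t_half, log s].


@dataclass(frozen=True)
class LinkPriors:
    """Priors for a series pair (declared, not taken from any source data).

    mu ~ Normal(series mean, (2 x series sd)^2); t1/2 log-uniform on
    [0.1, 1000] Myr; s log-normal(ln(series sd), 1); beta ~ Normal(0, 2.5^2);
    rho uniform on (-1, 1).  The coupling-prior scale was calibrated on
    null simulations so that evidence comparison keeps adequate specificity
    (a tight beta prior makes the causal models nearly indistinguishable
    from the null, handing chance correlations the win); couplings beyond
    |beta| ~ 2.5 are implausible regardless (bidirectional stability needs
    beta12*beta21 < 1).
    """

    mu_loc: tuple[float, float]
    mu_scale: tuple[float, float]
    logs_loc: tuple[float, float]
    logs_scale: float = 1.0
    beta_sd: float = 2.5
    logh_lo: float = math.log(_HL_BOUNDS[0])
    logh_hi: float = math.log(_HL_BOUNDS[1])

    @classmethod
    def from_obs(cls, obs1: TimeSeriesObs, obs2: TimeSeriesObs | None = None
                 ) -> "LinkPriors":
        def loc_scale(o):
            sd = float(np.std(o.values, ddof=1)) if len(o) > 1 else 1.0
            sd = max(sd, 1e-3)
            return float(np.mean(o.values)), sd

        m1, sd1 = loc_scale(obs1)
        m2, sd2 = loc_scale(obs2) if obs2 is not None else (m1, sd1)
        return cls(mu_loc=(m1, m2), mu_scale=(2 * sd1, 2 * sd2),
                   logs_loc=(math.log(sd1), math.log(sd2)))


def theta_dim(kind: str, bivariate: bool = True) -> int:
    if not bivariate:
        return 3
    return {"A": 6, "B": 7, "C": 7, "D": 8, "E": 7}[_check_kind(kind)]


def theta_to_params(kind: str, theta: np.ndarray, bivariate: bool = True
                    ) -> OUParams:
    theta = np.asarray(theta, dtype=float)
    if not bivariate:
        return OUParams(mu1=theta[0], halflife1=math.exp(theta[1]),
                        s1=math.exp(theta[2]))
    mu1, lh1, ls1, mu2, lh2, ls2 = theta[:6]
    extra = theta[6:]
    b12 = b21 = rho = 0.0
    if kind == "B":
        b12 = extra[0]
    elif kind == "C":
        b21 = extra[0]
    elif kind == "D":
        b12, b21 = extra[0], extra[1]
    elif kind == "E":
        rho = math.tanh(extra[0])
    return OUParams(mu1=mu1, halflife1=math.exp(lh1), s1=math.exp(ls1),
                    mu2=mu2, halflife2=math.exp(lh2), s2=math.exp(ls2),
                    beta12=b12, beta21=b21, rho=rho)


def _norm_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - math.log(scale) - 0.5 * core.LOG2PI


def log_prior(kind: str, theta: np.ndarray, priors: LinkPriors,
              bivariate: bool = True) -> float:
    theta = np.asarray(theta, dtype=float)
    lp = 0.0
    n_series = 2 if bivariate else 1
    logh_range = priors.logh_hi - priors.logh_lo
    for i in range(n_series):
        mu, lh, ls = theta[3 * i : 3 * i + 3]
        if not priors.logh_lo <= lh <= priors.logh_hi:
            return -np.inf
        lp += _norm_logpdf(mu, priors.mu_loc[i], priors.mu_scale[i])
        lp -= math.log(logh_range)
        lp += _norm_logpdf(ls, priors.logs_loc[i], priors.logs_scale)
    if not bivariate:
        return lp
    for z in theta[6:]:
        if kind == "E":
            # rho ~ U(-1,1) mapped through atanh: density 0.5 * sech^2(z)
            lp += math.log(0.5) + math.log(max(1.0 - math.tanh(z) ** 2, 1e-300))
        else:
            lp += _norm_logpdf(z, 0.0, priors.beta_sd)
    return lp


def sample_prior(kind: str, priors: LinkPriors, rng: np.random.Generator,
                 size: int, bivariate: bool = True) -> np.ndarray:
    dim = theta_dim(kind, bivariate)
    out = np.empty((size, dim))
    n_series = 2 if bivariate else 1
    for i in range(n_series):
        out[:, 3 * i] = rng.normal(priors.mu_loc[i], priors.mu_scale[i], size)
        out[:, 3 * i + 1] = rng.uniform(priors.logh_lo, priors.logh_hi, size)
        out[:, 3 * i + 2] = rng.normal(priors.logs_loc[i], priors.logs_scale,
                                       size)
    if bivariate:
        for j in range(6, dim):
            if kind == "E":
                out[:, j] = np.arctanh(rng.uniform(-1, 1, size))
            else:
                out[:, j] = rng.normal(0.0, priors.beta_sd, size)
    return out


# ---------------------------------------------------------------------------
# model object


@dataclass(frozen=True)
class LinkSDEResults:
    """Posterior summary for one link model.

    ``summary()`` reports mean/median/95% bounds for mu, t1/2, the
    stationary variance s^2, and the coupling (beta or rho) of each series,
    on the natural scale.  ``rhat``/``ess`` are split-Rhat and bulk effective
    sample size computed across walkers.
    """

    kind: str
    param_names: tuple[str, ...]
    draws: np.ndarray  # (n_draws, dim) on the sampling (theta) scale
    natural: pd.DataFrame  # per-draw natural-scale parameters
    log_prob: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    labels: tuple[str, str]

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.natural.columns:
            v = self.natural[col].to_numpy()
            rows.append(
                (col, float(np.mean(v)), float(np.median(v)),
                 float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
            )
        return pd.DataFrame(rows, columns=["parameter", "mean", "median",
                                           "lower95", "upper95"])


class LinkSDE:
    """One link model (A-E) for a pair of observed series.

    Model B is "first series causes second"; C is the reverse.  The pair
    ordering is whatever the caller passes and is echoed in all outputs.
    """

    def __init__(self, obs1: TimeSeriesObs, obs2: TimeSeriesObs, kind: str,
                 priors: LinkPriors | None = None):
        _check_kind(kind)
        if len(obs1) < 5 or len(obs2) < 5:
            raise ValueError("need at least 5 points per series")
        self.kind = kind
        self.obs1 = obs1
        self.obs2 = obs2
        self.priors = priors or LinkPriors.from_obs(obs1, obs2)
        self._m = _merge(obs1, obs2)
        self.dim = theta_dim(kind)

    # likelihood / posterior on the sampling scale -------------------------

    def loglike_theta(self, theta: np.ndarray) -> float:
        p = theta_to_params(self.kind, theta)
        A = drift_matrix(self.kind, p)
        C = diffusion_cov(self.kind, p)
        m = self._m
        ll = core.kalman2(A[0, 0], A[0, 1], A[1, 0], A[1, 1],
                          C[0, 0], C[0, 1], C[1, 1], p.mu1, p.mu2,
                          m.times, m.code, m.y1, m.y2, m.se1, m.se2)
        return ll if ll > core.NEG_INF else -np.inf

    def logpost_theta(self, theta: np.ndarray) -> float:
        lp = log_prior(self.kind, theta, self.priors)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.loglike_theta(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    def _natural_frame(self, draws: np.ndarray) -> pd.DataFrame:
        l1, l2 = self.obs1.label or "series1", self.obs2.label or "series2"
        cols = {
            f"mu.{l1}": draws[:, 0],
            f"t_half.{l1}": np.exp(draws[:, 1]),
            f"sigma2.{l1}": np.exp(2 * draws[:, 2]),
            f"mu.{l2}": draws[:, 3],
            f"t_half.{l2}": np.exp(draws[:, 4]),
            f"sigma2.{l2}": np.exp(2 * draws[:, 5]),
        }
        if self.kind == "B":
            cols[f"beta.{l1}.to.{l2}"] = draws[:, 6]
        elif self.kind == "C":
            cols[f"beta.{l2}.to.{l1}"] = draws[:, 6]
        elif self.kind == "D":
            cols[f"beta.{l1}.to.{l2}"] = draws[:, 6]
            cols[f"beta.{l2}.to.{l1}"] = draws[:, 7]
        elif self.kind == "E":
            cols["rho"] = np.tanh(draws[:, 6])
        return pd.DataFrame(cols)

    # posterior sampling ----------------------------------------------------

    def fit(self, n_draws: int = 4000, seed: int = 0, n_walkers: int = 32,
            burn: int = 800, rhat_threshold: float = 1.1) -> LinkSDEResults:
        """Sample the posterior with an affine-invariant ensemble sampler."""
        import arviz as az
        import emcee

        rng = np.random.default_rng(seed)
        p0 = sample_prior(self.kind, self.priors, rng, 16 * n_walkers)
        lp0 = np.array([self.logpost_theta(t) for t in p0])
        good = np.isfinite(lp0)
        if not good.any():
            raise RuntimeError("could not initialize walkers from the prior")
        # tight ball around the best prior draw (the usual ensemble-sampler
        # initialization); the burn-in then disperses it to the posterior
        center = p0[good][np.argmax(lp0[good])]
        scale = np.maximum(np.std(p0[good], axis=0), 1e-3)
        start = center + 0.02 * scale * rng.standard_normal(
            (n_walkers, self.dim))
        lps = np.array([self.logpost_theta(t) for t in start])
        bad = ~np.isfinite(lps)
        for i in np.flatnonzero(bad):
            start[i] = center
        # per-walker chains must be long relative to the autocorrelation
        # time (tens of steps for the stretch move) or split-Rhat across
        # walkers is meaningless
        n_steps = burn + max(int(np.ceil(n_draws / n_walkers)), 500)
        moves = [(emcee.moves.DEMove(), 0.8),
                 (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(n_walkers, self.dim,
                                        self.logpost_theta, moves=moves)
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31 - 1))).get_state()
        sampler.run_mcmc(start, n_steps, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain(discard=burn)  # (steps, walkers, dim)
        logp = sampler.get_log_prob(discard=burn)
        names = tuple(f"theta{i}" for i in range(self.dim))
        idata = az.from_dict(
            posterior={n: chain[:, :, i].T for i, n in enumerate(names)}
        )
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
        rhat = {n: float(rhat_ds[n].values) for n in names}
        ess = {n: float(ess_ds[n].values) for n in names}
        converged = all(np.isfinite(v) and v < rhat_threshold
                        for v in rhat.values())
        flat = chain.reshape(-1, self.dim)
        return LinkSDEResults(
            kind=self.kind, param_names=names, draws=flat,
            natural=self._natural_frame(flat), log_prob=logp.reshape(-1),
            rhat=rhat, ess=ess, converged=converged,
            labels=(self.obs1.label, self.obs2.label),
        )

    # evidence --------------------------------------------------------------

    def log_evidence(self, seed: int = 0, n_rungs: int = 16,
                     n_draws: int = 2000) -> tuple[float, float]:
        """Stepping-stone log marginal likelihood and its Monte-Carlo SE."""
        rng = np.random.default_rng(seed)
        return stepping_stone(
            log_lik=self.loglike_theta,
            log_prior=lambda t: log_prior(self.kind, t, self.priors),
            sample_prior=lambda r, m: sample_prior(self.kind, self.priors,
                                                   r, m),
            ndim=self.dim, rng=rng, n_rungs=n_rungs, n_draws=n_draws,
        )


# ---------------------------------------------------------------------------
# functional wrappers (module-level operations)


def sample_posterior(kind: str, obs1: TimeSeriesObs, obs2: TimeSeriesObs,
                     priors: LinkPriors | None = None, n_draws: int = 4000,
                     seed: int = 0, **kwargs) -> LinkSDEResults:
    """Posterior draws for one link model; see :meth:`LinkSDE.fit`."""
    return LinkSDE(obs1, obs2, kind, priors).fit(n_draws=n_draws, seed=seed,
                                                 **kwargs)


def marginal_likelihood(kind: str, obs1: TimeSeriesObs, obs2: TimeSeriesObs,
                        priors: LinkPriors | None = None, seed: int = 0,
                        n_rungs: int = 16, n_draws: int = 2000
                        ) -> tuple[float, float]:
    """Stepping-stone log evidence for one link model (value, MC SE)."""
    return LinkSDE(obs1, obs2, kind, priors).log_evidence(
        seed=seed, n_rungs=n_rungs, n_draws=n_draws)


@dataclass(frozen=True)
class ModelComparison:
    """Evidences, posterior model probabilities and Bayes factors."""

    kinds: tuple[str, ...]
    log_evidence: dict[str, float]
    evidence_se: dict[str, float]
    probabilities: dict[str, float]
    labels: tuple[str, str] = ("series1", "series2")

    @property
    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)

    def percent(self, kind: str) -> float:
        return 100.0 * self.probabilities[kind]

    def bayes_factor(self, kind_i: str, kind_j: str) -> float:
        return self.probabilities[kind_i] / self.probabilities[kind_j]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.kinds),
                "log_evidence": [self.log_evidence[k] for k in self.kinds],
                "mc_se": [self.evidence_se[k] for k in self.kinds],
                "percent_support": [round(self.percent(k), 1)
                                    for k in self.kinds],
            }
        )

    def to_dict(self) -> dict:
        return {
            "series": list(self.labels),
            "models": {
                k: {
                    "log_evidence": self.log_evidence[k],
                    "mc_se": self.evidence_se[k],
                    "percent_support": round(self.percent(k), 1),
                }
                for k in self.kinds
            },
            "best_model": self.best,
            "bayes_factor_best_vs_null": round(self.bayes_factor(self.best, "A"), 1)
            if "A" in self.probabilities else None,
        }


def compare_models(evidences: dict[str, float | tuple[float, float]],
                   labels: tuple[str, str] = ("series1", "series2")
                   ) -> ModelComparison:
    """Posterior model probabilities from log evidences (equal model priors)."""
    kinds = tuple(evidences)
    logz, se = {}, {}
    for k, v in evidences.items():
        if isinstance(v, tuple):
            logz[k], se[k] = float(v[0]), float(v[1])
        else:
            logz[k], se[k] = float(v), 0.0
    vals = np.array([logz[k] for k in kinds])
    w = np.exp(vals - vals.max())
    w /= w.sum()
    return ModelComparison(kinds=kinds, log_evidence=logz, evidence_se=se,
                           probabilities=dict(zip(kinds, w)), labels=labels)


def compare_link_models(obs1: TimeSeriesObs, obs2: TimeSeriesObs,
                        kinds=MODEL_KINDS, priors: LinkPriors | None = None,
                        seed: int = 0, n_rungs: int = 16, n_draws: int = 2000
                        ) -> ModelComparison:
    """Evidence for every model class of a pair, combined into weights."""
    priors = priors or LinkPriors.from_obs(obs1, obs2)
    ev = {}
    for i, kind in enumerate(kinds):
        ev[kind] = marginal_likelihood(kind, obs1, obs2, priors,
                                       seed=seed + 1000 * i,
                                       n_rungs=n_rungs, n_draws=n_draws)
    return compare_models(
        ev, labels=(obs1.label or "series1", obs2.label or "series2"))


# ---------------------------------------------------------------------------
# series preparation


def prepare_series(series: RateSeries, kind: str = "rate",
                   offset: float = LOG_OFFSET) -> TimeSeriesObs:
    """Convert an estimated series into link-model observations.

    Rates arrive already log-transformed (with log-scale SEs) and pass
    through.  Proportions are transformed as log(p + offset) with the small
    offset permitting p = 0; their SEs propagate by the delta method,
    se_log = se_p / (p + offset).
    """
    if kind == "rate":
        return TimeSeriesObs(times=series.times, values=series.values,
                             ses=series.ses, label=series.label)
    if kind == "proportion":
        p = series.values
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        vals = np.log(p + offset)
        ses = series.ses / (p + offset)
        return TimeSeriesObs(times=series.times, values=vals, ses=ses,
                             label=series.label)
    raise ValueError(f"unknown series kind {kind!r}")
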