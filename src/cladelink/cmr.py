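"""Capture-mark-recapture estimation of richness and diversification rates.

Detection histories (genus x stage, 0/1) are treated exactly like capture
histories of individuals over sampling occasions.  Two estimators are
provided:

* :class:`JollySeber` — the classical direct (closed-form) open-population
  estimators of "population size" (genus richness), survival and birth
  numbers, with Poisson-sampling confidence intervals on richness.
* :class:`PradelSeniority` — maximum likelihood for the fully time-varying
  seniority model combining forward-time survival ``phi`` (complement:
  extinction) and reverse-time seniority ``gamma`` (complement: origination)
  with per-occasion detection probabilities ``p``.

Interval probabilities are converted to instantaneous per-Myr rates under an
exponential waiting-time model, e.g. extinction rate = -ln(phi)/dt, because
the stage durations are unequal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .occurrences import DetectionMatrix
from .series import RateSeries
from .stages import StageTable

__all__ = [
    "JollySeber",
    "JollySeberResults",
    "PradelSeniority",
    "PradelResults",
    "jolly_seber_direct",
    "poisson_ci",
    "pradel_loglik",
    "pradel_fit",
    "to_instantaneous_rates",
]

_LOGIT_WELL_CONSTRAINED_SE = 2.0


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# Jolly-Seber direct estimators


@dataclass(frozen=True)
class JollySeberResults:
    """Direct Jolly-Seber estimates with estimability flags.

    Arrays are indexed by occasion (stage).  ``nhat`` is estimated richness,
    ``phi`` per-boundary survival (index t = boundary t -> t+1), ``births``
    per-boundary origination numbers.  NaN marks inestimable entries, which
    are additionally flagged in the ``*_ok`` masks.  Direct survival
    estimates may exceed 1; they are reported raw and flagged, never
    truncated.
    """

    n: np.ndarray
    m: np.ndarray
    z: np.ndarray
    r: np.ndarray
    mhat: np.ndarray
    nhat: np.ndarray
    nhat_lower: np.ndarray
    nhat_upper: np.ndarray
    phi: np.ndarray
    births: np.ndarray
    nhat_ok: np.ndarray
    phi_ok: np.ndarray
    phi_gt1: np.ndarray
    stage_names: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        T = self.n.size
        return pd.DataFrame(
            {
                "stage": list(self.stage_names),
                "n": self.n,
                "m": self.m,
                "z": self.z,
                "r": self.r,
                "Nhat": self.nhat,
                "Nhat_lower95": self.nhat_lower,
                "Nhat_upper95": self.nhat_upper,
                "Nhat_ok": self.nhat_ok,
                "phi": np.append(self.phi, np.nan),
                "phi_ok": np.append(self.phi_ok, False),
                "births": np.append(self.births, np.nan),
            },
            index=range(T),
        )


class JollySeber:
    """Classical direct Jolly-Seber estimators on a detection matrix."""

    def __init__(self, matrix: DetectionMatrix):
        if matrix.n_stages < 3:
            raise ValueError("Jolly-Seber needs at least 3 occasions")
        self.matrix = matrix

    def fit(self, ci_level: float = 0.95, ci_method: str = "exact"
            ) -> JollySeberResults:
        X = self.matrix.data.astype(bool)
        n_gen, T = X.shape
        seen_before = np.zeros_like(X)
        seen_after = np.zeros_like(X)
        seen_before[:, 1:] = np.cumsum(X[:, :-1], axis=1) > 0
        seen_after[:, :-1] = (np.cumsum(X[:, ::-1], axis=1) > 0)[:, ::-1][:, 1:]

        n = X.sum(axis=0).astype(float)
        m = (X & seen_before).sum(axis=0).astype(float)
        z = (~X & seen_before & seen_after).sum(axis=0).astype(float)
        r = (X & seen_after).sum(axis=0).astype(float)
        R = n.copy()  # all detected genera remain "released"

        mhat = np.full(T, np.nan)
        nhat = np.full(T, np.nan)
        nhat_ok = np.zeros(T, dtype=bool)
        for t in range(T):
            if t == T - 1 or r[t] == 0:
                continue
            mhat[t] = m[t] + R[t] * z[t] / r[t]
            if m[t] > 0:
                nhat[t] = n[t] * mhat[t] / m[t]
                nhat_ok[t] = 0 < t < T - 1
        phi = np.full(T - 1, np.nan)
        phi_ok = np.zeros(T - 1, dtype=bool)
        for t in range(T - 1):
            denom = mhat[t] - m[t] + R[t]
            if np.isfinite(mhat[t]) and np.isfinite(mhat[t + 1]) and denom > 0:
                phi[t] = mhat[t + 1] / denom
                phi_ok[t] = True
            elif t == 0 and np.isfinite(mhat[t + 1]):
                # m_1 = z_1 = 0 so Mhat_1 = 0 exactly: phi_1 is estimable
                phi[t] = mhat[t + 1] / R[t] if R[t] > 0 else np.nan
                phi_ok[t] = np.isfinite(phi[t])
        births = np.full(T - 1, np.nan)
        for t in range(T - 1):
            if np.isfinite(nhat[t]) and np.isfinite(nhat[t + 1]) and np.isfinite(phi[t]):
                births[t] = nhat[t + 1] - phi[t] * (nhat[t] - n[t] + R[t])

        lower = np.full(T, np.nan)
        upper = np.full(T, np.nan)
        for t in range(T):
            if np.isfinite(nhat[t]):
                lower[t], upper[t] = poisson_ci(nhat[t], level=ci_level,
                                                method=ci_method)
        return JollySeberResults(
            n=n, m=m, z=z, r=r, mhat=mhat, nhat=nhat,
            nhat_lower=lower, nhat_upper=upper, phi=phi, births=births,
            nhat_ok=nhat_ok, phi_ok=phi_ok,
            phi_gt1=np.isfinite(phi) & (phi > 1.0),
            stage_names=self.matrix.stage_names,
        )


def jolly_seber_direct(matrix: DetectionMatrix, **kwargs) -> JollySeberResults:
    """Functional wrapper: ``JollySeber(matrix).fit(**kwargs)``."""
    return JollySeber(matrix).fit(**kwargs)


def poisson_ci(nhat: float, level: float = 0.95, method: str = "exact"
               ) -> tuple[float, float]:
    """Confidence interval for a Poisson mean with observed count ``nhat``.

    ``exact`` uses the chi-square quantile relation (valid for non-integer
    counts via the gamma continuation); ``normal`` the Wald approximation.
    """
    if nhat < 0:
        raise ValueError("nhat must be >= 0")
    alpha = 1.0 - level
    if method == "exact":
        lower = 0.0 if nhat == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * nhat)
        upper = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * (nhat + 1))
        return float(lower), float(upper)
    if method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(nhat)
        return float(max(nhat - half, 0.0)), float(nhat + half)
    raise ValueError(f"unknown ci method {method!r}")


# ---------------------------------------------------------------------------
# Pradel seniority model


def _suff_stats(X: np.ndarray) -> dict[str, np.ndarray]:
    """Sufficient statistics of the fully time-varying seniority likelihood."""
    n_gen, T = X.shape
    first = X.argmax(axis=1)
    last = T - 1 - X[:, ::-1].argmax(axis=1)
    F = np.bincount(first, minlength=T).astype(float)
    L = np.bincount(last, minlength=T).astype(float)
    # S[t] = number of histories whose range spans boundary t (first<=t<last)
    S = np.zeros(T - 1)
    for f, l in zip(first, last):
        S[f:l] += 1
    colsum = X.sum(axis=0).astype(float)
    D1 = colsum - F  # detections at t that are not first detections
    inside = np.concatenate([[0.0], S])  # histories with first < t <= last
    D0 = inside - D1
    return {"F": F, "L": L, "S": S, "D1": D1, "D0": D0, "N": float(n_gen)}


def _pradel_loglik_stats(phi, gamma, p, ss) -> float:
    """Log-likelihood from sufficient statistics.

    ``phi[t]`` is survival across boundary t->t+1 (length T-1); ``gamma[t]``
    is the seniority of occasion t+1 relative to t (length T-1, i.e. the
    model-level gamma at occasions 2..T); ``p`` per-occasion detection
    (length T).  Histories are conditioned on at least one detection.
    """
    T = p.size
    with np.errstate(divide="ignore", invalid="ignore"):
        # relative cohort sizes and entry mass
        a = np.empty(T)
        a[0] = 1.0
        for t in range(1, T):
            a[t] = a[t - 1] * phi[t - 1] / gamma[t - 1]
        b = np.empty(T)
        b[0] = a[0]
        b[1:] = a[1:] * (1.0 - gamma)
        # reverse tail: no detection before first capture
        xi = np.empty(T)
        xi[0] = 1.0
        for t in range(1, T):
            xi[t] = (1.0 - gamma[t - 1]) + gamma[t - 1] * (1.0 - p[t - 1]) * xi[t - 1]
        # forward tail: no detection after last capture
        chi = np.empty(T)
        chi[-1] = 1.0
        for t in range(T - 2, -1, -1):
            chi[t] = (1.0 - phi[t]) + phi[t] * (1.0 - p[t + 1]) * chi[t + 1]
        # never-detected probability given alive at t
        eta = np.empty(T)
        eta[-1] = 1.0 - p[-1]
        for t in range(T - 2, -1, -1):
            eta[t] = (1.0 - p[t]) * ((1.0 - phi[t]) + phi[t] * eta[t + 1])
        denom = float(b @ (1.0 - eta))
        if not np.isfinite(denom) or denom <= 0:
            return -np.inf
        ll = (
            ss["F"] @ (np.log(a) + np.log(xi) + np.log(p))
            + ss["L"] @ np.log(chi)
            + ss["S"] @ np.log(phi)
            + ss["D1"] @ np.log(p)
            + ss["D0"] @ np.log1p(-p)
            - ss["N"] * np.log(denom)
        )
    return float(ll) if np.isfinite(ll) else -np.inf


@dataclass(frozen=True)
class PradelResults:
    """MLEs of the fully time-varying seniority model.

    ``phi``/``gamma`` have length T-1 (boundaries), ``p`` length T (stages).
    Standard errors are asymptotic (inverse observed information) on the
    logit scale, delta-transformed to the probability scale.  Confounded
    terminal parameters (phi at the last boundary with p at the last
    occasion; gamma at the first boundary with p at the first occasion) are
    flagged, as is any parameter whose logit-scale SE exceeds the
    well-constrained threshold.
    """

    phi: np.ndarray
    gamma: np.ndarray
    p: np.ndarray
    se_phi: np.ndarray
    se_gamma: np.ndarray
    se_p: np.ndarray
    se_logit_phi: np.ndarray
    se_logit_gamma: np.ndarray
    se_logit_p: np.ndarray
    loglik: float
    converged: bool
    phi_ok: np.ndarray
    gamma_ok: np.ndarray
    p_ok: np.ndarray
    stage_names: tuple[str, ...] = ()
    n_starts_converged: int = 0

    def summary(self) -> pd.DataFrame:
        T = self.p.size
        rows = []
        for t in range(T - 1):
            rows.append(("phi", t, self.phi[t], self.se_phi[t], self.phi_ok[t]))
            rows.append(("gamma", t, self.gamma[t], self.se_gamma[t],
                         self.gamma_ok[t]))
        for t in range(T):
            rows.append(("p", t, self.p[t], self.se_p[t], self.p_ok[t]))
        return pd.DataFrame(rows, columns=["param", "index", "estimate", "se",
                                           "well_constrained"])


class PradelSeniority:
    """Fully time-varying Pradel seniority model for one clade's matrix.

    Free parameters on the logit scale: survival across each of the T-1
    boundaries, seniority at occasions 2..T, detection at each of the T
    occasions.  The likelihood conditions every history on being detected at
    least once; entry probabilities follow from the seniority parameters via
    the relative cohort sizes, which makes the conditional probabilities of
    the observable histories sum to one (a property the test suite checks by
    enumeration).
    """

    def __init__(self, matrix: DetectionMatrix):
        if matrix.n_stages < 3:
            raise ValueError("need at least 3 occasions")
        self.matrix = matrix
        self._ss = _suff_stats(matrix.data.astype(np.int64))
        self.T = matrix.n_stages

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        T = self.T
        phi = _expit(theta[: T - 1])
        gamma = _expit(theta[T - 1 : 2 * (T - 1)])
        p = _expit(theta[2 * (T - 1) :])
        return phi, gamma, p

    def loglike(self, theta: np.ndarray) -> float:
        phi, gamma, p = self._unpack(theta)
        return _pradel_loglik_stats(phi, gamma, p, self._ss)

    def loglike_probs(self, phi, gamma, p) -> float:
        """Log-likelihood at probability-scale parameter values."""
        return _pradel_loglik_stats(np.asarray(phi, float),
                                    np.asarray(gamma, float),
                                    np.asarray(p, float), self._ss)

    # -- fitting ------------------------------------------------------------

    def _start(self) -> np.ndarray:
        """Heuristic start: range-through survival and detection fractions."""
        X = self.matrix.data.astype(bool)
        T = self.T
        first = X.argmax(axis=1)
        last = T - 1 - X[:, ::-1].argmax(axis=1)
        alive = np.zeros(T)
        det = X.sum(axis=0).astype(float)
        for f, l in zip(first, last):
            alive[f : l + 1] += 1
        p0 = np.clip(det / np.maximum(alive, 1.0), 0.05, 0.95)
        phi0 = np.full(T - 1, 0.8)
        gamma0 = np.full(T - 1, 0.8)
        return np.concatenate([_logit(phi0), _logit(gamma0), _logit(p0)])

    def fit(self, n_starts: int = 10, seed: int = 0, gtol: float = 1e-8,
            compute_se: bool = True) -> PradelResults:
        rng = np.random.default_rng(seed)
        base = self._start()
        best = None
        n_ok = 0
        for k in range(n_starts):
            theta0 = base if k == 0 else base + rng.normal(0, 0.75, base.size)
            res = optimize.minimize(
                lambda th: -self.loglike(th), theta0, method="L-BFGS-B",
                options={"maxiter": 2000, "gtol": gtol, "ftol": 1e-12},
            )
            if np.isfinite(res.fun):
                n_ok += 1
                if best is None or res.fun < best.fun - 1e-9:
                    best = res
        if best is None:
            raise RuntimeError("Pradel fit failed to converge from any start")
        theta = best.x
        T = self.T
        phi, gamma, p = self._unpack(theta)

        se_logit = np.full(theta.size, np.nan)
        if compute_se:
            H = approx_hess1(theta, self.loglike)
            # invert the observed information; pseudo-inverse guards the
            # confounded terminal directions
            try:
                cov = np.linalg.pinv(-H, hermitian=True)
                d = np.diag(cov)
                se_logit = np.sqrt(np.where(d > 0, d, np.nan))
            except np.linalg.LinAlgError:
                pass
        slp = se_logit[: T - 1]
        slg = se_logit[T - 1 : 2 * (T - 1)]
        slo = se_logit[2 * (T - 1) :]

        def ok(se, values):
            return (np.isfinite(se) & (se < _LOGIT_WELL_CONSTRAINED_SE)
                    & (values > 1e-7) & (values < 1 - 1e-7))

        phi_ok = ok(slp, phi)
        gamma_ok = ok(slg, gamma)
        p_ok = ok(slo, p)
        # confounded terminal parameters are never reported as constrained
        phi_ok[-1] = False       # phi_{T-1} confounded with p_T
        gamma_ok[0] = False      # gamma_2 confounded with p_1
        p_ok[0] = p_ok[-1] = False
        return PradelResults(
            phi=phi, gamma=gamma, p=p,
            se_phi=slp * phi * (1 - phi),
            se_gamma=slg * gamma * (1 - gamma),
            se_p=slo * p * (1 - p),
            se_logit_phi=slp, se_logit_gamma=slg, se_logit_p=slo,
            loglik=-best.fun, converged=bool(best.success or n_ok > 0),
            phi_ok=phi_ok, gamma_ok=gamma_ok, p_ok=p_ok,
            stage_names=self.matrix.stage_names, n_starts_converged=n_ok,
        )


def pradel_loglik(phi, gamma, p, matrix: DetectionMatrix) -> float:
    """Log-likelihood of the seniority model at given probability values.

    ``phi`` and ``gamma`` have length T-1 (gamma indexed at occasions 2..T),
    ``p`` length T.
    """
    return PradelSeniority(matrix).loglike_probs(phi, gamma, p)


def pradel_fit(matrix: DetectionMatrix, **kwargs) -> PradelResults:
    """Functional wrapper: ``PradelSeniority(matrix).fit(**kwargs)``."""
    return PradelSeniority(matrix).fit(**kwargs)


# ---------------------------------------------------------------------------
# probability -> instantaneous rate transforms


def to_instantaneous_rates(
    results: PradelResults,
    stage_table: StageTable,
    clade_label: str = "",
    include_unconstrained: bool = False,
    boundary_dt: str = "exposure",
) -> dict[str, RateSeries]:
    """Per-Myr instantaneous rates from the fitted interval probabilities.

    * extinction rate at boundary i = -ln(phi_i)/dt
    * origination rate at boundary i = -ln(gamma at occasion i+1)/dt
      (entering-cohort convention)
    * sampling rate in stage i = -ln(1 - p_i)/(stage i duration)

    ``boundary_dt`` selects the effective interval for the boundary
    probabilities.  The default ``exposure`` matches each probability to the
    stage over which its event accumulates when occasions are stage
    presences: a genus present in stage i persists into stage i+1 by
    surviving stage i, so survival across boundary i is exposed over stage
    i's duration, while a genus new to stage i+1 originated within it, so
    seniority at boundary i is exposed over stage i+1's duration.  ``mean``
    divides both by the mean of the two adjacent durations; with unequal
    stages that injects a deterministic log(duration ratio) artifact into
    every clade's rate series (the same pattern in each clade, which
    manufactures spurious between-series correlation downstream), so it is
    provided only for sensitivity.

    SEs follow by the delta method and the series values are returned
    log-transformed (per-point SE of the log rate).  Points that are not
    well-constrained, or whose probability sits on a boundary (rate 0 or
    infinite), are dropped.
    """
    if len(results.p) != len(stage_table):
        raise ValueError("results and stage table disagree on occasion count")
    durations = stage_table.durations
    if boundary_dt == "exposure":
        dt_ext = durations[:-1]   # survival across boundary i: stage i
        dt_orig = durations[1:]   # seniority at boundary i: stage i+1
    elif boundary_dt == "mean":
        dt_ext = dt_orig = stage_table.boundary_durations()
    else:
        raise ValueError(f"unknown boundary_dt {boundary_dt!r}")
    bound_ages = stage_table.boundary_ages
    out: dict[str, RateSeries] = {}

    def series(prob, se_prob, okmask, dt, ages, kind):
        times, vals, ses = [], [], []
        for i in range(prob.size):
            if not okmask[i] and not include_unconstrained:
                continue
            q = prob[i]
            if not 0 < q < 1:
                continue
            rate = -np.log(q) / dt[i] if kind != "sampling" else -np.log1p(-q) / dt[i]
            if rate <= 0:
                continue
            se_rate = (se_prob[i] / (q * dt[i]) if kind != "sampling"
                       else se_prob[i] / ((1 - q) * dt[i]))
            times.append(-ages[i])
            vals.append(np.log(rate))
            se_log = se_rate / rate if se_rate > 0 else np.nan
            ses.append(se_log)
        order = np.argsort(times)
        t = np.asarray(times)[order]
        v = np.asarray(vals)[order]
        s = np.asarray(ses)[order]
        keep = np.isfinite(s) & (s > 0)
        label = f"{clade_label}:{kind}" if clade_label else kind
        return RateSeries(times=t[keep], values=v[keep], ses=s[keep], label=label)

    out["extinction"] = series(results.phi, results.se_phi, results.phi_ok,
                               dt_ext, bound_ages, "extinction")
    out["origination"] = series(results.gamma, results.se_gamma,
                                results.gamma_ok, dt_orig, bound_ages,
                                "origination")
    out["sampling"] = series(results.p, results.se_p, results.p_ok,
                             stage_table.durations, stage_table.midpoints,
                             "sampling")
    return out
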