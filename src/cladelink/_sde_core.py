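"""Compiled numerics for the linear-SDE link models.

Closed-form 2x2 matrix exponential and Lyapunov solves, plus the exact
Gaussian (Kalman) filter likelihood on an irregular merged time grid with
partial observations.  These run ~10^4 times per evidence estimate, hence the
@njit compilation; everything here is plain scalar algebra with no Python
objects.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)
NEG_INF = -1.0e300


@njit(cache=False)
def expm2(m11, m12, m21, m22):
    """exp(M) for a real 2x2 matrix via the Cayley-Hamilton closed form."""
    tau = 0.5 * (m11 + m22)
    det = m11 * m22 - m12 * m21
    q2 = tau * tau - det
    if q2 > 1e-12:
        q = math.sqrt(q2)
        c = math.cosh(q)
        s = math.sinh(q) / q
    elif q2 < -1e-12:
        w = math.sqrt(-q2)
        c = math.cos(w)
        s = math.sin(w) / w
    else:  # defective/near-defective: second-order series in q2
        c = 1.0 + q2 / 2.0
        s = 1.0 + q2 / 6.0
    e = math.exp(tau)
    return (
        e * (c + s * (m11 - tau)),
        e * s * m12,
        e * s * m21,
        e * (c + s * (m22 - tau)),
    )


@njit(cache=False)
def lyap2(a11, a12, a21, a22, c11, c12, c22):
    """Solve A S + S A^T = C for symmetric S (A with positive-real-part
    eigenvalues; C symmetric).  Returns (s11, s12, s22).

    Componentwise the system is
        2 a11 s11 + 2 a12 s12             = c11
        a21 s11 + (a11+a22) s12 + a12 s22 = c12
                  2 a21 s12 + 2 a22 s22   = c22
    solved by Cramer's rule; det = 4 (a11+a22) det(A).
    """
    t = a11 + a22
    det_a = a11 * a22 - a12 * a21
    det = 4.0 * t * det_a
    if det == 0.0:
        return (np.nan, np.nan, np.nan)
    d1 = c11 * (2.0 * a22 * t - 2.0 * a12 * a21) - 2.0 * a12 * (
        2.0 * a22 * c12 - a12 * c22
    )
    d2 = 2.0 * a11 * (2.0 * a22 * c12 - a12 * c22) - 2.0 * a21 * a22 * c11
    d3 = (
        2.0 * a11 * (t * c22 - 2.0 * a21 * c12)
        - 2.0 * a12 * a21 * c22
        + 2.0 * a21 * a21 * c11
    )
    return (d1 / det, d2 / det, d3 / det)


@njit(cache=False)
def kalman2(
    a11, a12, a21, a22, c11, c12, c22, mu1, mu2,
    times, code, y1, y2, se1, se2,
):
    """Exact Gaussian log-likelihood of a bivariate OU observed with noise.

    ``code[k]`` = 1 (series 1 only), 2 (series 2 only) or 3 (both observed)
    at ``times[k]``.  Drift is dX = -A(X - mu)dt, diffusion covariance C;
    the filter starts from the stationary law.  Returns -1e300 for a
    non-stationary drift or numerical breakdown.
    """
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    if not (tr > 0.0 and det > 0.0):
        return NEG_INF
    s11, s12, s22 = lyap2(a11, a12, a21, a22, c11, c12, c22)
    if not (np.isfinite(s11) and np.isfinite(s22)) or s11 <= 0.0 or s22 <= 0.0:
        return NEG_INF

    x1 = mu1
    x2 = mu2
    p11, p12, p22 = s11, s12, s22
    ll = 0.0
    n = times.shape[0]
    for k in range(n):
        if k > 0:
            dt = times[k] - times[k - 1]
            f11, f12, f21, f22 = expm2(-a11 * dt, -a12 * dt, -a21 * dt, -a22 * dt)
            # mean: mu + F (x - mu)
            d1 = x1 - mu1
            d2 = x2 - mu2
            x1 = mu1 + f11 * d1 + f12 * d2
            x2 = mu2 + f21 * d1 + f22 * d2
            # covariance: F (P - S) F^T + S  (exact OU dispersion identity)
            e11 = p11 - s11
            e12 = p12 - s12
            e22 = p22 - s22
            t11 = f11 * e11 + f12 * e12
            t12 = f11 * e12 + f12 * e22
            t21 = f21 * e11 + f22 * e12
            t22 = f21 * e12 + f22 * e22
            p11 = t11 * f11 + t12 * f12 + s11
            p12 = t11 * f21 + t12 * f22 + s12
            p22 = t21 * f21 + t22 * f22 + s22
        c = code[k]
        if c == 3:
            r1 = se1[k] * se1[k]
            r2 = se2[k] * se2[k]
            v11 = p11 + r1
            v12 = p12
            v22 = p22 + r2
            dv = v11 * v22 - v12 * v12
            if dv <= 0.0 or v11 <= 0.0:
                return NEG_INF
            i1 = y1[k] - x1
            i2 = y2[k] - x2
            quad = (v22 * i1 * i1 - 2.0 * v12 * i1 * i2 + v11 * i2 * i2) / dv
            ll += -LOG2PI - 0.5 * math.log(dv) - 0.5 * quad
            # gain K = P V^{-1}
            k11 = (p11 * v22 - p12 * v12) / dv
            k12 = (-p11 * v12 + p12 * v11) / dv
            k21 = (p12 * v22 - p22 * v12) / dv
            k22 = (-p12 * v12 + p22 * v11) / dv
            x1 += k11 * i1 + k12 * i2
            x2 += k21 * i1 + k22 * i2
            n11 = (1.0 - k11) * p11 - k12 * p12
            n12 = (1.0 - k11) * p12 - k12 * p22
            n21 = -k21 * p11 + (1.0 - k22) * p12
            n22 = -k21 * p12 + (1.0 - k22) * p22
            p11 = n11
            p12 = 0.5 * (n12 + n21)
            p22 = n22
        elif c == 1:
            s = p11 + se1[k] * se1[k]
            if s <= 0.0:
                return NEG_INF
            i1 = y1[k] - x1
            ll += -0.5 * (LOG2PI + math.log(s) + i1 * i1 / s)
            g1 = p11 / s
            g2 = p12 / s
            x1 += g1 * i1
            x2 += g2 * i1
            p22 = p22 - g2 * p12
            p12 = p12 - g1 * p12
            p11 = p11 - g1 * p11
        elif c == 2:
            s = p22 + se2[k] * se2[k]
            if s <= 0.0:
                return NEG_INF
            i2 = y2[k] - x2
            ll += -0.5 * (LOG2PI + math.log(s) + i2 * i2 / s)
            g1 = p12 / s
            g2 = p22 / s
            x1 += g1 * i2
            x2 += g2 * i2
            p11 = p11 - g1 * p12
            p12 = p12 - g2 * p12
            p22 = p22 - g2 * p22
        if not np.isfinite(ll):
            return NEG_INF
    return ll


@njit(cache=False)
def kalman1(mu, alpha, c, times, y, se):
    """Univariate OU-plus-noise log-likelihood (c is the diffusion variance)."""
    if alpha <= 0.0 or c <= 0.0:
        return NEG_INF
    svar = c / (2.0 * alpha)
    x = mu
    p = svar
    ll = 0.0
    n = times.shape[0]
    for k in range(n):
        if k > 0:
            dt = times[k] - times[k - 1]
            f = math.exp(-alpha * dt)
            x = mu + f * (x - mu)
            p = f * f * (p - svar) + svar
        s = p + se[k] * se[k]
        if s <= 0.0:
            return NEG_INF
        innov = y[k] - x
        ll += -0.5 * (LOG2PI + math.log(s) + innov * innov / s)
        g = p / s
        x += g * innov
        p -= g * p
    return ll if np.isfinite(ll) else NEG_INF
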