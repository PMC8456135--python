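"""Within-assemblage species proportions and their temporal trend.

Each locality/horizon contributes one proportion of cheilostome (vs
cyclostome) species at its age-range midpoint.  The trend through time is
estimated two ways — locally weighted quadratic regression (tricube kernel,
nearest-neighbour span) and a penalized cubic smoothing spline with the
penalty chosen by generalized cross-validation — and the crossover age is the
age at which the smoothed cheilostome proportion first exceeds the cyclostome
proportion.

The smoothing spline solves the classic penalized least-squares problem
min Σ wᵢ(yᵢ − f(xᵢ))² + λ∫f″² over natural cubic splines via the
Reinsch/Green–Silverman banded matrices; scipy's equivalent-criterion
smoother is used as an independent cross-check in the test suite.  We carry
our own solver because the confidence bands and the GCV trace require the
explicit linear smoother matrix, which library smoothers do not expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .series import RateSeries
from .stages import StageTable

__all__ = [
    "AssemblageRecord",
    "SmoothedCurve",
    "load_assemblages",
    "assemblages_from_occurrences",
    "filter_assemblages",
    "loess_smooth",
    "spline_smooth",
    "stage_mean_proportions",
    "crossover_age",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class AssemblageRecord:
    """One locality/horizon: species counts per clade and an age range (Ma)."""

    locality_id: str
    age_older: float
    age_younger: float
    n_cheilostome: int
    n_cyclostome: int

    def __post_init__(self) -> None:
        if self.age_older < self.age_younger:
            raise ValueError("age_older must be >= age_younger")
        if self.n_cheilostome < 0 or self.n_cyclostome < 0:
            raise ValueError("species counts must be non-negative")

    @property
    def age_mid(self) -> float:
        return (self.age_older + self.age_younger) / 2.0

    @property
    def n_total(self) -> int:
        return self.n_cheilostome + self.n_cyclostome

    @property
    def p_cheilostome(self) -> float:
        if self.n_total == 0:
            raise ValueError("proportion undefined for empty assemblage")
        return self.n_cheilostome / self.n_total

    @property
    def p_cyclostome(self) -> float:
        return 1.0 - self.p_cheilostome


@dataclass(frozen=True)
class SmoothedCurve:
    """A fitted trend with a pointwise 95% confidence band.

    ``ages`` are in Ma (decreasing toward the present is *not* required; the
    grid is stored sorted ascending).  ``method`` is ``loess`` or ``spline``;
    ``smoothing`` records the span or penalty actually used.
    """

    ages: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str
    smoothing: float

    def __post_init__(self) -> None:
        for name in ("ages", "fit", "lower", "upper"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.lower <= self.fit + 1e-12).all() or not (
            self.fit <= self.upper + 1e-12
        ).all():
            raise ValueError("confidence band must contain the fit")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_ma": self.ages, "fit": self.fit,
                             "lower95": self.lower, "upper95": self.upper})


# ---------------------------------------------------------------------------
# records


def load_assemblages(path) -> list[AssemblageRecord]:
    """Read an assemblage CSV: locality_id, age_older, age_younger, n_cheil, n_cycl."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    alias = {"n_cheil": "n_cheilostome", "n_cycl": "n_cyclostome"}
    for short, full in alias.items():
        if short in cols and full not in cols:
            cols[full] = cols[short]
    needed = ["locality_id", "age_older", "age_younger",
              "n_cheilostome", "n_cyclostome"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"assemblage file missing columns {missing}")
    return [
        AssemblageRecord(
            locality_id=str(row[cols["locality_id"]]),
            age_older=float(row[cols["age_older"]]),
            age_younger=float(row[cols["age_younger"]]),
            n_cheilostome=int(row[cols["n_cheilostome"]]),
            n_cyclostome=int(row[cols["n_cyclostome"]]),
        )
        for _, row in df.iterrows()
    ]


def assemblages_from_occurrences(records, stage_table: StageTable | None = None
                                 ) -> list[AssemblageRecord]:
    """Aggregate species-level occurrence records into assemblage counts.

    Genus-only records (no species name) are excluded from species counts.
    Each (locality_id, stage-or-range) pair becomes one assemblage; its age
    range is the stage's bounds (or the record's own range).
    """
    groups: dict[tuple, dict] = {}
    for rec in records:
        if rec.locality_id is None or rec.species is None:
            continue
        if rec.stage is not None:
            if stage_table is None:
                raise ValueError("stage_table required to resolve stage names")
            i = stage_table.index_of(rec.stage)
            older, younger = stage_table.older[i], stage_table.younger[i]
        else:
            older, younger = rec.age_older, rec.age_younger
        key = (rec.locality_id, older, younger)
        g = groups.setdefault(key, {"cheilostome": set(), "cyclostome": set()})
        g[rec.clade].add((rec.genus, rec.species))
    return [
        AssemblageRecord(
            locality_id=loc, age_older=older, age_younger=younger,
            n_cheilostome=len(g["cheilostome"]),
            n_cyclostome=len(g["cyclostome"]),
        )
        for (loc, older, younger), g in sorted(groups.items())
    ]


def filter_assemblages(
    records: Sequence[AssemblageRecord],
    min_species: int = 15,
    require_both: bool = True,
) -> list[AssemblageRecord]:
    """Keep assemblages with at least ``min_species`` total species and,
    if ``require_both``, at least one species of each clade."""
    if min_species < 0:
        raise ValueError("min_species must be >= 0")
    out = []
    for r in records:
        if r.n_total < min_species:
            continue
        if require_both and (r.n_cheilostome == 0 or r.n_cyclostome == 0):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# LOESS


def _loess_weights_row(x: np.ndarray, x0: float, k: int, degree: int
                       ) -> np.ndarray:
    """Row of the linear smoother: fit(x0) = row @ y."""
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    if h <= 0:
        w = (d == 0).astype(float)
    else:
        u = np.clip(d / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
    X = np.vander(x - x0, N=degree + 1, increasing=True)
    XtW = X.T * w
    beta_mat = np.linalg.pinv(XtW @ X) @ XtW
    return beta_mat[0]


def loess_smooth(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    eval_x=None,
    n_grid: int = 200,
) -> SmoothedCurve:
    """Locally weighted polynomial regression with tricube weights.

    At each evaluation point the fit is the weighted least-squares prediction
    of a degree-``degree`` polynomial over the ⌈span·n⌉ nearest neighbours.
    The 95% band uses the linear-smoother variance ‖l(x₀)‖²σ̂², with σ̂²
    estimated from the residual sum of squares corrected by the smoother's
    equivalent degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.unique(x).size < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct x values")
    k = max(int(np.ceil(span * n)), degree + 1)
    if k > n:
        raise ValueError("span window exceeds the number of points")

    # smoother matrix at the observed points -> residual scale estimate
    L = np.empty((n, n))
    for i in range(n):
        L[i] = _loess_weights_row(x, x[i], k, degree)
    resid = y - L @ y
    delta1 = n - 2.0 * np.trace(L) + np.einsum("ij,ij->", L, L)
    sigma2 = float(resid @ resid) / max(delta1, 1.0)

    if eval_x is None:
        grid = np.union1d(x, np.linspace(x.min(), x.max(), n_grid))
    else:
        grid = np.sort(np.asarray(eval_x, dtype=float))
        if grid.min() < x.min() - 1e-9 or grid.max() > x.max() + 1e-9:
            raise ValueError("evaluation grid must lie within the data range")
    fit = np.empty_like(grid)
    se = np.empty_like(grid)
    for j, x0 in enumerate(grid):
        row = _loess_weights_row(x, x0, k, degree)
        fit[j] = row @ y
        se[j] = np.sqrt(sigma2 * (row @ row))
    return SmoothedCurve(ages=grid, fit=fit, lower=fit - Z95 * se,
                         upper=fit + Z95 * se, method="loess", smoothing=span)


# ---------------------------------------------------------------------------
# smoothing spline


def _reinsch_matrices(x: np.ndarray):
    """Q (n x n-2) and R (n-2 x n-2) with penalty K = Q R^{-1} Q^T.

    fᵀKf = ∫f″² over natural cubic splines with knots x.  The smoother is
    evaluated through the Reinsch form A = I - λ W⁻¹Q(R + λ QᵀW⁻¹Q)⁻¹Qᵀ,
    which stays well-conditioned for arbitrarily large penalties (the naive
    (W + λK)⁻¹W solve does not).
    """
    n = x.size
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    return Q, R


def _collapse_duplicates(x: np.ndarray, y: np.ndarray):
    order = np.argsort(x)
    x, y = x[order], y[order]
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    ym = np.zeros(ux.size)
    np.add.at(ym, inv, y)
    ym /= counts
    return ux, ym, counts.astype(float)


def spline_smooth(x, y, penalty: float | str = "gcv",
                  eval_x=None, n_grid: int = 200) -> SmoothedCurve:
    """Cubic smoothing spline minimizing Σwᵢ(yᵢ−f(xᵢ))² + λ∫f″².

    Duplicate abscissae are collapsed to weighted means.  ``penalty='gcv'``
    selects λ by generalized cross-validation on a log-spaced grid refined by
    golden-section search; a numeric ``penalty`` is used as-is (0 interpolates
    the collapsed data).  The 95% band uses the explicit smoother matrix
    A(λ) = (W + λK)⁻¹W.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    ux, uy, w = _collapse_duplicates(x, y)
    m = ux.size
    if m < 4:
        raise ValueError("need at least 4 distinct x values")
    Q, R = _reinsch_matrices(ux)
    winv = 1.0 / w
    QtWinvQ = Q.T @ (winv[:, None] * Q)
    n = x.size

    def smoother(lam: float) -> np.ndarray:
        M = R + lam * QtWinvQ
        return np.eye(m) - lam * (winv[:, None] * Q) @ np.linalg.solve(M, Q.T)

    def gcv(lam: float) -> float:
        A = smoother(lam)
        f = A @ uy
        rss = float(w @ (uy - f) ** 2)
        tr = float(np.trace(A))
        return n * rss / (n - tr) ** 2 if n > tr else np.inf

    if penalty == "gcv":
        # scale-aware bracket: lambda in units of span^3
        span3 = (ux[-1] - ux[0]) ** 3
        grid = span3 * np.logspace(-9, 3, 25)
        scores = [gcv(l) for l in grid]
        i = int(np.argmin(scores))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda t: gcv(np.exp(t)),
                              bracket=None,
                              bounds=(np.log(lo), np.log(hi)),
                              method="bounded")
        lam = float(np.exp(res.x))
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be >= 0")

    A = smoother(lam)
    fknots = A @ uy
    resid_w = float(w @ (uy - fknots) ** 2)
    tr = float(np.trace(A))
    sigma2 = resid_w / max(n - tr, 1.0)

    spline = CubicSpline(ux, fknots, bc_type="natural")
    if eval_x is None:
        grid_x = np.union1d(ux, np.linspace(ux[0], ux[-1], n_grid))
    else:
        grid_x = np.sort(np.asarray(eval_x, dtype=float))
    fit = spline(grid_x)
    # variance of the fit at the knots; interpolate se to the grid
    cov_diag = np.einsum("ij,j,ij->i", A, 1.0 / w, A) * sigma2
    se_knots = np.sqrt(np.maximum(cov_diag, 0.0))
    se = np.interp(grid_x, ux, se_knots)
    return SmoothedCurve(ages=grid_x, fit=fit, lower=fit - Z95 * se,
                         upper=fit + Z95 * se, method="spline", smoothing=lam)


# ---------------------------------------------------------------------------
# stage means and crossover


def stage_mean_proportions(
    records: Sequence[AssemblageRecord], stage_table: StageTable
) -> dict[str, RateSeries]:
    """Per-stage mean within-assemblage proportions (records pre-filtered).

    Localities are binned by age-range midpoint.  The standard error is the
    sample sd/√n; a stage with a single locality gets the global median
    per-stage SE (a zero observation variance would be indefensible
    downstream).  Stages with no localities are absent.  Returns proportion
    series for both clades, time-stamped at stage midpoints (forward time).
    """
    per_stage: dict[int, list[float]] = {}
    for r in records:
        if r.n_total == 0:
            continue
        mid = min(max(r.age_mid, stage_table.younger[-1]), stage_table.older[0])
        per_stage.setdefault(stage_table.stage_of_age(mid), []).append(
            r.p_cyclostome
        )
    stages = sorted(per_stage)
    means, ses, times = [], [], []
    raw_ses = {}
    for i in stages:
        vals = np.asarray(per_stage[i])
        if vals.size > 1:
            raw_ses[i] = float(vals.std(ddof=1) / np.sqrt(vals.size))
    fallback = float(np.median(list(raw_ses.values()))) if raw_ses else 0.1
    for i in stages:
        vals = np.asarray(per_stage[i])
        means.append(float(vals.mean()))
        se = raw_ses.get(i, fallback)
        ses.append(se if se > 0 else fallback)
        times.append(-stage_table.midpoints[i])
    order = np.argsort(times)
    times = np.asarray(times)[order]
    means = np.asarray(means)[order]
    ses = np.asarray(ses)[order]
    return {
        "cyclostome": RateSeries(times=times, values=means, ses=ses,
                                 label="proportion:cyclostome"),
        "cheilostome": RateSeries(times=times, values=1.0 - means, ses=ses,
                                  label="proportion:cheilostome"),
    }


def crossover_age(curve_cheil: SmoothedCurve, curve_cycl: SmoothedCurve
                  ) -> list[float]:
    """Ages (Ma) where the smoothed cheilostome and cyclostome curves cross.

    Curves must share an evaluation grid; crossings are located by linear
    interpolation of the fitted difference between grid points.  Empty if the
    difference never changes sign.
    """
    if curve_cheil.ages.shape != curve_cycl.ages.shape or not np.allclose(
        curve_cheil.ages, curve_cycl.ages
    ):
        raise ValueError("curves must share an evaluation grid")
    ages = curve_cheil.ages
    diff = curve_cheil.fit - curve_cycl.fit
    out = []
    for i in range(diff.size - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            out.append(float(ages[i]))
        elif a * b < 0:
            frac = a / (a - b)
            out.append(float(ages[i] + frac * (ages[i + 1] - ages[i])))
    if diff[-1] == 0.0:
        out.append(float(ages[-1]))
    return sorted(set(round(v, 10) for v in out))
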