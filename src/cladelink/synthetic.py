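"""Synthetic fossil records, assemblages and linked series.

Generators that reproduce the statistical structure the estimators assume:

* a continuous-time birth-death process per genus with stage-varying rates
  and incomplete, residence-time-weighted stage-level sampling, yielding
  detection matrices plus the true richness/rate record;
* locality assemblages whose cheilostome:cyclostome species split follows a
  controllable temporal trend (logistic by default);
* paired time series drawn from the exact Gaussian transition law of any of
  the five link-model classes, observed with known noise;
* detection histories drawn directly from the seniority-model generative law
  (entry from the seniority-implied cohort sizes, survival, detection),
  for estimator validation.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .occurrences import DetectionMatrix
from .proportions import AssemblageRecord
from .sde import OUParams, ou_transition, stationary_cov, is_stable, _check_kind
from .series import TimeSeriesObs
from .stages import StageTable, default_stage_table

__all__ = [
    "BDSimConfig",
    "AssemblageSimConfig",
    "FossilRecordSim",
    "simulate_fossil_record",
    "simulate_assemblages",
    "simulate_linked_series",
    "simulate_pradel_histories",
    "logistic_trend",
]


# ---------------------------------------------------------------------------
# birth-death fossil record


@dataclass(frozen=True)
class BDSimConfig:
    """Birth-death + sampling configuration for one or two clades.

    ``origination`` / ``extinction`` map clade -> per-stage per-capita rates
    (per Myr, piecewise constant within each stage); ``sampling`` maps clade
    -> per-stage sampling rates r_i (per Myr of residence time).  ``n0`` is
    the initial richness at the older edge of the table.
    """

    origination: Mapping[str, np.ndarray]
    extinction: Mapping[str, np.ndarray]
    sampling: Mapping[str, np.ndarray]
    n0: Mapping[str, int]
    stage_table: StageTable = field(default_factory=default_stage_table)
    seed: int = 0

    def __post_init__(self) -> None:
        T = len(self.stage_table)
        for name, m in (("origination", self.origination),
                        ("extinction", self.extinction),
                        ("sampling", self.sampling)):
            for clade, rates in m.items():
                r = np.asarray(rates, dtype=float)
                if r.shape != (T,) or (r < 0).any():
                    raise ValueError(
                        f"{name}[{clade}] must be {T} non-negative rates")
        for clade, n in self.n0.items():
            if n < 0:
                raise ValueError("n0 must be >= 0")


@dataclass(frozen=True)
class CladeTruth:
    """True (complete-record) state of one simulated clade."""

    birth_ages: np.ndarray   # Ma; birth at the older end of the span
    death_ages: np.ndarray   # Ma; 0.0 means extant at present
    richness_at_older_bound: np.ndarray  # standing richness at stage starts
    presence_richness: np.ndarray        # genera alive at any point in stage
    births_per_stage: np.ndarray
    deaths_per_stage: np.ndarray
    detected: np.ndarray     # bool per genus


@dataclass(frozen=True)
class FossilRecordSim:
    matrices: dict[str, DetectionMatrix]
    truth: dict[str, CladeTruth]
    config: BDSimConfig


def _simulate_clade(rng, stage_table: StageTable, lam, mu, n0):
    """Per-lineage continuous-time birth-death over the stage intervals.

    Returns (birth_ages, death_ages); a pending lineage is pushed through
    each stage with constant rates, branching spawning new lineages at their
    branch time.
    """
    older = np.asarray(stage_table.older)
    younger = np.asarray(stage_table.younger)
    T = len(stage_table)
    stack = [older[0]] * n0  # birth ages of unprocessed lineages
    births: list[float] = []
    deaths: list[float] = []
    while stack:
        if len(births) > 2_000_000:
            raise RuntimeError("birth-death simulation exploded; "
                               "check origination/extinction rates")
        birth = stack.pop()
        age = birth
        # walk the lineage forward (decreasing age) to extinction or present
        i = stage_table.stage_of_age(min(age, older[0]))
        death = 0.0
        while True:
            lo = younger[i]
            lam_i, mu_i = lam[i], mu[i]
            while True:
                total = lam_i + mu_i
                if total <= 0:
                    age = lo
                    break
                wait = rng.exponential(1.0 / total)
                if age - wait <= lo:
                    age = lo
                    break
                age -= wait
                if rng.random() < mu_i / total:
                    death = age
                    break
                stack.append(age)  # branching: new genus born now
            if death > 0.0:
                break
            if i == T - 1:
                death = 0.0  # extant
                break
            i += 1
        births.append(birth)
        deaths.append(death)
    return np.asarray(births), np.asarray(deaths)


def simulate_fossil_record(config: BDSimConfig) -> FossilRecordSim:
    """Simulate detection matrices and the underlying true record.

    Detection in stage i occurs with probability ``1 - exp(-r_i * o_i)``
    where ``o_i`` is the genus's residence time in the stage; genera never
    detected are dropped from the matrix but retained in the truth record.
    """
    rng = np.random.default_rng(config.seed)
    st = config.stage_table
    older = np.asarray(st.older)
    younger = np.asarray(st.younger)
    T = len(st)
    matrices: dict[str, DetectionMatrix] = {}
    truth: dict[str, CladeTruth] = {}
    for clade in config.n0:
        lam = np.asarray(config.origination[clade], dtype=float)
        mu = np.asarray(config.extinction[clade], dtype=float)
        r = np.asarray(config.sampling[clade], dtype=float)
        b_ages, d_ages = _simulate_clade(rng, st, lam, mu, config.n0[clade])
        n_gen = b_ages.size
        # residence time of each genus in each stage
        o = np.maximum(
            np.minimum(b_ages[:, None], older[None, :])
            - np.maximum(d_ages[:, None], younger[None, :]),
            0.0,
        )
        p_det = 1.0 - np.exp(-o * r[None, :])
        det = rng.random((n_gen, T)) < p_det
        detected = det.any(axis=1)
        if not detected.any():
            warnings.warn(f"clade {clade!r}: no genus was ever detected; "
                          "detection matrix is empty")
        genera = tuple(f"{clade}_g{i:05d}" for i in range(n_gen))
        matrices[clade] = DetectionMatrix(
            genera=tuple(g for g, d in zip(genera, detected) if d),
            data=det[detected].astype(np.uint8),
            clade=clade, stage_names=st.names,
        )
        at_bound = ((b_ages[:, None] >= older[None, :])
                    & (d_ages[:, None] < older[None, :]))
        presence = o > 0
        births_per = np.array([
            ((b_ages < older[i]) & (b_ages >= younger[i])).sum()
            for i in range(T)
        ])
        deaths_per = np.array([
            ((d_ages < older[i]) & (d_ages >= younger[i]) & (d_ages > 0)).sum()
            for i in range(T)
        ])
        truth[clade] = CladeTruth(
            birth_ages=b_ages, death_ages=d_ages,
            richness_at_older_bound=at_bound.sum(axis=0),
            presence_richness=presence.sum(axis=0),
            births_per_stage=births_per, deaths_per_stage=deaths_per,
            detected=detected,
        )
    return FossilRecordSim(matrices=matrices, truth=truth, config=config)


# ---------------------------------------------------------------------------
# assemblages


def logistic_trend(crossover_age_ma: float, slope_per_myr: float
                   ) -> Callable[[float], float]:
    """Cheilostome proportion rising through 0.5 at the crossover age."""

    def trend(age_ma: float) -> float:
        return 1.0 / (1.0 + np.exp(-slope_per_myr * (crossover_age_ma - age_ma)))

    return trend


@dataclass(frozen=True)
class AssemblageSimConfig:
    """Locality-assemblage generator settings.

    Each stage receives ``localities_per_stage`` localities at uniform ages;
    total species counts are negative-binomial(mean, dispersion) (dispersion
    = gamma shape; larger is closer to Poisson) and split binomially by the
    cheilostome-proportion trend evaluated at the locality age.
    """

    localities_per_stage: int = 30
    species_mean: float = 25.0
    species_dispersion: float = 5.0
    crossover_age_ma: float = 80.0
    slope_per_myr: float = 0.08
    trend: Callable[[float], float] | None = None
    age_halfwidth_myr: float = 0.25
    stage_table: StageTable = field(default_factory=default_stage_table)
    seed: int = 0

    def trend_fn(self) -> Callable[[float], float]:
        return self.trend or logistic_trend(self.crossover_age_ma,
                                            self.slope_per_myr)


def simulate_assemblages(config: AssemblageSimConfig) -> list[AssemblageRecord]:
    """Draw locality assemblages following the configured proportion trend."""
    rng = np.random.default_rng(config.seed)
    trend = config.trend_fn()
    st = config.stage_table
    out: list[AssemblageRecord] = []
    k = config.species_dispersion
    m = config.species_mean
    # negative binomial with mean m, shape k: p = k/(k+m)
    p_nb = k / (k + m)
    for i in range(len(st)):
        ages = rng.uniform(st.younger[i], st.older[i],
                           config.localities_per_stage)
        for j, age in enumerate(ages):
            total = 0
            while total < 2:  # an assemblage needs at least two species
                total = rng.negative_binomial(k, p_nb)
            p_che = float(np.clip(trend(age), 0.0, 1.0))
            n_che = rng.binomial(total, p_che)
            hw = config.age_halfwidth_myr
            out.append(AssemblageRecord(
                locality_id=f"loc_{st.names[i]}_{j:03d}",
                age_older=min(age + hw, st.older[0]),
                age_younger=max(age - hw, 0.0),
                n_cheilostome=int(n_che),
                n_cyclostome=int(total - n_che),
            ))
    return out


# ---------------------------------------------------------------------------
# linked series


def simulate_linked_series(
    kind: str,
    params: OUParams,
    times,
    obs_se,
    seed: int = 0,
    times2=None,
    obs_se2=None,
) -> tuple[TimeSeriesObs, TimeSeriesObs]:
    """Draw a pair of series from the exact transition law of a link model.

    ``times`` (and optionally a distinct ``times2`` for the second series)
    are strictly increasing forward-time stamps; the latent state is sampled
    sequentially from the exact Gaussian transition and observed with
    independent N(0, se^2) noise.  ``obs_se`` may be a scalar or per-point
    array.
    """
    _check_kind(kind)
    if not params.bivariate:
        raise ValueError("linked-series simulation needs bivariate params")
    if not is_stable(kind, params):
        raise ValueError("non-stationary parameters")
    rng = np.random.default_rng(seed)
    t1 = np.asarray(times, dtype=float)
    t2 = t1 if times2 is None else np.asarray(times2, dtype=float)
    for t in (t1, t2):
        if t.size >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
    merged = np.unique(np.concatenate([t1, t2]))
    mu = np.array([params.mu1, params.mu2])
    S = stationary_cov(kind, params)
    x = rng.multivariate_normal(mu, S)
    states = np.empty((merged.size, 2))
    states[0] = x
    for k in range(1, merged.size):
        phi, c, Q = ou_transition(kind, params, merged[k] - merged[k - 1])
        mean = phi @ states[k - 1] + c
        states[k] = rng.multivariate_normal(mean, Q)
    idx1 = np.searchsorted(merged, t1)
    idx2 = np.searchsorted(merged, t2)
    se1 = np.broadcast_to(np.asarray(obs_se, dtype=float), t1.shape).copy()
    se2_src = obs_se if obs_se2 is None else obs_se2
    se2 = np.broadcast_to(np.asarray(se2_src, dtype=float), t2.shape).copy()
    y1 = states[idx1, 0] + rng.normal(0.0, se1)
    y2 = states[idx2, 1] + rng.normal(0.0, se2)
    return (
        TimeSeriesObs(times=t1, values=y1, ses=se1, label="series1"),
        TimeSeriesObs(times=t2, values=y2, ses=se2, label="series2"),
    )


# ---------------------------------------------------------------------------
# seniority-model histories


def simulate_pradel_histories(phi, gamma, p, n_genera: int, seed: int = 0
                              ) -> np.ndarray:
    """Detection histories from the seniority model's generative law.

    ``phi``/``gamma`` are length T-1 (gamma indexed at occasions 2..T), ``p``
    length T.  Entry occasions are drawn from the entry mass implied by the
    seniority parameters via relative cohort sizes; lineages then survive
    each boundary with phi and are detected with p.  Returns the (m, T)
    0/1 array of the lineages detected at least once (m <= n_genera).
    """
    phi = np.asarray(phi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    p = np.asarray(p, dtype=float)
    T = p.size
    if phi.size != T - 1 or gamma.size != T - 1:
        raise ValueError("phi and gamma must have length T-1")
    rng = np.random.default_rng(seed)
    a = np.empty(T)
    a[0] = 1.0
    for t in range(1, T):
        a[t] = a[t - 1] * phi[t - 1] / gamma[t - 1]
    b = np.empty(T)
    b[0] = a[0]
    b[1:] = a[1:] * (1.0 - gamma)
    entry = rng.choice(T, size=n_genera, p=b / b.sum())
    X = np.zeros((n_genera, T), dtype=np.uint8)
    for g in range(n_genera):
        t = entry[g]
        while True:
            if rng.random() < p[t]:
                X[g, t] = 1
            if t == T - 1 or rng.random() >= phi[t]:
                break
            t += 1
    return X[X.any(axis=1)]
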