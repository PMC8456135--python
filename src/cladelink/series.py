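"""Time-series containers shared by the estimation and link-model layers.

All series live on the forward time axis ``t = -age`` (Myr, increasing toward
the present).  Points that could not be estimated are simply absent — never
imputed as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RateSeries", "TimeSeriesObs"]


def _validated(times, values, ses, *, positive_se: bool = True):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    s = np.asarray(ses, dtype=float)
    if not (t.shape == v.shape == s.shape) or t.ndim != 1:
        raise ValueError("times, values and ses must be equal-length 1-d arrays")
    if t.size >= 2 and not (np.diff(t) > 0).all():
        raise ValueError("time stamps must be strictly increasing")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    if positive_se and not (s > 0).all():
        raise ValueError("standard errors must be positive")
    return t, v, s


@dataclass(frozen=True)
class RateSeries:
    """Logged rate (or proportion) estimates with per-point standard errors.

    ``label`` identifies the quantity, e.g. ``cheilostome:extinction`` or
    ``proportion``.
    """

    times: np.ndarray
    values: np.ndarray
    ses: np.ndarray
    label: str

    def __post_init__(self) -> None:
        t, v, s = _validated(self.times, self.values, self.ses)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ses", s)

    def __len__(self) -> int:
        return self.times.size

    @property
    def ages_ma(self) -> np.ndarray:
        return -self.times

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_myr": self.times, "age_ma": -self.times,
             "value": self.values, "se": self.ses, "label": self.label}
        )


@dataclass(frozen=True)
class TimeSeriesObs:
    """Noisily observed series entering the SDE link models.

    Values are on the (logged) scale the models assume; ``ses`` are known
    observation-error standard deviations.  Two paired series need not share
    time stamps.
    """

    times: np.ndarray
    values: np.ndarray
    ses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t, v, s = _validated(self.times, self.values, self.ses)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ses", s)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_myr": self.times, "value": self.values, "se": self.ses}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "TimeSeriesObs":
        cols = {c.lower(): c for c in df.columns}
        if "time_ma" in cols:
            order = np.argsort(-df[cols["time_ma"]].to_numpy())
            df = df.iloc[order]
            times = -df[cols["time_ma"]].to_numpy(dtype=float)
        else:
            times = df[cols["time_myr"]].to_numpy(dtype=float)
        return cls(times=times, values=df[cols["value"]].to_numpy(dtype=float),
                   ses=df[cols["se"]].to_numpy(dtype=float), label=label)
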