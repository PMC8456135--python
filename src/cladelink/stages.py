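"""Geologic stage table: ordered time intervals with boundary ages.

Ages are in Ma before present.  The internal analysis time axis used by the
time-series machinery is forward time ``t = -age`` (Myr, increasing toward the
present), so that "X precedes Y" has its ordinary direction; conversions happen
at the module boundaries, never implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StageTable", "default_stage_table", "load_stage_table"]

# ICS boundary ages (Ma), Tithonian through the present.  The terminal interval
# merges the post-Calabrian Pleistocene with the Holocene so that the table has
# exactly 33 contiguous intervals spanning 152.1-0 Ma.
_DEFAULT_STAGES: list[tuple[str, float, float]] = [
    ("Tithonian", 152.1, 145.0),
    ("Berriasian", 145.0, 139.8),
    ("Valanginian", 139.8, 132.9),
    ("Hauterivian", 132.9, 129.4),
    ("Barremian", 129.4, 125.0),
    ("Aptian", 125.0, 113.0),
    ("Albian", 113.0, 100.5),
    ("Cenomanian", 100.5, 93.9),
    ("Turonian", 93.9, 89.8),
    ("Coniacian", 89.8, 86.3),
    ("Santonian", 86.3, 83.6),
    ("Campanian", 83.6, 72.1),
    ("Maastrichtian", 72.1, 66.0),
    ("Danian", 66.0, 61.6),
    ("Selandian", 61.6, 59.2),
    ("Thanetian", 59.2, 56.0),
    ("Ypresian", 56.0, 47.8),
    ("Lutetian", 47.8, 41.2),
    ("Bartonian", 41.2, 37.8),
    ("Priabonian", 37.8, 33.9),
    ("Rupelian", 33.9, 28.1),
    ("Chattian", 28.1, 23.03),
    ("Aquitanian", 23.03, 20.44),
    ("Burdigalian", 20.44, 15.97),
    ("Langhian", 15.97, 13.82),
    ("Serravallian", 13.82, 11.63),
    ("Tortonian", 11.63, 7.246),
    ("Messinian", 7.246, 5.333),
    ("Zanclean", 5.333, 3.6),
    ("Piacenzian", 3.6, 2.588),
    ("Gelasian", 2.588, 1.806),
    ("Calabrian", 1.806, 0.774),
    ("Pleistocene-Holocene", 0.774, 0.0),
]


@dataclass(frozen=True)
class StageTable:
    """Ordered, contiguous geologic intervals (oldest first).

    Parameters
    ----------
    names : tuple of str
        Interval names, oldest to youngest.
    older : tuple of float
        Older (lower) boundary age of each interval in Ma.
    younger : tuple of float
        Younger (upper) boundary age of each interval in Ma.
    """

    names: tuple[str, ...]
    older: tuple[float, ...]
    younger: tuple[float, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.older) == len(self.younger)):
            raise ValueError("names, older and younger must have equal length")
        if len(self.names) == 0:
            raise ValueError("stage table is empty")
        for i, (o, y) in enumerate(zip(self.older, self.younger)):
            if not o > y:
                raise ValueError(
                    f"stage {self.names[i]!r}: older bound {o} must exceed "
                    f"younger bound {y}"
                )
        for i in range(len(self.names) - 1):
            if abs(self.younger[i] - self.older[i + 1]) > 1e-9:
                raise ValueError(
                    f"stages {self.names[i]!r} and {self.names[i + 1]!r} are "
                    "not contiguous"
                )
        object.__setattr__(
            self, "_index", {n.lower(): i for i, n in enumerate(self.names)}
        )
        if len(self._index) != len(self.names):
            raise ValueError("duplicate stage names")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def durations(self) -> np.ndarray:
        """Interval durations in Myr."""
        return np.asarray(self.older) - np.asarray(self.younger)

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoint ages in Ma."""
        return (np.asarray(self.older) + np.asarray(self.younger)) / 2.0

    @property
    def boundary_ages(self) -> np.ndarray:
        """Ages (Ma) of the internal boundaries between consecutive stages.

        Boundary ``i`` separates stage ``i`` from stage ``i+1``; length is
        ``len(self) - 1``.
        """
        return np.asarray(self.younger[:-1])

    def boundary_durations(self) -> np.ndarray:
        """Effective interval length (Myr) attached to each internal boundary.

        The mean of the two adjacent stage durations; used when converting
        boundary-crossing probabilities into per-Myr rates.
        """
        d = self.durations
        return (d[:-1] + d[1:]) / 2.0

    def index_of(self, name: str) -> int:
        """Resolve a stage name (case-insensitive) to its column index."""
        try:
            return self._index[name.strip().lower()]
        except KeyError:
            raise KeyError(f"unknown stage name: {name!r}") from None

    def stage_of_age(self, age_ma: float) -> int:
        """Index of the stage containing ``age_ma`` (Ma before present).

        Ages exactly on an internal boundary belong to the younger stage;
        the table span's endpoints are inclusive.
        """
        if age_ma > self.older[0] or age_ma < self.younger[-1]:
            raise ValueError(
                f"age {age_ma} Ma is outside the table span "
                f"[{self.younger[-1]}, {self.older[0]}]"
            )
        for i in range(len(self) - 1, -1, -1):
            if age_ma <= self.older[i]:
                if age_ma > self.younger[i] or i == len(self) - 1:
                    return i
        return 0  # pragma: no cover

    def stages_overlapping(self, older_ma: float, younger_ma: float) -> list[int]:
        """Indices of all stages overlapping the age range (half-open overlap)."""
        if older_ma < younger_ma:
            raise ValueError("older_ma must be >= younger_ma")
        out = []
        for i in range(len(self)):
            if min(older_ma, self.older[i]) - max(younger_ma, self.younger[i]) > 0:
                out.append(i)
        if not out:  # zero-width range sitting on a boundary
            out = [self.stage_of_age((older_ma + younger_ma) / 2.0)]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "older_ma": self.older,
                "younger_ma": self.younger,
                "duration_myr": self.durations,
                "midpoint_ma": self.midpoints,
            }
        )


def default_stage_table() -> StageTable:
    """The 33-interval Tithonian (152.1 Ma) to present stage table."""
    names, older, younger = zip(*_DEFAULT_STAGES)
    return StageTable(names=names, older=older, younger=younger)


def load_stage_table(path) -> StageTable:
    """Read a stage table from CSV with columns name, older_ma, younger_ma."""
    df = pd.read_csv(path)
    required = {"name", "older_ma", "younger_ma"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stage table file missing columns: {sorted(missing)}")
    return StageTable(
        names=tuple(str(n) for n in df["name"]),
        older=tuple(float(v) for v in df["older_ma"]),
        younger=tuple(float(v) for v in df["younger_ma"]),
    )
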