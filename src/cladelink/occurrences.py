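"""Occurrence data model and I/O.

One row per fossil species (or genus-only) occurrence: taxon identity, clade,
locality, and a chronostratigraphic assignment given either as a stage name or
as an age range in Ma.  From validated records this module builds the binary
genus x stage detection matrices consumed by the capture-mark-recapture
estimators, and computes range-through richness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stages import StageTable

__all__ = [
    "CLADES",
    "OccurrenceRecord",
    "SynonymyMap",
    "DetectionMatrix",
    "load_occurrence_table",
    "load_synonymy",
    "apply_synonymy",
    "build_detection_matrix",
    "range_through_richness",
]

CLADES = ("cheilostome", "cyclostome")
SOURCE_DBS = ("foslocal", "ageonly")


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single occurrence: who, where, when.

    ``species`` is None for genus-only records (they count toward genus
    detection but never toward assemblage species counts).  Exactly one of
    ``stage`` or the age range (``age_older``, ``age_younger``) is set; stage
    resolution for ranged records is deferred to matrix construction.
    """

    genus: str
    species: str | None
    clade: str
    locality_id: str | None
    source_db: str = "foslocal"
    stage: str | None = None
    age_older: float | None = None
    age_younger: float | None = None

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}; expected one of {CLADES}")
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        has_stage = self.stage is not None
        has_range = self.age_older is not None and self.age_younger is not None
        if has_stage == has_range:
            raise ValueError("exactly one of stage or age range must be given")
        if has_range and self.age_older < self.age_younger:
            raise ValueError("age_older must be >= age_younger")


class SynonymyMap:
    """Mapping (clade, name) -> accepted name; accepted names map to themselves.

    The map must be resolved after a single application: an accepted name may
    not itself be a synonym of something else, and synonymy never crosses
    clades.
    """

    def __init__(self, entries: dict[tuple[str, str], str] | None = None):
        self._map: dict[tuple[str, str], str] = {}
        for (clade, name), accepted in (entries or {}).items():
            self.add(clade, name, accepted)

    def add(self, clade: str, name: str, accepted: str) -> None:
        if clade not in CLADES:
            raise ValueError(f"unknown clade {clade!r}")
        key = (clade, name)
        if name != accepted and any(
            v == name and k != key for k, v in self._map.items()
            if k[0] == clade
        ):
            raise ValueError(
                f"{name!r} ({clade}) is already an accepted name; synonymy "
                "chains are not allowed"
            )
        if key in self._map and self._map[key] != accepted:
            raise ValueError(f"conflicting synonymy for {key}: "
                             f"{self._map[key]!r} vs {accepted!r}")
        self._map[key] = accepted
        # keep one-application idempotence: accepted names are fixed points
        tgt = (clade, accepted)
        if self._map.get(tgt, accepted) != accepted:
            raise ValueError(
                f"accepted name {accepted!r} ({clade}) is itself mapped to "
                f"{self._map[tgt]!r}; chains are not allowed"
            )
        self._map.setdefault(tgt, accepted)

    def resolve(self, clade: str, name: str) -> str:
        return self._map.get((clade, name), name)

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class DetectionMatrix:
    """Binary genus x stage observation histories for one clade.

    Rows are genera, columns follow the StageTable order; entry 1 means the
    genus was observed at least once in that stage.  Every row has at least
    one detection.
    """

    genera: tuple[str, ...]
    data: np.ndarray  # (n_genera, n_stages) uint8
    clade: str
    stage_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2 or data.shape != (len(self.genera), len(self.stage_names)):
            raise ValueError("detection matrix shape mismatch")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("detection matrix entries must be 0/1")
        if (data.sum(axis=1) == 0).any():
            raise ValueError("every genus must have at least one detection")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    @property
    def n_stages(self) -> int:
        return len(self.stage_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.genera),
                            columns=list(self.stage_names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, clade: str) -> "DetectionMatrix":
        return cls(
            genera=tuple(str(g) for g in df.index),
            data=df.to_numpy(),
            clade=clade,
            stage_names=tuple(str(c) for c in df.columns),
        )


def _normalize(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    return s if s else None


def load_occurrence_table(
    path, stage_table: StageTable, *, deduplicate: bool = False
) -> list[OccurrenceRecord]:
    """Read a delimited occurrence table into validated records.

    The file must carry a header with columns ``genus``, ``clade`` and either
    ``stage`` or ``age_older``/``age_younger``; ``species``, ``locality_id``
    and ``source_db`` are optional.  Delimiter (comma or tab) is sniffed.
    Stage names resolve case-insensitively against ``stage_table``.  With
    ``deduplicate`` the fully identical rows across source databases are
    collapsed (the merged-database overlap is otherwise kept as-is).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"occurrence file {path} contains no data rows")
    cols = {c.lower(): c for c in df.columns}
    for required in ("genus", "clade"):
        if required not in cols:
            raise ValueError(f"occurrence file missing column {required!r}")
    has_stage = "stage" in cols
    has_range = "age_older" in cols and "age_younger" in cols
    if not (has_stage or has_range):
        raise ValueError("occurrence file needs a stage column or an "
                         "age_older/age_younger pair")

    records: list[OccurrenceRecord] = []
    seen: set[tuple] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        clade = _normalize(row.get(cols["clade"]))
        if clade is None or clade.lower() not in CLADES:
            raise ValueError(f"row {pos}: unknown clade value {clade!r}")
        genus = _normalize(row.get(cols["genus"]))
        if genus is None:
            raise ValueError(f"row {pos}: missing genus")
        stage = _normalize(row.get(cols["stage"])) if has_stage else None
        age_older = age_younger = None
        if stage is not None:
            idx = stage_table._index.get(stage.lower())
            if idx is None:
                raise ValueError(f"row {pos}: unresolvable stage name {stage!r}")
            stage = stage_table.names[idx]
        elif has_range:
            try:
                age_older = float(row[cols["age_older"]])
                age_younger = float(row[cols["age_younger"]])
            except (TypeError, ValueError):
                raise ValueError(f"row {pos}: missing stage and unusable age range")
            span_old, span_young = stage_table.older[0], stage_table.younger[-1]
            if age_younger > span_old or age_older < span_young:
                raise ValueError(
                    f"row {pos}: age range {age_older}-{age_younger} Ma does "
                    "not overlap the stage table span"
                )
        else:
            raise ValueError(f"row {pos}: no stage assignment")
        source = "foslocal"
        if "source_db" in cols:
            source = (_normalize(row.get(cols["source_db"])) or "foslocal").lower()
        rec = OccurrenceRecord(
            genus=genus,
            species=_normalize(row.get(cols.get("species", ""), None))
            if "species" in cols else None,
            clade=clade.lower(),
            locality_id=_normalize(row.get(cols.get("locality_id", ""), None))
            if "locality_id" in cols else None,
            source_db=source,
            stage=stage,
            age_older=age_older,
            age_younger=age_younger,
        )
        if deduplicate:
            key = (rec.genus, rec.species, rec.clade, rec.locality_id,
                   rec.stage, rec.age_older, rec.age_younger)
            if key in seen:
                continue
            seen.add(key)
        records.append(rec)
    return records


def load_synonymy(path, clade: str) -> SynonymyMap:
    """Read a two-column CSV (name, accepted_name) for one clade."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "name" not in cols or "accepted_name" not in cols:
        raise ValueError("synonymy file needs columns name, accepted_name")
    m = SynonymyMap()
    for _, row in df.iterrows():
        m.add(clade, str(row[cols["name"]]).strip(),
              str(row[cols["accepted_name"]]).strip())
    return m


def apply_synonymy(
    records: Sequence[OccurrenceRecord], synonymy: SynonymyMap
) -> list[OccurrenceRecord]:
    """Replace genus names by accepted names and collapse duplicate rows.

    The collapse key is (accepted genus, species, stage-or-range, locality_id,
    source_db); renaming can therefore only merge rows, never split them.
    Applying the map twice is a no-op because accepted names are fixed points.
    """
    out: list[OccurrenceRecord] = []
    seen: set[tuple] = set()
    for rec in records:
        accepted = synonymy.resolve(rec.clade, rec.genus)
        rec = rec if accepted == rec.genus else replace(rec, genus=accepted)
        key = (rec.clade, rec.genus, rec.species, rec.stage, rec.age_older,
               rec.age_younger, rec.locality_id, rec.source_db)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def _record_stages(
    rec: OccurrenceRecord, stage_table: StageTable, policy: str
) -> list[int]:
    if rec.stage is not None:
        return [stage_table.index_of(rec.stage)]
    if policy == "midpoint-stage":
        mid = (rec.age_older + rec.age_younger) / 2.0
        mid = min(max(mid, stage_table.younger[-1]), stage_table.older[0])
        return [stage_table.stage_of_age(mid)]
    if policy == "all-overlapped-stages":
        older = min(rec.age_older, stage_table.older[0])
        younger = max(rec.age_younger, stage_table.younger[-1])
        return stage_table.stages_overlapping(older, younger)
    raise ValueError(f"unknown age resolution policy {policy!r}")


def build_detection_matrix(
    records: Iterable[OccurrenceRecord],
    stage_table: StageTable,
    clade: str,
    age_resolution_policy: str = "midpoint-stage",
) -> DetectionMatrix:
    """Binary genus x stage observation histories for one clade.

    Age-ranged records are assigned to the stage containing their range
    midpoint by default; the ``all-overlapped-stages`` policy instead marks
    every overlapped stage (sensitivity variant).
    """
    if clade not in CLADES:
        raise ValueError(f"unknown clade {clade!r}")
    hits: dict[str, set[int]] = {}
    for rec in records:
        if rec.clade != clade:
            continue
        hits.setdefault(rec.genus, set()).update(
            _record_stages(rec, stage_table, age_resolution_policy)
        )
    if not hits:
        raise ValueError(f"no occurrence records for clade {clade!r}")
    genera = tuple(sorted(hits))
    data = np.zeros((len(genera), len(stage_table)), dtype=np.uint8)
    for i, g in enumerate(genera):
        data[i, sorted(hits[g])] = 1
    return DetectionMatrix(genera=genera, data=data, clade=clade,
                           stage_names=stage_table.names)


def range_through_richness(matrix: DetectionMatrix) -> np.ndarray:
    """Per-stage genus counts assuming each genus spans first to last detection.

    The count at stage j is the number of genera whose first and last
    detections bracket j (inclusive).
    """
    data = matrix.data
    first = data.argmax(axis=1)
    last = data.shape[1] - 1 - data[:, ::-1].argmax(axis=1)
    counts = np.zeros(data.shape[1], dtype=int)
    for f, l in zip(first, last):
        counts[f : l + 1] += 1
    return counts
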