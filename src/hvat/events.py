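"""Domain types for raw clinical data and their delimited-text readers/writers.

The raw material of the pipeline is a long-format event table (one row per
dated clinical observation), a static per-patient table (demographics plus the
binary case/control outcome), and a concept vocabulary declaring which
concepts carry numerical values and how repeated values are aggregated within
a time interval.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RACES = ("White", "Black", "Other", "Unknown")
ETHNICITIES = ("Non-Hispanic", "Hispanic", "Unknown")
AGGREGATIONS = ("mean", "max", "none")

#: Name of the artificial summary concept; distinct from every clinical concept.
SPECIAL_CONCEPT = "[S]"


@dataclass(frozen=True)
class EventRecord:
    """One dated clinical observation for one patient.

    ``value`` is ``None`` for concepts without associated numerical values
    (diagnoses, medications, note titles); a real number for valued concepts
    such as lab tests, vitals or fitness measurements.
    """

    patient_id: str
    event_date: dt.date
    concept: str
    value: float | None = None


@dataclass(frozen=True)
class StaticRecord:
    """Non-longitudinal data for one patient.

    sex is coded female=1 / male=0; outcome is case=1 / control=0. The index
    date is the endpoint of the patient's observation window.
    """

    patient_id: str
    age: float
    sex: int
    race: str
    ethnicity: str
    outcome: int
    index_date: dt.date

    def __post_init__(self) -> None:
        if self.race not in RACES:
            raise ValueError(f"unknown race category {self.race!r}; expected one of {RACES}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"unknown ethnicity category {self.ethnicity!r}; expected one of {ETHNICITIES}"
            )
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded female=1 / male=0")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be coded case=1 / control=0")


class ConceptVocabulary:
    """Ordered clinical-concept vocabulary with a reserved summary concept.

    Index 0 is always the artificial concept ``[S]`` used by the sequence
    summary token; clinical concepts occupy contiguous indices 1..n.  Each
    clinical concept declares whether it carries values and, if so, how
    multiple values within one time interval are aggregated (``mean`` or
    ``max``); unvalued concepts use aggregation ``none``.
    """

    def __init__(self, entries: list[tuple[str, bool, str]]):
        names = [name for name, _, _ in entries]
        if SPECIAL_CONCEPT in names:
            raise ValueError(f"{SPECIAL_CONCEPT} is reserved and may not appear as a clinical concept")
        if len(set(names)) != len(names):
            raise ValueError("duplicate concept names in vocabulary")
        for name, has_values, agg in entries:
            if agg not in AGGREGATIONS:
                raise ValueError(f"concept {name!r}: unknown aggregation {agg!r}")
            if has_values and agg == "none":
                raise ValueError(f"valued concept {name!r} needs aggregation 'mean' or 'max'")
            if not has_values and agg != "none":
                raise ValueError(f"unvalued concept {name!r} must use aggregation 'none'")
        self._entries = list(entries)
        self._index = {SPECIAL_CONCEPT: 0}
        for i, (name, _, _) in enumerate(entries, start=1):
            self._index[name] = i

    # -- lookups ---------------------------------------------------------
    @property
    def special_index(self) -> int:
        return 0

    @property
    def concepts(self) -> list[str]:
        """Clinical concept names, in index order (excludes the special concept)."""
        return [name for name, _, _ in self._entries]

    @property
    def n_rows(self) -> int:
        """Number of embedding rows needed: clinical concepts plus the special one."""
        return len(self._entries) + 1

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self._entries)

    def index(self, name: str) -> int:
        return self._index[name]

    def name(self, index: int) -> str:
        if index == 0:
            return SPECIAL_CONCEPT
        return self._entries[index - 1][0]

    def has_values(self, name: str) -> bool:
        return self._entries[self._index[name] - 1][1]

    def aggregation(self, name: str) -> str:
        return self._entries[self._index[name] - 1][2]

    def valued_concepts(self) -> list[str]:
        return [name for name, hv, _ in self._entries if hv]

    def unvalued_concepts(self) -> list[str]:
        return [name for name, hv, _ in self._entries if not hv]

    def subset(self, keep: list[str]) -> "ConceptVocabulary":
        """Restricted vocabulary keeping only ``keep`` (original relative order)."""
        keep_set = set(keep)
        return ConceptVocabulary([e for e in self._entries if e[0] in keep_set])

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._entries, columns=["concept", "has_values", "aggregation"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConceptVocabulary":
        entries = [
            (str(r.concept), _parse_bool(r.has_values), str(r.aggregation))
            for r in frame.itertuples(index=False)
        ]
        return cls(entries)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ConceptVocabulary":
        return cls.from_frame(pd.read_csv(path))


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("1", "true", "yes")


@dataclass
class CohortSplit:
    """Disjoint, exhaustive patient partition into train/validation/test.

    Stratified by outcome so each subset has (up to rounding) equal case and
    control counts.
    """

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    _subsets: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def subset(self, name: str) -> list[str]:
        if name not in ("train", "validation", "test"):
            raise KeyError(name)
        if not self._subsets:
            for pid, s in self.assignment.items():
                self._subsets.setdefault(s, []).append(pid)
        return self._subsets.get(name, [])


def stratified_split(
    statics: list[StaticRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> CohortSplit:
    """Split a cohort into train/validation/test, stratified by outcome.

    Within each outcome class, validation and test sizes are
    ``floor(fraction * class size)``; the remainder goes to train.
    Deterministic for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for outcome in (0, 1):
        ids = sorted(s.patient_id for s in statics if s.outcome == outcome)
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        for pid in ids[:n_train]:
            assignment[pid] = "train"
        for pid in ids[n_train : n_train + n_val]:
            assignment[pid] = "validation"
        for pid in ids[n_train + n_val :]:
            assignment[pid] = "test"
    return CohortSplit(assignment=assignment, fractions=fractions, seed=seed)


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Comma-delimited with a header row; ISO-8601 dates.
# ---------------------------------------------------------------------------

def read_events(path, vocabulary: ConceptVocabulary) -> list[EventRecord]:
    """Read an events table, validating against the vocabulary.

    Rows whose concept is absent from the vocabulary are dropped (their count
    is logged).  An unparseable date, or a missing/non-numeric value for a
    valued concept, is a hard error naming the offending row.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str, "concept": str})
    required = {"patient_id", "date", "concept", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[EventRecord] = []
    dropped = 0
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is row 1
        concept = row.concept
        if concept not in vocabulary or concept == SPECIAL_CONCEPT:
            dropped += 1
            continue
        try:
            date = dt.date.fromisoformat(str(row.date))
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: unparseable date {row.date!r}") from exc
        if vocabulary.has_values(concept):
            try:
                value = float(row.value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}, row {i}: non-numeric value {row.value!r} for valued concept {concept!r}"
                ) from exc
            if np.isnan(value):
                raise ValueError(f"{path}, row {i}: missing value for valued concept {concept!r}")
        else:
            value = None
        records.append(EventRecord(str(row.patient_id), date, concept, value))
    if dropped:
        logger.info("read_events: dropped %d rows with concepts absent from the vocabulary", dropped)
    return records


def write_events(records: list[EventRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "date": [r.event_date.isoformat() for r in records],
            "concept": [r.concept for r in records],
            "value": [r.value if r.value is not None else "" for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_statics(path) -> list[StaticRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            index_date = dt.date.fromisoformat(str(row.index_date))
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: unparseable index_date {row.index_date!r}") from exc
        records.append(
            StaticRecord(
                patient_id=str(row.patient_id),
                age=float(row.age),
                sex=int(row.sex),
                race=str(row.race),
                ethnicity=str(row.ethnicity),
                outcome=int(row.outcome),
                index_date=index_date,
            )
        )
    return records


def write_statics(records: list[StaticRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "race": [r.race for r in records],
            "ethnicity": [r.ethnicity for r in records],
            "outcome": [r.outcome for r in records],
            "index_date": [r.index_date.isoformat() for r in records],
        }
    )
    frame.to_csv(path, index=False)
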