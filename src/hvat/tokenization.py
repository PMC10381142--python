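"""Clinical-token sequences: backward temporal indexing, per-interval
aggregation, value normalization, and the static-vector dummy coding.

A patient's longitudinal history within a time window is represented as a
sequence of *clinical tokens* ``(t, C, v)``: ``t`` is the 1-based index of the
fixed-length interval containing the event, counted backward from the index
date (latest interval = 1); ``C`` is the concept; ``v`` is the aggregated
numerical value for valued concepts and 0 otherwise.  A special summary token
``(0, S, 0)`` is prepended to every sequence; its transformer output summarises
the whole sequence, playing the role a classification token plays in masked
language models.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .events import ConceptVocabulary, EventRecord, StaticRecord, RACES, ETHNICITIES

logger = logging.getLogger(__name__)

#: Days per interval when "1 month" is the interval unit.
DAYS_PER_MONTH = 30.5


class ClinicalToken(NamedTuple):
    t: int
    concept: int  # index into the vocabulary; 0 is the special concept
    value: float


@dataclass
class TokenSequence:
    """One patient's token list; the special token (0, S, 0) sits at position 0."""

    patient_id: str
    tokens: list[ClinicalToken]
    window_start: dt.date
    index_date: dt.date
    interval_length: float

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def clinical_tokens(self) -> list[ClinicalToken]:
        return [tok for tok in self.tokens if tok.t > 0]


def assign_temporal_index(event_date: dt.date, index_date: dt.date, interval_length: float) -> int:
    """Backward temporal index of an event: ``floor(days_before / L) + 1``.

    The window is divided into equal intervals of ``interval_length`` days,
    numbered 1, 2, 3, ... from the latest (ending at the index date) to the
    earliest.  An event on the index date itself falls in interval 1; index 0
    is reserved for the special summary token.
    """
    if interval_length <= 0:
        raise ValueError("interval_length must be positive")
    days = (index_date - event_date).days
    if days < 0:
        raise ValueError(f"event date {event_date} is after index date {index_date}")
    return int(days // interval_length) + 1


def word_tokens(sentence: str) -> list[tuple[int, str]]:
    """Tokenize a sentence into (position, word) pairs, positions 1-based.

    The natural-language analogue of clinical tokenization: repeated words at
    different positions are distinct tokens, so "to go or not to go" yields
    six tokens over four distinct words.
    """
    return [(i, w) for i, w in enumerate(sentence.split(), start=1)]


def tokenize_patient(
    events: Iterable[EventRecord],
    static: StaticRecord,
    window_start: dt.date,
    interval_length: float,
    vocabulary: ConceptVocabulary,
) -> TokenSequence:
    """Convert one patient's in-window events into a clinical-token sequence.

    Events outside ``[window_start, index_date]`` are discarded.  Within each
    (interval, concept) group a single token is emitted: unvalued concepts get
    v = 0; valued concepts get the vocabulary-declared aggregate (mean or max)
    of the raw values.  Values stay raw here; normalization is a separate,
    training-set-fitted step.  Tokens are ordered by ascending (t, concept
    index) purely for reproducibility — the model reads order from t alone.
    """
    index_date = static.index_date
    groups: dict[tuple[int, int], list[float | None]] = {}
    for ev in events:
        if ev.patient_id != static.patient_id:
            raise ValueError(f"event for {ev.patient_id!r} passed with static record {static.patient_id!r}")
        if ev.event_date < window_start or ev.event_date > index_date:
            continue
        t = assign_temporal_index(ev.event_date, index_date, interval_length)
        groups.setdefault((t, vocabulary.index(ev.concept)), []).append(ev.value)

    tokens = [ClinicalToken(0, vocabulary.special_index, 0.0)]
    for (t, cidx) in sorted(groups):
        name = vocabulary.name(cidx)
        if vocabulary.has_values(name):
            values = [v for v in groups[(t, cidx)] if v is not None]
            if not values:
                raise ValueError(
                    f"patient {static.patient_id}: valued concept {name!r} has no values in interval {t}"
                )
            agg = vocabulary.aggregation(name)
            v = float(np.mean(values)) if agg == "mean" else float(np.max(values))
        else:
            v = 0.0
        tokens.append(ClinicalToken(t, cidx, v))
    return TokenSequence(static.patient_id, tokens, window_start, index_date, float(interval_length))


@dataclass
class NormalizationStats:
    """Per-concept mean/SD of aggregated token values, fitted on training data."""

    stats: dict[int, tuple[float, float]]  # concept index -> (mean, sd)

    def transform_value(self, concept: int, value: float) -> float:
        mean, sd = self.stats[concept]
        return (value - mean) / sd

    def inverse_value(self, concept: int, value: float) -> float:
        mean, sd = self.stats[concept]
        return value * sd + mean


def fit_normalization(
    train_sequences: Iterable[TokenSequence], vocabulary: ConceptVocabulary
) -> NormalizationStats:
    """Population mean/SD per valued concept over training-set token values.

    A valued concept with constant values gets SD 1 (it carries no scale); a
    valued concept absent from the training data gets (0, 1) with a warning.
    """
    values: dict[int, list[float]] = {vocabulary.index(c): [] for c in vocabulary.valued_concepts()}
    for seq in train_sequences:
        for tok in seq.tokens:
            if tok.concept in values and tok.t > 0:
                values[tok.concept].append(tok.value)
    stats: dict[int, tuple[float, float]] = {}
    for cidx, vals in values.items():
        if not vals:
            logger.warning(
                "valued concept %r absent from training data; using stats (0, 1)",
                vocabulary.name(cidx),
            )
            stats[cidx] = (0.0, 1.0)
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std())  # population convention
        stats[cidx] = (float(arr.mean()), sd if sd > 0 else 1.0)
    return NormalizationStats(stats)


def apply_normalization(seq: TokenSequence, stats: NormalizationStats) -> TokenSequence:
    """Z-score valued tokens; unvalued and special tokens pass through."""
    tokens = [
        ClinicalToken(tok.t, tok.concept, stats.transform_value(tok.concept, tok.value))
        if tok.t > 0 and tok.concept in stats.stats
        else tok
        for tok in seq.tokens
    ]
    return TokenSequence(seq.patient_id, tokens, seq.window_start, seq.index_date, seq.interval_length)


def encode_static(static: StaticRecord) -> np.ndarray:
    """Dummy-code a static record into the 7-vector
    [age, sex, Race_Black, Race_Other, Race_Unknown, Ethnicity_Hispanic, Ethnicity_Unknown]
    with White and Non-Hispanic as reference categories.  Age is raw years
    here; z-scoring of age happens at model-input time with training-set stats.
    """
    if static.race not in RACES:
        raise ValueError(f"unknown race {static.race!r}")
    if static.ethnicity not in ETHNICITIES:
        raise ValueError(f"unknown ethnicity {static.ethnicity!r}")
    return np.array(
        [
            static.age,
            static.sex,
            1.0 if static.race == "Black" else 0.0,
            1.0 if static.race == "Other" else 0.0,
            1.0 if static.race == "Unknown" else 0.0,
            1.0 if static.ethnicity == "Hispanic" else 0.0,
            1.0 if static.ethnicity == "Unknown" else 0.0,
        ],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# JSON-lines serialization: one object per patient.
# ---------------------------------------------------------------------------

def sequences_to_jsonl(sequences: Iterable[TokenSequence], path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(
                json.dumps(
                    {
                        "patient_id": seq.patient_id,
                        "window_start": seq.window_start.isoformat(),
                        "index_date": seq.index_date.isoformat(),
                        "interval_length": seq.interval_length,
                        "tokens": [[tok.t, tok.concept, tok.value] for tok in seq.tokens],
                    }
                )
                + "\n"
            )


def sequences_from_jsonl(path) -> list[TokenSequence]:
    out = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            out.append(
                TokenSequence(
                    patient_id=obj["patient_id"],
                    tokens=[ClinicalToken(int(t), int(c), float(v)) for t, c, v in obj["tokens"]],
                    window_start=dt.date.fromisoformat(obj["window_start"]),
                    index_date=dt.date.fromisoformat(obj["index_date"]),
                    interval_length=float(obj["interval_length"]),
                )
            )
    return out
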