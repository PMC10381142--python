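"""Shared fixtures: the canonical worked-example patient and small cohorts."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from hvat import (
    ConceptVocabulary,
    EventRecord,
    StaticRecord,
    tokenize_patient,
)


@pytest.fixture
def example_vocabulary() -> ConceptVocabulary:
    return ConceptVocabulary(
        [
            ("diabetes", False, "none"),
            ("hypertension", False, "none"),
            ("a-fib", False, "none"),
            ("calcium", True, "mean"),
            ("glucose", True, "mean"),
        ]
    )


@pytest.fixture
def example_static() -> StaticRecord:
    return StaticRecord("p1", 70.0, 0, "White", "Non-Hispanic", 0, dt.date(2012, 12, 31))


@pytest.fixture
def example_events() -> list[EventRecord]:
    """Two diagnoses in January, two valued labs in April, three diagnoses in
    October of a one-year window ending 2012-12-31."""
    d = dt.date
    return [
        EventRecord("p1", d(2012, 1, 19), "diabetes"),
        EventRecord("p1", d(2012, 1, 19), "hypertension"),
        EventRecord("p1", d(2012, 4, 15), "calcium", 9.5),
        EventRecord("p1", d(2012, 4, 15), "glucose", 199.0),
        EventRecord("p1", d(2012, 10, 8), "diabetes"),
        EventRecord("p1", d(2012, 10, 8), "hypertension"),
        EventRecord("p1", d(2012, 10, 8), "a-fib"),
    ]


@pytest.fixture
def example_sequence(example_events, example_static, example_vocabulary):
    return tokenize_patient(
        example_events, example_static, dt.date(2012, 1, 1), 30.5, example_vocabulary
    )


def make_toy_cohort(n_per_class: int = 30, seed: int = 0):
    """A tiny hand-rolled cohort where one concept separates the classes:
    cases carry 'riskmed', controls mostly don't."""
    rng = np.random.default_rng(seed)
    vocab = ConceptVocabulary(
        [("riskmed", False, "none"), ("noise", False, "none"), ("lab", True, "mean")]
    )
    index_date = dt.date(2019, 12, 31)
    statics, events = [], []
    for i in range(2 * n_per_class):
        outcome = 1 if i < n_per_class else 0
        pid = f"t{i:03d}"
        statics.append(
            StaticRecord(pid, float(rng.normal(70, 5)), int(rng.random() < 0.5),
                         "White", "Non-Hispanic", outcome, index_date)
        )
        day = int(rng.integers(1, 360))
        if (outcome == 1 and rng.random() < 0.9) or (outcome == 0 and rng.random() < 0.1):
            events.append(EventRecord(pid, index_date - dt.timedelta(days=day), "riskmed"))
        if rng.random() < 0.5:
            events.append(EventRecord(pid, index_date - dt.timedelta(days=day), "noise"))
        events.append(
            EventRecord(pid, index_date - dt.timedelta(days=day), "lab", float(rng.normal(10, 2)))
        )
    return events, statics, vocab


@pytest.fixture
def toy_cohort():
    return make_toy_cohort()
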