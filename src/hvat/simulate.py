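"""Synthetic case-control cohort generator.

Emulates the structure of a longitudinal EHR case-control study — irregular
visit times over a multi-year window, repeated unvalued concepts (diagnoses /
medications / note titles), valued concepts (fitness- and BMI-like measures),
and mildly informative demographics — with outcome signal planted at three
separately tunable levels:

* **presence**: designated signal concepts are present (anywhere in the
  window) with probability ``q * exp(presence_effect)`` in cases versus ``q``
  in controls, so the planted log prevalence ratio of whole-window presence is
  exactly ``presence_effect``;
* **timing**: an "early-marker" concept is equally prevalent in both groups,
  but in cases (with probability ``temporal_effect``) it occurs only in the
  older half of the window — only the temporal indices carry its signal;
* **values**: a designated valued concept is measured everywhere, but in
  cases its mean is shifted by ``value_effect`` SD units with a sign that
  flips between the older and the recent half of the window, so whole-window
  mean aggregates carry (asymptotically) no signal and only a time-resolved,
  value-aware model can use it.

The generator is the test bed for every claim about what the sequence model
can learn; its ground-truth parameters are returned for recovery checks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np

from .events import ConceptVocabulary, EventRecord, StaticRecord

INDEX_DATE = dt.date(2019, 12, 31)


@dataclass
class SimConfig:
    """Cohort design; defaults give a moderately sized, clearly learnable
    cohort with all three signal channels active."""

    n_cases: int = 1000
    n_controls: int = 1000
    n_unvalued_concepts: int = 20
    n_signal_concepts: int = 3
    n_valued_concepts: int = 2
    window_years: float = 5.0
    interval_length: float = 365.25
    visit_rate: float = 10.0
    concepts_per_visit: int = 3
    presence_effect: float = 0.7
    temporal_effect: float = 0.95
    value_effect: float = 1.5
    background_presence: float = 0.3
    marker_presence: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.visit_rate, self.window_years, self.interval_length) <= 0:
            raise ValueError("rates and lengths must be positive")
        if self.n_signal_concepts + 1 > self.n_unvalued_concepts:
            raise ValueError("need at least n_signal_concepts + 1 unvalued concepts")
        if not 0 <= self.temporal_effect <= 1:
            raise ValueError("temporal_effect is a probability")


@dataclass
class SimTruth:
    """Planted parameters, for estimator-recovery checks."""

    presence_logpr: dict[str, float] = field(default_factory=dict)
    early_marker: str = ""
    temporal_effect: float = 0.0
    valued_signal: str = ""
    value_effect: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _make_vocabulary(config: SimConfig) -> ConceptVocabulary:
    entries: list[tuple[str, bool, str]] = []
    for i in range(config.n_signal_concepts):
        entries.append((f"signal_{i:03d}", False, "none"))
    entries.append(("early_marker", False, "none"))
    n_background = config.n_unvalued_concepts - config.n_signal_concepts - 1
    for i in range(n_background):
        entries.append((f"background_{i:03d}", False, "none"))
    entries.append(("fitness", True, "mean"))
    for i in range(config.n_valued_concepts - 1):
        entries.append((f"biomarker_{i:03d}", True, "mean"))
    return ConceptVocabulary(entries)


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[EventRecord], list[StaticRecord], ConceptVocabulary, SimTruth]:
    """Draw a full cohort: events, statics, vocabulary and ground truth."""
    rng = np.random.default_rng(config.seed)
    vocab = _make_vocabulary(config)
    window_days = config.window_years * 365.25
    window_start = INDEX_DATE - dt.timedelta(days=int(np.ceil(window_days)))
    half_days = window_days / 2.0  # events older than this (days before index) = "older half"

    q0 = config.background_presence
    q_case_signal = min(q0 * float(np.exp(config.presence_effect)), 0.95)
    planted_logpr = float(np.log(q_case_signal / q0))

    truth = SimTruth(
        presence_logpr={
            f"signal_{i:03d}": planted_logpr for i in range(config.n_signal_concepts)
        },
        early_marker="early_marker",
        temporal_effect=config.temporal_effect,
        valued_signal="fitness",
        value_effect=config.value_effect,
    )

    events: list[EventRecord] = []
    statics: list[StaticRecord] = []
    outcomes = [1] * config.n_cases + [0] * config.n_controls
    signal_names = list(truth.presence_logpr)
    background_names = [c for c in vocab.unvalued_concepts()
                        if c not in truth.presence_logpr and c != "early_marker"]
    extra_valued = [c for c in vocab.valued_concepts() if c != "fitness"]

    for pidx, outcome in enumerate(outcomes):
        pid = f"p{pidx:06d}"
        is_case = outcome == 1

        # demographics: age carries a mild signal, the rest none
        age = rng.normal(71.0 if is_case else 70.0, 5.0)
        sex = int(rng.random() < 0.1)
        race = rng.choice(["White", "Black", "Other", "Unknown"], p=[0.70, 0.20, 0.05, 0.05])
        ethnicity = rng.choice(["Non-Hispanic", "Hispanic", "Unknown"], p=[0.90, 0.07, 0.03])
        statics.append(StaticRecord(pid, float(age), sex, str(race), str(ethnicity), outcome, INDEX_DATE))

        # visit process: Poisson count, uniform days-before-index
        n_visits = rng.poisson(config.visit_rate * config.window_years)
        if n_visits == 0:
            continue
        visit_days = rng.uniform(0.0, window_days, size=n_visits)  # days before index

        def date_of(days_before: float) -> dt.date:
            return INDEX_DATE - dt.timedelta(days=float(days_before))

        def emit(concept: str, days_before: float, value: float | None = None) -> None:
            events.append(EventRecord(pid, date_of(days_before), concept, value))

        def occurrence_days(pool: np.ndarray) -> np.ndarray:
            k = 1 + rng.poisson(0.5)
            return rng.choice(pool, size=min(k, len(pool)), replace=True)

        # presence-signal and background concepts: patient-level Bernoulli
        for name in signal_names:
            q = q_case_signal if is_case else q0
            if rng.random() < q:
                for days in occurrence_days(visit_days):
                    emit(name, days)
        for name in background_names:
            if rng.random() < q0:
                for days in occurrence_days(visit_days):
                    emit(name, days)

        # early marker: equally prevalent; timing differs in cases
        if rng.random() < config.marker_presence:
            old_half = visit_days[visit_days >= half_days]
            if is_case and rng.random() < config.temporal_effect and len(old_half) > 0:
                pool = old_half
            else:
                pool = visit_days
            for days in occurrence_days(pool):
                emit("early_marker", days)

        # valued signal concept: measured in everyone, time-varying shift in cases
        n_meas = 1 + rng.poisson(7.0)
        meas_days = rng.choice(visit_days, size=min(n_meas, len(visit_days)), replace=True)
        base, sd = 8.0, 2.0
        for days in meas_days:
            shift = 0.0
            if is_case:
                sign = 1.0 if days >= half_days else -1.0
                shift = sign * config.value_effect * sd
            emit("fitness", days, float(rng.normal(base + shift, sd)))

        # extra valued concepts: pure noise
        for name in extra_valued:
            n_meas = 1 + rng.poisson(3.0)
            for days in rng.choice(visit_days, size=min(n_meas, len(visit_days)), replace=True):
                emit(name, days, float(rng.normal(28.0, 4.0)))

    return events, statics, vocab, truth


def window_start_for(config: SimConfig) -> dt.date:
    """Common window start implied by the cohort design."""
    return INDEX_DATE - dt.timedelta(days=int(np.ceil(config.window_years * 365.25)))


def degrade_to_orderless(
    events: list[EventRecord],
    statics: list[StaticRecord],
    window_starts: dict[str, dt.date],
    seed: int = 0,
) -> list[EventRecord]:
    """Destroy temporal structure: each event's date is redrawn uniformly in
    its patient's window.  Per-patient presence counts and the multiset of
    values are conserved; only timing information is lost."""
    rng = np.random.default_rng(seed)
    index_dates = {s.patient_id: s.index_date for s in statics}
    out = []
    for ev in events:
        start = window_starts[ev.patient_id]
        span = (index_dates[ev.patient_id] - start).days
        new_date = start + dt.timedelta(days=float(rng.uniform(0, span)))
        out.append(EventRecord(ev.patient_id, new_date, ev.concept, ev.value))
    return out
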