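"""Feature ranking for binary presence/absence concepts.

Medications and note titles carry their information in whether they appear at
all in a patient's window.  Each such concept is scored by a continuity-
corrected log prevalence ratio (Walters estimator) penalized by its standard
error: ``score = |LogPR| - z_{alpha/2} * SE``.  The score equals the
confidence-interval limit nearer zero (sign-adjusted), so a positive score
means the prevalence ratio differs from 1 with statistical significance at
level 1 - alpha.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable

from scipy import stats as _st

from .events import EventRecord, StaticRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConceptStats:
    """Per-concept 2x2 counts and ranking quantities.

    a = cases with the concept present, b = controls with it present,
    m / n = total cases / controls.
    """

    concept: str
    a: int
    b: int
    m: int
    n: int
    log_pr: float
    se: float
    score: float


def contingency_counts(
    events: Iterable[EventRecord],
    statics: list[StaticRecord],
    concept: str,
    window_starts: dict[str, dt.date],
) -> tuple[int, int, int, int]:
    """(a, b, m, n) for one concept: presence = at least one in-window event."""
    outcome = {s.patient_id: s.outcome for s in statics}
    index_dates = {s.patient_id: s.index_date for s in statics}
    present: set[str] = set()
    for ev in events:
        pid = ev.patient_id
        if ev.concept != concept or pid not in outcome:
            continue
        if window_starts[pid] <= ev.event_date <= index_dates[pid]:
            present.add(pid)
    m = sum(1 for s in statics if s.outcome == 1)
    n = len(statics) - m
    a = sum(1 for pid in present if outcome[pid] == 1)
    b = len(present) - a
    return a, b, m, n


def walters_logpr(a: int, b: int, m: int, n: int) -> tuple[float, float]:
    """Continuity-corrected log prevalence ratio and its standard error.

    LogPR = ln(((a+0.5)/(m+0.5)) / ((b+0.5)/(n+0.5)));
    SE = sqrt(1/(a+0.5) - 1/(m+0.5) + 1/(b+0.5) - 1/(n+0.5)).
    Both are finite for all valid counts, including a = 0 or b = 0, thanks to
    the added 0.5.
    """
    if not (0 <= a <= m and 0 <= b <= n):
        raise ValueError(f"invalid counts a={a}, b={b}, m={m}, n={n}")
    log_pr = math.log(((a + 0.5) / (m + 0.5)) / ((b + 0.5) / (n + 0.5)))
    se = math.sqrt(1 / (a + 0.5) - 1 / (m + 0.5) + 1 / (b + 0.5) - 1 / (n + 0.5))
    return log_pr, se


def critical_value(alpha: float) -> float:
    """Two-sided standard-normal critical value z_{alpha/2}."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(_st.norm.ppf(1 - alpha / 2))


def ranking_score(log_pr: float, se: float, alpha: float = 0.05) -> float:
    """``|LogPR| - z_{alpha/2} * SE``.

    Equivalently: the lower confidence limit when LogPR >= 0, and -1 times the
    upper limit when LogPR < 0 — the CI limit nearer zero, sign-adjusted.
    """
    return abs(log_pr) - critical_value(alpha) * se


def score_concepts(
    events: Iterable[EventRecord],
    statics: list[StaticRecord],
    concepts: list[str],
    window_starts: dict[str, dt.date],
    alpha: float = 0.05,
) -> list[ConceptStats]:
    """Walters-score every concept on the given (training) patients."""
    events = list(events)
    out = []
    for concept in concepts:
        a, b, m, n = contingency_counts(events, statics, concept, window_starts)
        log_pr, se = walters_logpr(a, b, m, n)
        out.append(ConceptStats(concept, a, b, m, n, log_pr, se, ranking_score(log_pr, se, alpha)))
    return out


def select_top_k(stats: list[ConceptStats], k: int) -> list[str]:
    """Top-k concept names by score (descending).

    Ties break by |LogPR| descending, then name lexicographic.  If k exceeds
    the number of scored concepts, all are returned with a warning.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(stats):
        logger.warning("select_top_k: k=%d exceeds %d scored concepts; returning all", k, len(stats))
        k = len(stats)
    ranked = sorted(stats, key=lambda s: (-s.score, -abs(s.log_pr), s.concept))
    selected = ranked[:k]
    if selected and not all(s.score > 0 for s in selected):
        logger.info("select_top_k: some selected features have score <= 0 (LogPR not significant)")
    return [s.concept for s in selected]
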