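"""Temporal indexing, per-interval aggregation, normalization and the
static-vector dummy coding."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hvat import (
    ClinicalToken,
    EventRecord,
    StaticRecord,
    TokenSequence,
    apply_normalization,
    assign_temporal_index,
    encode_static,
    fit_normalization,
    tokenize_patient,
)
from hvat.tokenization import sequences_from_jsonl, sequences_to_jsonl, word_tokens
from hvat.events import ConceptVocabulary

D = dt.date
INDEX = D(2012, 12, 31)


class TestTemporalIndex:
    @pytest.mark.parametrize(
        "event_date,expected",
        [
            (D(2012, 10, 8), 3),
            (D(2012, 4, 15), 9),
            (D(2012, 1, 19), 12),
            (INDEX, 1),
        ],
    )
    def test_monthly_interval_examples(self, event_date, expected):
        assert assign_temporal_index(event_date, INDEX, 30.5) == expected

    def test_event_after_index_date_rejected(self):
        with pytest.raises(ValueError):
            assign_temporal_index(D(2013, 1, 1), INDEX, 30.5)

    @given(days=st.integers(0, 10_000), length=st.floats(1.0, 400.0))
    @settings(max_examples=200, deadline=None)
    def test_index_positive_and_monotone_in_days(self, days, length):
        t = assign_temporal_index(INDEX - dt.timedelta(days=days), INDEX, length)
        t_next = assign_temporal_index(INDEX - dt.timedelta(days=days + 1), INDEX, length)
        assert t >= 1
        assert t_next >= t


class TestTokenizePatient:
    def test_worked_example_reproduces_expected_tokens(self, example_sequence, example_vocabulary):
        named = {
            (tok.t, example_vocabulary.name(tok.concept), tok.value)
            for tok in example_sequence.clinical_tokens
        }
        assert named == {
            (3, "diabetes", 0.0),
            (3, "hypertension", 0.0),
            (3, "a-fib", 0.0),
            (9, "calcium", 9.5),
            (9, "glucose", 199.0),
            (12, "diabetes", 0.0),
            (12, "hypertension", 0.0),
        }
        assert example_sequence.tokens[0] == ClinicalToken(0, 0, 0.0)
        assert sum(1 for tok in example_sequence.tokens if tok.t == 0) == 1

    def test_repeated_concept_in_one_interval_collapses(self, example_vocabulary, example_static):
        events = [
            EventRecord("p1", D(2012, 10, 8), "diabetes"),
            EventRecord("p1", D(2012, 10, 9), "diabetes"),
        ]
        seq = tokenize_patient(events, example_static, D(2012, 1, 1), 30.5, example_vocabulary)
        assert len(seq.clinical_tokens) == 1

    def test_value_aggregation_mean_and_max(self, example_static):
        vocab = ConceptVocabulary([("bmi", True, "mean"), ("met", True, "max")])
        events = [
            EventRecord("p1", D(2012, 10, 8), "bmi", 20.0),
            EventRecord("p1", D(2012, 10, 9), "bmi", 30.0),
            EventRecord("p1", D(2012, 10, 8), "met", 5.0),
            EventRecord("p1", D(2012, 10, 9), "met", 8.0),
        ]
        seq = tokenize_patient(events, example_static, D(2012, 1, 1), 30.5, vocab)
        values = {vocab.name(t.concept): t.value for t in seq.clinical_tokens}
        assert values == {"bmi": 25.0, "met": 8.0}

    def test_no_events_leaves_only_special_token(self, example_vocabulary, example_static):
        seq = tokenize_patient([], example_static, D(2012, 1, 1), 30.5, example_vocabulary)
        assert seq.tokens == [ClinicalToken(0, 0, 0.0)]

    def test_out_of_window_events_discarded(self, example_vocabulary, example_static):
        events = [EventRecord("p1", D(2011, 12, 31), "diabetes")]
        seq = tokenize_patient(events, example_static, D(2012, 1, 1), 30.5, example_vocabulary)
        assert seq.clinical_tokens == []

    def test_token_count_equals_distinct_interval_concept_pairs(
        self, example_events, example_static, example_vocabulary
    ):
        seq = tokenize_patient(example_events, example_static, D(2012, 1, 1), 30.5, example_vocabulary)
        pairs = {
            (assign_temporal_index(e.event_date, INDEX, 30.5), e.concept) for e in example_events
        }
        assert len(seq.clinical_tokens) == len(pairs)

    def test_discussion_scale_arithmetic(self):
        """10 visits/year x 10 repeated concepts x 20 years: 2000 tokens at
        day-scale intervals, 200 at year-scale; quadratic-cost ratio 1%."""
        concepts = [(f"c{i}", False, "none") for i in range(10)]
        vocab = ConceptVocabulary(concepts)
        index_date = D(2019, 12, 31)
        static = StaticRecord("p1", 70.0, 0, "White", "Non-Hispanic", 0, index_date)
        events = []
        day = 0
        for year in range(20):
            for visit in range(10):
                date = index_date - dt.timedelta(days=year * 365 + visit * 36 + 1)
                events.extend(EventRecord("p1", date, f"c{i}") for i in range(10))
        daily = tokenize_patient(events, static, D(1999, 1, 1), 1.0, vocab)
        yearly = tokenize_patient(events, static, D(1999, 1, 1), 365.0, vocab)
        assert len(daily.clinical_tokens) == 2000
        assert len(yearly.clinical_tokens) == 200
        ratio = (len(yearly.clinical_tokens) / len(daily.clinical_tokens)) ** 2
        assert ratio == pytest.approx(0.01)

    def test_word_token_analogy(self):
        tokens = word_tokens("to go or not to go")
        assert len(tokens) == 6
        assert len({w for _, w in tokens}) == 4
        assert tokens[0] == (1, "to") and tokens[-1] == (6, "go")


class TestNormalization:
    def _seq(self, values, vocab, pid="p1"):
        toks = [ClinicalToken(0, 0, 0.0)] + [
            ClinicalToken(i + 1, vocab.index("lab"), v) for i, v in enumerate(values)
        ]
        return TokenSequence(pid, toks, D(2012, 1, 1), INDEX, 30.5)

    def test_two_point_stats(self):
        vocab = ConceptVocabulary([("lab", True, "mean")])
        stats = fit_normalization([self._seq([9.0, 11.0], vocab)], vocab)
        assert stats.stats[vocab.index("lab")] == (10.0, 1.0)

    def test_constant_concept_gets_unit_sd(self):
        vocab = ConceptVocabulary([("lab", True, "mean")])
        stats = fit_normalization([self._seq([5.0, 5.0], vocab)], vocab)
        assert stats.stats[vocab.index("lab")] == (5.0, 1.0)

    def test_absent_concept_gets_identity_stats(self):
        vocab = ConceptVocabulary([("lab", True, "mean"), ("other", True, "mean")])
        stats = fit_normalization([self._seq([1.0], vocab)], vocab)
        assert stats.stats[vocab.index("other")] == (0.0, 1.0)

    def test_apply_centers_and_scales(self):
        vocab = ConceptVocabulary([("lab", True, "mean")])
        stats = fit_normalization([self._seq([9.0, 11.0], vocab)], vocab)
        normed = apply_normalization(self._seq([10.0, 11.0], vocab), stats)
        assert [t.value for t in normed.clinical_tokens] == [0.0, 1.0]

    def test_unvalued_and_special_tokens_unchanged(self):
        vocab = ConceptVocabulary([("lab", True, "mean"), ("dx", False, "none")])
        seq = TokenSequence(
            "p1",
            [ClinicalToken(0, 0, 0.0), ClinicalToken(2, vocab.index("dx"), 0.0)],
            D(2012, 1, 1), INDEX, 30.5,
        )
        stats = fit_normalization([self._seq([1.0, 3.0], vocab)], vocab)
        assert apply_normalization(seq, stats).tokens == seq.tokens

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_normalization_is_invertible(self, values):
        vocab = ConceptVocabulary([("lab", True, "mean")])
        seq = self._seq(values, vocab)
        stats = fit_normalization([seq], vocab)
        normed = apply_normalization(seq, stats)
        cidx = vocab.index("lab")
        back = [stats.inverse_value(cidx, t.value) for t in normed.clinical_tokens]
        assert np.allclose(back, values, atol=1e-9 * (1 + np.max(np.abs(values))))


class TestStaticEncoding:
    def test_reference_categories_are_all_zero(self):
        s = StaticRecord("p", 70.0, 0, "White", "Non-Hispanic", 0, INDEX)
        assert encode_static(s).tolist() == [70.0, 0, 0, 0, 0, 0, 0]

    def test_dummy_positions(self):
        s = StaticRecord("p", 65.0, 1, "Black", "Hispanic", 1, INDEX)
        assert encode_static(s).tolist() == [65.0, 1, 1, 0, 0, 1, 0]

    def test_unknown_levels(self):
        s = StaticRecord("p", 80.0, 0, "Unknown", "Unknown", 0, INDEX)
        assert encode_static(s).tolist() == [80.0, 0, 0, 0, 1, 0, 1]

    def test_vector_dimension_is_seven(self):
        for race in ("White", "Black", "Other", "Unknown"):
            s = StaticRecord("p", 50.0, 1, race, "Hispanic", 1, INDEX)
            assert encode_static(s).shape == (7,)

    def test_invalid_category_rejected_at_construction(self):
        with pytest.raises(ValueError):
            StaticRecord("p", 70.0, 0, "Martian", "Non-Hispanic", 0, INDEX)


def test_jsonl_roundtrip_bit_exact(example_sequence, tmp_path):
    path = tmp_path / "seqs.jsonl"
    sequences_to_jsonl([example_sequence], path)
    (back,) = sequences_from_jsonl(path)
    assert back == example_sequence
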