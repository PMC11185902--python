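import numpy as np
import pytest

from soapeval.records import Section, Sentence
from soapeval.span_matching import (
    MatchType,
    Polarity,
    ScopeMismatchError,
    SpanSource,
    SpanValidationError,
    count_matches,
    match_corpus,
    match_spans,
    overlap_length,
    parse_inline_tagged,
    read_spans_tsv,
    spans_from_inline,
    write_spans_tsv,
)

from conftest import make_span, oracle_max_matching, random_disjoint_spans


class TestOverlapLength:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [((0, 4), (2, 6), 2), ((0, 2), (2, 4), 0), ((1, 3), (1, 3), 2), ((0, 9), (3, 5), 2)],
    )
    def test_interval_intersection(self, a, b, expected):
        assert overlap_length(make_span(*a), make_span(*b)) == expected

    def test_cross_sentence_comparison_is_a_bug(self):
        with pytest.raises(ScopeMismatchError):
            overlap_length(make_span(0, 4), make_span(0, 4, sentence_index=1))


class TestMatchSpans:
    def test_identical_spans_give_one_exact_pair(self):
        result = match_spans([make_span(0, 4)], [make_span(0, 4, source=SpanSource.SYSTEM)])
        assert len(result.pairs) == 1
        assert result.pairs[0].match_type is MatchType.EXACT
        assert result.pairs[0].polarity_agrees

    def test_one_system_span_covering_two_gold_counts_once(self):
        # counting in the units that minimize the matched-term total
        gold = [make_span(0, 4), make_span(5, 9)]
        system = [make_span(0, 9, source=SpanSource.SYSTEM)]
        result = match_spans(gold, system)
        assert len(result.pairs) == 1
        assert result.pairs[0].match_type is MatchType.PARTIAL
        assert len(result.unmatched_gold) == 1
        assert result.unmatched_system == []
        # leftmost-first tie-break pairs the covering span with the first gold
        assert result.pairs[0].gold.char_start == 0

    def test_repeated_surface_pairs_order_preservingly(self):
        gold = [make_span(0, 2, surface="痛み"), make_span(6, 8, surface="痛み")]
        system = [
            make_span(0, 2, surface="痛み", source=SpanSource.SYSTEM),
            make_span(6, 8, surface="痛み", source=SpanSource.SYSTEM),
        ]
        result = match_spans(gold, system)
        assert [(p.gold.char_start, p.system.char_start) for p in result.pairs] == [(0, 0), (6, 6)]
        assert all(p.match_type is MatchType.EXACT for p in result.pairs)

    def test_disjoint_spans_leave_both_unmatched(self):
        result = match_spans([make_span(0, 3)], [make_span(5, 8, source=SpanSource.SYSTEM)])
        assert result.pairs == []
        assert len(result.unmatched_gold) == 1
        assert len(result.unmatched_system) == 1

    def test_polarity_recorded_but_not_steering(self):
        gold = [make_span(0, 4, polarity=Polarity.POSITIVE)]
        system = [make_span(0, 4, polarity=Polarity.NEGATIVE, source=SpanSource.SYSTEM)]
        result = match_spans(gold, system)
        assert len(result.pairs) == 1
        assert not result.pairs[0].polarity_agrees

    def test_overlapping_same_source_spans_rejected(self):
        with pytest.raises(SpanValidationError):
            match_spans([make_span(0, 4), make_span(3, 6)], [])

    def test_surface_validated_against_sentence(self):
        sentence = Sentence("R0", Section.SUBJECTIVE, 0, "疼痛あり。", 0, 5)
        good = make_span(0, 2, surface="疼痛")
        bad = make_span(0, 2, surface="発熱")
        assert match_spans([good], [], sentence).unmatched_gold == [good]
        with pytest.raises(SpanValidationError, match="surface"):
            match_spans([bad], [], sentence)


class TestMatchingProperties:
    def _random_case(self, rng):
        gold = random_disjoint_spans(rng, source=SpanSource.GOLD)
        system = random_disjoint_spans(rng, source=SpanSource.SYSTEM)
        return gold, system

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(300):
            gold, system = self._random_case(rng)
            result = match_spans(gold, system)
            assert len(result.pairs) == oracle_max_matching(gold, system)

    def test_swapping_sides_preserves_cardinality(self, rng):
        for _ in range(100):
            gold, system = self._random_case(rng)
            forward = match_spans(gold, system)
            swapped = match_spans(
                [make_span(s.char_start, s.char_end, source=SpanSource.GOLD) for s in system],
                [make_span(g.char_start, g.char_end, source=SpanSource.SYSTEM) for g in gold],
            )
            assert len(forward.pairs) == len(swapped.pairs)

    def test_adding_a_system_span_never_decreases_matches(self, rng):
        for _ in range(100):
            gold, system = self._random_case(rng)
            if not system:
                continue
            fewer = match_spans(gold, system[:-1])
            more = match_spans(gold, system)
            assert len(more.pairs) >= len(fewer.pairs)

    def test_one_to_one_overlap_graph_matches_every_edge(self, rng):
        # when each span overlaps at most one on the other side, the
        # assignment is forced and |pairs| equals the number of edges
        for _ in range(100):
            gold, system = self._random_case(rng)
            degree_g = [
                sum(overlap_length(g, s) >= 1 for s in system) for g in gold
            ]
            degree_s = [
                sum(overlap_length(g, s) >= 1 for g in gold) for s in system
            ]
            if any(d > 1 for d in degree_g + degree_s):
                continue
            result = match_spans(gold, system)
            assert len(result.pairs) == sum(degree_g)

    def test_pn_matches_never_exceed_ner_matches(self, rng):
        for _ in range(100):
            gold, system = self._random_case(rng)
            result = match_spans(gold, system)
            assert result.n_matched_pn <= result.n_matched_ner


class TestCountMatches:
    def test_levels_and_empty(self):
        gold = [make_span(0, 4), make_span(5, 9, polarity=Polarity.NEGATIVE)]
        system = [
            make_span(0, 4, source=SpanSource.SYSTEM),
            make_span(5, 9, source=SpanSource.SYSTEM),  # positive vs gold negative
        ]
        result = match_spans(gold, system)
        assert count_matches([result], "ner_only") == 2
        assert count_matches([result], "ner_plus_pn") == 1
        assert count_matches([], "ner_only") == 0

    def test_overlapping_scopes_rejected(self):
        result = match_spans([make_span(0, 4)], [make_span(0, 4, source=SpanSource.SYSTEM)])
        with pytest.raises(ValueError, match="overlapping scopes"):
            count_matches([result, result])


class TestAnnotationIO:
    def test_tsv_round_trip(self, tmp_path):
        spans = [
            make_span(0, 2, surface="疼痛"),
            make_span(4, 6, surface="発熱", polarity=Polarity.NEGATIVE, sentence_index=1),
        ]
        path = tmp_path / "gold.tsv"
        write_spans_tsv(spans, path)
        assert read_spans_tsv(path, SpanSource.GOLD) == spans

    def test_inline_tags_become_standoff_offsets(self):
        tagged = '嘔気は<C certainty="negative">なし</C>、<C certainty="positive">頭痛</C>あり。'
        text, spans = parse_inline_tagged(tagged)
        assert text == "嘔気はなし、頭痛あり。"
        assert spans == [(3, 5, Polarity.NEGATIVE), (6, 8, Polarity.POSITIVE)]

    def test_inline_spans_carry_surface_and_scope(self):
        tagged = '<C certainty="positive">発熱</C>続く。'
        text, spans = spans_from_inline(
            tagged, record_id="R1", section="assessment", sentence_index=2
        )
        assert text == "発熱続く。"
        (span,) = spans
        assert (span.char_start, span.char_end, span.surface) == (0, 2, "発熱")
        assert span.scope == ("R1", Section.ASSESSMENT, 2)

    def test_match_corpus_requires_known_sentences(self):
        sentence = Sentence("R1", Section.SUBJECTIVE, 0, "疼痛あり。", 0, 5)
        stray = make_span(0, 2, record_id="R2", surface="疼痛")
        with pytest.raises(SpanValidationError, match="missing sentence"):
            match_corpus([stray], [], [sentence])
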