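import datetime
import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soapeval.records import (
    CareRecord,
    DosingCourse,
    SENTENCE_DELIMITERS,
    Section,
    filter_records,
    normalize_text,
    read_records_jsonl,
    segment_sentences,
    write_records_jsonl,
)

# characters spanning half-width kana, ASCII, full-width and ordinary Japanese
_text = st.text(
    alphabet=st.one_of(
        st.characters(min_codepoint=0xFF61, max_codepoint=0xFF9F),
        st.characters(min_codepoint=0x20, max_codepoint=0x7E),
        st.characters(min_codepoint=0x3040, max_codepoint=0x30FF),
        st.sampled_from("。．！\n漢字医療痛"),
    ),
    max_size=40,
)


class TestNormalizeText:
    @pytest.mark.parametrize(
        ("raw", "expected"),
        [
            ("痛い!", "痛い。"),
            ("", ""),
            ("ｾﾌｧｿﾞﾘﾝ", "セファゾリン"),
            ("CEZ 100mg", "ＣＥＺ　１００ｍｇ"),
            ("！？", "。？"),
            ("｡｢｣･ｰ", "。「」・ー"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_text(raw) == expected

    @settings(derandomize=True, max_examples=200)
    @given(_text)
    def test_idempotent(self, text):
        once = normalize_text(text)
        assert normalize_text(once) == once

    @settings(derandomize=True, max_examples=200)
    @given(_text)
    def test_length_preserved_without_voiced_pairs(self, text):
        # a kana followed by a voiced/semi-voiced mark (half-width or
        # combining) composes 2 -> 1; everything else maps one-to-one
        if any(ch in "ﾞﾟ゙゚" for ch in text):
            return
        assert len(normalize_text(text)) == len(text)

    def test_output_is_full_width(self):
        out = normalize_text("ﾊﾟｲﾝ apple 123 !?")
        assert not any(0x21 <= ord(c) <= 0x7E or 0xFF61 <= ord(c) <= 0xFF9F for c in out)


class TestSegmentSentences:
    def test_period_split_with_offsets(self):
        sentences = segment_sentences("眠れない。食欲あり")
        assert [(s.text, s.char_start, s.char_end) for s in sentences] == [
            ("眠れない。", 0, 5),
            ("食欲あり", 5, 9),
        ]
        assert [s.sentence_index for s in sentences] == [0, 1]

    def test_line_break_split(self):
        assert [s.text for s in segment_sentences("Ａ\nＢ")] == ["Ａ\n", "Ｂ"]

    def test_delimiter_only_text_yields_nothing(self):
        assert segment_sentences("。。。") == []
        assert segment_sentences("\n　\n") == []

    def test_fullwidth_period_is_delimiter(self):
        assert [s.text for s in segment_sentences("発熱あり．経過良好．")] == [
            "発熱あり．",
            "経過良好．",
        ]

    @settings(derandomize=True, max_examples=200)
    @given(_text)
    def test_offsets_reconstruct_input(self, text):
        normalized = normalize_text(text)
        sentences = segment_sentences(normalized)
        rebuilt = list(normalized)
        for s in sentences:
            assert normalized[s.char_start : s.char_end] == s.text
            for k in range(s.char_start, s.char_end):
                rebuilt[k] = None
        # everything not covered by a sentence is delimiter or whitespace
        leftovers = [c for c in rebuilt if c is not None]
        assert all(c in SENTENCE_DELIMITERS or c.isspace() for c in leftovers)
        # sentences are ordered and non-overlapping
        bounds = [(s.char_start, s.char_end) for s in sentences]
        assert bounds == sorted(bounds)
        assert all(b1[1] <= b2[0] for b1, b2 in zip(bounds, bounds[1:]))


def _record(record_id="R1", patient="P1", date="2018-05-01", **sections):
    return CareRecord(
        record_id=record_id,
        patient_id=patient,
        record_date=datetime.date.fromisoformat(date),
        sections={Section(k): v for k, v in sections.items()},
    )


class TestFilterRecords:
    course = DosingCourse("P1", datetime.date(2018, 5, 1), datetime.date(2018, 5, 3))

    def test_keyword_in_objective_and_soap_content_included(self):
        record = _record(subjective="眠れない。", objective="CEZ点滴中", free_text="")
        assert filter_records([record], [self.course]) == [record]

    def test_keyword_only_in_assessment_excluded(self):
        record = _record(subjective="眠れない。", assessment="CEZ継続", free_text="経過")
        assert filter_records([record], [self.course]) == []

    def test_all_sections_blank_excluded(self):
        record = _record(subjective=" ", objective="", free_text="CEZ")
        assert filter_records([record], [self.course]) == []

    def test_window_boundaries(self):
        inside = _record(record_id="R1", date="2018-05-15", objective="CEZ投与")
        outside = _record(record_id="R2", date="2018-05-16", objective="CEZ投与")
        kept = filter_records([inside, outside], [self.course], window_days=12)
        assert kept == [inside]

    def test_patient_without_course_excluded_with_warning(self, caplog):
        record = _record(patient="P9", objective="CEZ投与")
        with caplog.at_level("WARNING"):
            assert filter_records([record], [self.course]) == []
        assert "P9" in caplog.text

    def test_halfwidth_keyword_matched_on_raw_text(self):
        record = _record(objective="ｾﾌｧｿﾞﾘﾝ投与")
        assert filter_records([record], [self.course]) == [record]
        # normalized spelling is a *different* keyword and must be listed itself
        assert filter_records([record], [self.course], keywords=["セファゾリン"]) == []

    def test_adding_keyword_is_monotone(self):
        records = [
            _record(record_id=f"R{i}", objective=text)
            for i, text in enumerate(["CEZ", "cez", "セファメジン", "なし"])
        ]
        kept_small = filter_records(records, [self.course] , keywords=["CEZ"])
        kept_large = filter_records(records, [self.course], keywords=["CEZ", "cez", "セファメジン"])
        assert set(r.record_id for r in kept_small) <= set(r.record_id for r in kept_large)


class TestRecordIO:
    def test_jsonl_round_trip(self, tmp_path):
        records = [
            _record(record_id="R1", subjective="眠れない。", free_text="CEZ"),
            _record(record_id="R2", objective="発熱なし。"),
        ]
        path = tmp_path / "records.jsonl"
        write_records_jsonl(records, path)
        assert read_records_jsonl(path) == records

    def test_soap_shorthand_keys_accepted(self, tmp_path):
        path = tmp_path / "records.jsonl"
        path.write_text(
            json.dumps(
                {
                    "record_id": "R1",
                    "patient_id": "P1",
                    "record_date": "2018-05-01",
                    "sections": {"S": "眠れない。", "O": "CEZ", "free_text": "x"},
                },
                ensure_ascii=False,
            )
            + "\n",
            encoding="utf-8",
        )
        (record,) = read_records_jsonl(path)
        assert record.section_text(Section.SUBJECTIVE) == "眠れない。"

    def test_duplicate_record_id_rejected(self, tmp_path):
        path = tmp_path / "records.jsonl"
        line = json.dumps(
            {"record_id": "R1", "patient_id": "P1", "record_date": "2018-05-01", "sections": {"S": "x"}}
        )
        path.write_text(line + "\n" + line + "\n", encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate"):
            read_records_jsonl(path)
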