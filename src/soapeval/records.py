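"""SOAP care-record data model, inclusion filtering, normalization and segmentation.

Pharmaceutical care records are pharmacist-authored patient notes split into
subjective / objective / assessment / plan (SOAP) sections plus a free-text
section.  This module holds the record-level data model, the cohort inclusion
filter (keyword + dosing-window), the Japanese half-to-full-width text
normalization applied before NER, and sentence segmentation with exact
character-offset bookkeeping so that downstream entity spans can always be
mapped back into the section text.
"""
from __future__ import annotations

import csv
import datetime
import json
import logging
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Section",
    "SOAP_SECTIONS",
    "CareRecord",
    "DosingCourse",
    "Sentence",
    "DEFAULT_KEYWORDS",
    "DEFAULT_WINDOW_DAYS",
    "filter_records",
    "normalize_text",
    "segment_sentences",
    "read_records_jsonl",
    "write_records_jsonl",
    "read_dosing_csv",
    "write_dosing_csv",
]


class Section(str, Enum):
    """The five section kinds of a pharmaceutical care record."""

    SUBJECTIVE = "subjective"
    OBJECTIVE = "objective"
    ASSESSMENT = "assessment"
    PLAN = "plan"
    FREE_TEXT = "free_text"


#: The four SOAP sections proper (free text excluded).
SOAP_SECTIONS: tuple[Section, ...] = (
    Section.SUBJECTIVE,
    Section.OBJECTIVE,
    Section.ASSESSMENT,
    Section.PLAN,
)

_SECTION_ALIASES: dict[str, Section] = {
    "s": Section.SUBJECTIVE,
    "o": Section.OBJECTIVE,
    "a": Section.ASSESSMENT,
    "p": Section.PLAN,
    "f": Section.FREE_TEXT,
    "free": Section.FREE_TEXT,
    "freetext": Section.FREE_TEXT,
    "free_text": Section.FREE_TEXT,
}
_SECTION_ALIASES.update({s.value: s for s in Section})


def coerce_section(value: "Section | str") -> Section:
    """Resolve a section given as enum, full name, or S/O/A/P shorthand."""
    if isinstance(value, Section):
        return value
    key = str(value).strip().lower()
    try:
        return _SECTION_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown section kind: {value!r}") from None


#: Cohort keywords: cefazolin / cefamezin in full- and half-width katakana,
#: plus the upper- and lower-case Latin abbreviation.  Matched case-sensitively
#: against the raw (un-normalized) text, which is why the half-width variants
#: are listed explicitly.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "セファゾリン",
    "ｾﾌｧｿﾞﾘﾝ",
    "セファメジン",
    "ｾﾌｧﾒｼﾞﾝ",
    "CEZ",
    "cez",
)

#: Records are retained up to this many days after the last dose.
DEFAULT_WINDOW_DAYS: int = 12


@dataclass(frozen=True)
class CareRecord:
    """One patient-contact record with dated SOAP and free-text sections."""

    record_id: str
    patient_id: str
    record_date: datetime.date
    sections: Mapping[Section, str]

    def __post_init__(self) -> None:
        coerced = {coerce_section(k): v for k, v in self.sections.items()}
        if not coerced:
            raise ValueError(f"record {self.record_id!r}: at least one section required")
        object.__setattr__(self, "sections", coerced)

    def section_text(self, section: "Section | str") -> str:
        return self.sections.get(coerce_section(section), "")

    def has_soap_content(self) -> bool:
        """True if at least one of the four SOAP sections is non-blank."""
        return any(self.sections.get(s, "").strip() for s in SOAP_SECTIONS)


@dataclass(frozen=True)
class DosingCourse:
    """First/last administration dates of the study drug for one patient."""

    patient_id: str
    first_dose_date: datetime.date
    last_dose_date: datetime.date

    def __post_init__(self) -> None:
        if self.first_dose_date > self.last_dose_date:
            raise ValueError(
                f"dosing course for {self.patient_id!r}: first dose "
                f"{self.first_dose_date} after last dose {self.last_dose_date}"
            )

    def window(self, window_days: int) -> tuple[datetime.date, datetime.date]:
        return (
            self.first_dose_date,
            self.last_dose_date + datetime.timedelta(days=window_days),
        )


@dataclass(frozen=True)
class Sentence:
    """One segmented sentence, with offsets into its normalized section text.

    Offsets are 0-based half-open and counted in Unicode code points; the
    sentence text keeps its trailing delimiter so that concatenating sentences
    (plus dropped delimiter-only gaps) reconstructs the section exactly.
    """

    record_id: str
    section: Section
    sentence_index: int
    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_end - self.char_start != len(self.text):
            raise ValueError(
                f"sentence {self.record_id}/{self.section}/{self.sentence_index}: "
                f"offsets [{self.char_start},{self.char_end}) disagree with text length "
                f"{len(self.text)}"
            )

    @property
    def scope(self) -> tuple[str, Section, int]:
        return (self.record_id, self.section, self.sentence_index)


# --- normalization ----------------------------------------------------------

def _build_halfwidth_table() -> dict[int, str]:
    # Half-width kana block U+FF61..U+FF9F via the Unicode compatibility
    # mapping; the voiced/semi-voiced sound marks go to combining marks so a
    # following NFC pass composes e.g. half-width SO + voiced mark into ゾ.
    table: dict[int, str] = {}
    for cp in range(0xFF61, 0xFFA0):
        if cp == 0xFF9E:
            table[cp] = "゙"
        elif cp == 0xFF9F:
            table[cp] = "゚"
        else:
            table[cp] = unicodedata.normalize("NFKC", chr(cp))
    return table


_HALFWIDTH_KANA = _build_halfwidth_table()
_ASCII_SHIFT = 0xFEE0  # U+0021..U+007E -> U+FF01..U+FF5E


def normalize_text(text: str) -> str:
    """Convert half-width characters to full width; exclamation marks to 。.

    Every half-width katakana, ASCII letter, digit and symbol is replaced by
    its full-width compatibility equivalent (the ASCII space becomes the
    ideographic space U+3000).  Both the half- and full-width exclamation mark
    become the ideographic full stop "。" so that exclamations terminate
    sentences.  The mapping is one character to one character except that a
    half-width kana followed by a separate voiced/semi-voiced sound mark
    composes into a single full-width character.
    """
    out: list[str] = []
    for ch in text:
        cp = ord(ch)
        if 0xFF61 <= cp <= 0xFF9F:
            out.append(_HALFWIDTH_KANA[cp])
        elif 0x21 <= cp <= 0x7E:
            out.append(chr(cp + _ASCII_SHIFT))
        elif ch == " ":
            out.append("　")
        else:
            out.append(ch)
    normalized = unicodedata.normalize("NFC", "".join(out))
    return normalized.replace("！", "。")


# --- sentence segmentation --------------------------------------------------

#: A sentence break is a line break or a period (ideographic or full-width).
SENTENCE_DELIMITERS: frozenset[str] = frozenset({"\n", "\r", "。", "．"})


def segment_sentences(
    section_text: str,
    *,
    record_id: str = "",
    section: "Section | str" = Section.FREE_TEXT,
) -> list[Sentence]:
    """Split normalized section text into sentences at line breaks and periods.

    Delimiters attach to the end of the preceding sentence.  Segments that are
    empty or whitespace-only after stripping delimiters are dropped, but their
    character range is never reassigned, so the surviving sentences' offsets
    always index into the original section text.
    """
    sec = coerce_section(section)
    sentences: list[Sentence] = []
    start = 0
    index = 0

    def emit(end: int) -> None:
        nonlocal start, index
        segment = section_text[start:end]
        core = "".join(c for c in segment if c not in SENTENCE_DELIMITERS)
        if core.strip():
            sentences.append(
                Sentence(
                    record_id=record_id,
                    section=sec,
                    sentence_index=index,
                    text=segment,
                    char_start=start,
                    char_end=end,
                )
            )
            index += 1
        start = end

    for i, ch in enumerate(section_text):
        if ch in SENTENCE_DELIMITERS:
            emit(i + 1)
    if start < len(section_text):
        emit(len(section_text))
    return sentences


# --- inclusion filtering ----------------------------------------------------

def filter_records(
    records: Iterable[CareRecord],
    courses: Iterable[DosingCourse],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> list[CareRecord]:
    """Apply the cohort inclusion criteria and return the retained records.

    A record is kept iff (a) at least one SOAP section is non-blank, (b) at
    least one keyword occurs as a raw substring of the free-text or objective
    section, and (c) its date falls inside [first dose, last dose +
    ``window_days``] of one of its patient's dosing courses.  Keyword search is
    case-sensitive on un-normalized text — full- and half-width spelling
    variants must be supplied as separate keywords.  A record whose patient has
    no dosing course is excluded with a warning.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    keywords = list(keywords)
    if not keywords:
        raise ValueError("keywords must be non-empty")

    by_patient: dict[str, list[DosingCourse]] = {}
    for course in courses:
        by_patient.setdefault(course.patient_id, []).append(course)

    kept: list[CareRecord] = []
    for record in records:
        if not record.has_soap_content():
            logger.warning("record %s excluded: no SOAP section content", record.record_id)
            continue
        haystacks = (
            record.section_text(Section.FREE_TEXT),
            record.section_text(Section.OBJECTIVE),
        )
        if not any(kw in text for kw in keywords for text in haystacks):
            logger.warning("record %s excluded: no keyword match", record.record_id)
            continue
        patient_courses = by_patient.get(record.patient_id)
        if not patient_courses:
            logger.warning(
                "record %s excluded: patient %s has no dosing course",
                record.record_id,
                record.patient_id,
            )
            continue
        in_window = False
        for course in patient_courses:
            lo, hi = course.window(window_days)
            if lo <= record.record_date <= hi:
                in_window = True
                break
        if not in_window:
            logger.warning("record %s excluded: outside dosing window", record.record_id)
            continue
        kept.append(record)
    return kept


# --- file ingestion ---------------------------------------------------------

def read_records_jsonl(path: "str | Path") -> list[CareRecord]:
    """Read care records from JSON Lines.

    Each line is an object with keys ``record_id``, ``patient_id``,
    ``record_date`` (ISO-8601) and ``sections`` (object keyed by section name
    or S/O/A/P shorthand).
    """
    path = Path(path)
    records: list[CareRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                record = CareRecord(
                    record_id=str(obj["record_id"]),
                    patient_id=str(obj["patient_id"]),
                    record_date=datetime.date.fromisoformat(obj["record_date"]),
                    sections={coerce_section(k): str(v) for k, v in obj["sections"].items()},
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid record: {exc}") from exc
            if record.record_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate record_id {record.record_id!r}")
            seen.add(record.record_id)
            records.append(record)
    return records


def write_records_jsonl(records: Iterable[CareRecord], path: "str | Path") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for record in records:
            obj = {
                "record_id": record.record_id,
                "patient_id": record.patient_id,
                "record_date": record.record_date.isoformat(),
                "sections": {s.value: t for s, t in record.sections.items()},
            }
            handle.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_dosing_csv(path: "str | Path") -> list[DosingCourse]:
    """Read dosing courses from CSV with columns patient_id, first_dose_date, last_dose_date."""
    path = Path(path)
    courses: list[DosingCourse] = []
    with path.open(encoding="utf-8", newline="") as handle:
        for lineno, row in enumerate(csv.DictReader(handle), start=2):
            try:
                courses.append(
                    DosingCourse(
                        patient_id=str(row["patient_id"]),
                        first_dose_date=datetime.date.fromisoformat(row["first_dose_date"]),
                        last_dose_date=datetime.date.fromisoformat(row["last_dose_date"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid dosing course: {exc}") from exc
    return courses


def write_dosing_csv(courses: Iterable[DosingCourse], path: "str | Path") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "first_dose_date", "last_dose_date"])
        for course in courses:
            writer.writerow(
                [
                    course.patient_id,
                    course.first_dose_date.isoformat(),
                    course.last_dose_date.isoformat(),
                ]
            )
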