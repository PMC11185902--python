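"""Gold/system entity-span alignment with exact and partial (≥1 char) matching.

Spans are aligned strictly within one sentence.  Two spans match partially
when they share at least one character position; a match is exact when the
boundaries are identical.  When a span on one side overlaps several on the
other, matched terms are counted in the units that minimize the matched-term
total — implemented as a maximum-cardinality one-to-one assignment, which in
every star configuration yields exactly the smaller unit count.  Among
maximum-cardinality assignments, those with the most exact pairs are
preferred, and remaining ties are broken leftmost-first.

Because spans from one source never overlap each other, two candidate pairs
can never "cross" (an interval argument: if gold g1 < g2 and system s1 < s2,
g1 overlapping s2 forces g2 and s1 apart), so repeated identical surfaces in a
sentence are automatically paired order-preservingly.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .records import Section, Sentence, coerce_section

__all__ = [
    "Polarity",
    "SpanSource",
    "MatchType",
    "EntitySpan",
    "MatchedPair",
    "MatchResult",
    "ScopeMismatchError",
    "SpanValidationError",
    "overlap_length",
    "match_spans",
    "match_corpus",
    "count_matches",
    "read_spans_tsv",
    "write_spans_tsv",
    "parse_inline_tagged",
    "spans_from_inline",
]


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class SpanSource(str, Enum):
    SYSTEM = "system"
    ANNOTATOR_A = "annotator_A"
    ANNOTATOR_B = "annotator_B"
    GOLD = "gold"


class MatchType(str, Enum):
    EXACT = "exact"
    PARTIAL = "partial"


class ScopeMismatchError(ValueError):
    """Spans from different sentences were compared — a scoping bug."""


class SpanValidationError(ValueError):
    """A span violates its sentence bounds, surface, or non-overlap contract."""


Scope = tuple[str, Section, int]


@dataclass(frozen=True)
class EntitySpan:
    """A character-offset entity span within one sentence, with polarity."""

    record_id: str
    section: Section
    sentence_index: int
    char_start: int
    char_end: int
    surface: str
    polarity: Polarity
    source: SpanSource

    def __post_init__(self) -> None:
        object.__setattr__(self, "section", coerce_section(self.section))
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        object.__setattr__(self, "source", SpanSource(self.source))
        if not (0 <= self.char_start < self.char_end):
            raise SpanValidationError(
                f"span {self.describe()}: offsets must satisfy 0 <= start < end"
            )

    @property
    def scope(self) -> Scope:
        return (self.record_id, self.section, self.sentence_index)

    def describe(self) -> str:
        return (
            f"{self.record_id}/{self.section.value}/s{self.sentence_index}"
            f"[{self.char_start},{self.char_end}) {self.surface!r}"
        )


@dataclass(frozen=True)
class MatchedPair:
    gold: EntitySpan
    system: EntitySpan
    match_type: MatchType
    polarity_agrees: bool


@dataclass
class MatchResult:
    """Aligned gold/system pairs plus unmatched residues for one scope."""

    scope: Scope
    pairs: list[MatchedPair]
    unmatched_gold: list[EntitySpan]
    unmatched_system: list[EntitySpan]

    @property
    def gold_spans(self) -> list[EntitySpan]:
        return [p.gold for p in self.pairs] + list(self.unmatched_gold)

    @property
    def system_spans(self) -> list[EntitySpan]:
        return [p.system for p in self.pairs] + list(self.unmatched_system)

    @property
    def n_matched_ner(self) -> int:
        return len(self.pairs)

    @property
    def n_matched_pn(self) -> int:
        return sum(1 for p in self.pairs if p.polarity_agrees)


def overlap_length(a: EntitySpan, b: EntitySpan) -> int:
    """Length of the character-position intersection of two same-sentence spans."""
    if a.scope != b.scope:
        raise ScopeMismatchError(
            f"spans from different sentences compared: {a.describe()} vs {b.describe()}"
        )
    return max(0, min(a.char_end, b.char_end) - max(a.char_start, b.char_start))


def _validate_side(spans: Sequence[EntitySpan], sentence: "Sentence | None", label: str) -> None:
    ordered = sorted(spans, key=lambda s: (s.char_start, s.char_end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.char_start < prev.char_end:
            raise SpanValidationError(
                f"{label} spans overlap within one sentence: "
                f"{prev.describe()} and {cur.describe()}"
            )
    if sentence is None:
        return
    for span in spans:
        if span.scope != sentence.scope:
            raise SpanValidationError(
                f"{label} span {span.describe()} does not belong to sentence {sentence.scope}"
            )
        if span.char_end > len(sentence.text):
            raise SpanValidationError(
                f"{label} span {span.describe()} exceeds sentence length {len(sentence.text)}"
            )
        actual = sentence.text[span.char_start : span.char_end]
        if span.surface != actual:
            raise SpanValidationError(
                f"{label} span {span.describe()}: surface disagrees with sentence text {actual!r}"
            )


def match_spans(
    gold: Sequence[EntitySpan],
    system: Sequence[EntitySpan],
    sentence: "Sentence | None" = None,
) -> MatchResult:
    """One-to-one alignment of gold and system spans within a single sentence.

    Returns the maximum-cardinality assignment over ≥1-character-overlap
    edges; among such assignments the number of exact-boundary pairs is
    maximized, and remaining ties resolve leftmost-first.  Polarity agreement
    is recorded per pair but never influences the assignment.
    """
    gold = sorted(gold, key=lambda s: (s.char_start, s.char_end))
    system = sorted(system, key=lambda s: (s.char_start, s.char_end))

    scopes = {s.scope for s in gold} | {s.scope for s in system}
    if len(scopes) > 1:
        raise ScopeMismatchError(f"match_spans received spans from {len(scopes)} scopes: {scopes}")
    if sentence is not None:
        scope = sentence.scope
    elif scopes:
        scope = next(iter(scopes))
    else:
        scope = ("", Section.FREE_TEXT, 0)

    _validate_side(gold, sentence, "gold")
    _validate_side(system, sentence, "system")

    if not gold or not system:
        return MatchResult(scope=scope, pairs=[], unmatched_gold=list(gold), unmatched_system=list(system))

    n_g, n_s = len(gold), len(system)
    n = max(n_g, n_s)
    # Tiered integer weights: one extra matched pair outweighs every exact
    # bonus; one extra exact pair outweighs every positional tie-break.
    tie_cap = 2 * n + 1
    exact_w = n * tie_cap + 1
    edge_w = n * (exact_w + tie_cap) + 1
    weights = np.zeros((n_g, n_s), dtype=np.int64)
    for i, g in enumerate(gold):
        for j, s in enumerate(system):
            if overlap_length(g, s) >= 1:
                w = edge_w - (i + j)
                if (g.char_start, g.char_end) == (s.char_start, s.char_end):
                    w += exact_w
                weights[i, j] = w

    rows, cols = linear_sum_assignment(weights, maximize=True)
    paired_g: set[int] = set()
    paired_s: set[int] = set()
    pairs: list[MatchedPair] = []
    for i, j in zip(rows, cols):
        if weights[i, j] <= 0:
            continue
        g, s = gold[i], system[j]
        exact = (g.char_start, g.char_end) == (s.char_start, s.char_end)
        pairs.append(
            MatchedPair(
                gold=g,
                system=s,
                match_type=MatchType.EXACT if exact else MatchType.PARTIAL,
                polarity_agrees=g.polarity == s.polarity,
            )
        )
        paired_g.add(i)
        paired_s.add(j)
    pairs.sort(key=lambda p: p.gold.char_start)
    return MatchResult(
        scope=scope,
        pairs=pairs,
        unmatched_gold=[g for i, g in enumerate(gold) if i not in paired_g],
        unmatched_system=[s for j, s in enumerate(system) if j not in paired_s],
    )


def match_corpus(
    gold: Iterable[EntitySpan],
    system: Iterable[EntitySpan],
    sentences: "Iterable[Sentence] | None" = None,
) -> list[MatchResult]:
    """Run :func:`match_spans` over every sentence scope present on either side.

    If ``sentences`` is given, every span must reference one of them (spans
    are validated against the sentence text); scopes with a sentence but no
    spans contribute empty results and are omitted.
    """
    by_scope: dict[Scope, tuple[list[EntitySpan], list[EntitySpan]]] = {}
    for span in gold:
        by_scope.setdefault(span.scope, ([], []))[0].append(span)
    for span in system:
        by_scope.setdefault(span.scope, ([], []))[1].append(span)

    sentence_map: dict[Scope, Sentence] | None = None
    if sentences is not None:
        sentence_map = {s.scope: s for s in sentences}
        for scope in by_scope:
            if scope not in sentence_map:
                raise SpanValidationError(f"annotation references missing sentence {scope}")

    results = []
    for scope in sorted(by_scope, key=lambda sc: (sc[0], sc[1].value, sc[2])):
        g, s = by_scope[scope]
        sent = sentence_map[scope] if sentence_map is not None else None
        results.append(match_spans(g, s, sent))
    return results


def count_matches(results: Iterable[MatchResult], level: str = "ner_only") -> int:
    """Total matched terms over disjoint scopes at a given evaluation level.

    ``ner_only`` counts every aligned pair (exact + partial); ``ner_plus_pn``
    counts only pairs whose polarity labels agree.
    """
    if level not in ("ner_only", "ner_plus_pn"):
        raise ValueError(f"unknown level {level!r}")
    seen: set[Scope] = set()
    total = 0
    for result in results:
        if result.scope in seen:
            raise ValueError(f"overlapping scopes in aggregation: {result.scope}")
        seen.add(result.scope)
        total += result.n_matched_ner if level == "ner_only" else result.n_matched_pn
    return total


# --- annotation ingestion ---------------------------------------------------

_TSV_FIELDS = ["record_id", "section", "sentence_index", "char_start", "char_end", "polarity", "surface"]


def read_spans_tsv(path: "str | Path", source: "SpanSource | str") -> list[EntitySpan]:
    """Read standoff annotations: one span per tab-separated line.

    Columns: record_id, section, sentence_index, char_start, char_end,
    polarity, surface (header row required).
    """
    path = Path(path)
    source = SpanSource(source)
    spans: list[EntitySpan] = []
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                spans.append(
                    EntitySpan(
                        record_id=row["record_id"],
                        section=coerce_section(row["section"]),
                        sentence_index=int(row["sentence_index"]),
                        char_start=int(row["char_start"]),
                        char_end=int(row["char_end"]),
                        surface=row["surface"],
                        polarity=Polarity(row["polarity"]),
                        source=source,
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid span: {exc}") from exc
    return spans


def write_spans_tsv(spans: Iterable[EntitySpan], path: "str | Path") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_TSV_FIELDS)
        for span in spans:
            writer.writerow(
                [
                    span.record_id,
                    span.section.value,
                    span.sentence_index,
                    span.char_start,
                    span.char_end,
                    span.polarity.value,
                    span.surface,
                ]
            )


_INLINE_TAG = re.compile(
    r"<(?P<tag>[A-Za-z][\w.-]*)\b[^>]*certainty=\"(?P<certainty>positive|negative)\"[^>]*>"
    r"(?P<body>[^<]*)</(?P=tag)>"
)


def parse_inline_tagged(tagged: str) -> tuple[str, list[tuple[int, int, Polarity]]]:
    """Convert inline-XML entity markup to plain text plus standoff offsets.

    Entities are wrapped in tags carrying a ``certainty`` attribute with
    values ``positive``/``negative`` (the MedNER-J output dialect).  Returns
    the tag-stripped text and (start, end, polarity) tuples over it.
    """
    plain: list[str] = []
    spans: list[tuple[int, int, Polarity]] = []
    pos = 0
    length = 0
    for m in _INLINE_TAG.finditer(tagged):
        before = tagged[pos : m.start()]
        plain.append(before)
        length += len(before)
        body = m.group("body")
        spans.append((length, length + len(body), Polarity(m.group("certainty"))))
        plain.append(body)
        length += len(body)
        pos = m.end()
    plain.append(tagged[pos:])
    return "".join(plain), spans


def spans_from_inline(
    tagged: str,
    *,
    record_id: str,
    section: "Section | str",
    sentence_index: int,
    source: "SpanSource | str" = SpanSource.SYSTEM,
) -> tuple[str, list[EntitySpan]]:
    """Parse one inline-tagged sentence into EntitySpan objects."""
    text, raw = parse_inline_tagged(tagged)
    spans = [
        EntitySpan(
            record_id=record_id,
            section=coerce_section(section),
            sentence_index=sentence_index,
            char_start=start,
            char_end=end,
            surface=text[start:end],
            polarity=polarity,
            source=SpanSource(source),
        )
        for start, end, polarity in raw
    ]
    return text, spans
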