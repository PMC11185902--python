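"""Seeded synthetic SOAP corpora with gold annotations and injected NER errors.

The confidential hospital records cannot ship, so this module generates
SOAP-structured Japanese-like records whose section-level sentence counts and
sentence lengths follow the study corpus' per-section medians and ranges, with
disease/symptom surfaces from a small lexicon embedded as gold entity spans.
A simulated system annotation is derived from the gold standard by a
parameterized error-injection model whose four knobs map one-to-one onto the
mismatch cause taxonomy:

* deletion with probability ``p_fn``        → system extraction failures,
* spurious spans at per-sentence rate ``p_fp`` → incorrect extractions,
* polarity flips with probability ``p_flip``   → P-N classification differences,
* boundary shifts with probability ``p_boundary`` → length differences.

Sentence text is template-generated (lexicon surfaces separated by filler
characters), not natural language: matching and metrics depend only on
offsets, surfaces, polarities and delimiters.  All randomness flows from one
seeded generator in documented order, so equal seeds give byte-identical
corpora.
"""
from __future__ import annotations

import json
import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import (
    SOAP_SECTIONS,
    CareRecord,
    DosingCourse,
    Section,
    Sentence,
    coerce_section,
    write_dosing_csv,
    write_records_jsonl,
)
from .span_matching import EntitySpan, Polarity, SpanSource, write_spans_tsv

__all__ = [
    "DEFAULT_LEXICON",
    "SectionProfile",
    "GeneratorConfig",
    "SyntheticCorpus",
    "ParameterEstimates",
    "generate_corpus",
    "recover_parameters",
    "build_structured_annotations",
    "write_corpus",
]

#: Japanese disease/symptom surfaces (full-width), including colloquial forms.
DEFAULT_LEXICON: tuple[str, ...] = (
    "疼痛",
    "発熱",
    "頭痛",
    "嘔気",
    "嘔吐",
    "不眠",
    "発疹",
    "下痢",
    "便秘",
    "浮腫",
    "悪寒",
    "冷汗",
    "腹痛",
    "咳嗽",
    "眠れない",
    "めまい",
    "倦怠感",
    "掻痒感",
    "食欲低下",
    "アレルギー",
    "腎機能障害",
    "肝機能障害",
)

_FILLER = "のにてでをはがも経過良好確認様子本日引続予定特記状態変化少安定服薬継続中"


@dataclass(frozen=True)
class SectionProfile:
    """Sentence-count/length distribution and error rates for one section."""

    sentences_median: float
    sentences_min: int
    sentences_max: int
    chars_median: float
    chars_min: int
    chars_max: int
    entity_rate: float  # mean gold entities per sentence (Poisson)
    p_fn: float
    p_fp: float
    p_flip: float
    p_boundary: float

    def __post_init__(self) -> None:
        for name in ("p_fn", "p_fp", "p_flip", "p_boundary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if min(self.sentences_median, self.chars_median, self.entity_rate + 1) <= 0:
            raise ValueError("distribution parameters must be positive")


def _default_profiles() -> dict[Section, SectionProfile]:
    # Sentence/length targets follow the study corpus' per-section medians and
    # ranges; entity rates follow gold terms per sentence; error rates follow
    # the per-section mismatch structure (miss rate = 1 - recall, flip and
    # boundary rates relative to matched terms, spurious rate per sentence).
    return {
        Section.SUBJECTIVE: SectionProfile(4, 1, 17, 18, 6, 61, 0.62, 0.68, 0.043, 0.39, 0.32),
        Section.OBJECTIVE: SectionProfile(37, 5, 120, 29, 6, 113, 0.18, 0.32, 0.046, 0.46, 0.27),
        Section.ASSESSMENT: SectionProfile(4.5, 2, 21, 15, 6, 97, 0.80, 0.38, 0.006, 0.15, 0.23),
        Section.PLAN: SectionProfile(2, 1, 5, 10, 6, 44, 0.13, 0.40, 0.25, 0.80, 0.22),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded parameters of the synthetic corpus and its error-injection model."""

    seed: int = 0
    n_records: int = 60
    sections: Mapping[Section, SectionProfile] = field(default_factory=_default_profiles)
    polarity_positive_rate: float = 0.6
    lexicon: tuple[str, ...] = DEFAULT_LEXICON
    boundary_shift_max: int = 2
    allow_overlapping_spurious: bool = False
    first_record_date: datetime.date = datetime.date(2018, 4, 1)

    def __post_init__(self) -> None:
        if not self.lexicon:
            raise ValueError("lexicon must be non-empty")
        if not 0.0 <= self.polarity_positive_rate <= 1.0:
            raise ValueError("polarity_positive_rate must lie in [0, 1]")
        if self.boundary_shift_max < 1:
            raise ValueError("boundary_shift_max must be >= 1")
        longest = max(len(term) for term in self.lexicon)
        for section, profile in self.sections.items():
            if longest + 3 > profile.chars_max:
                raise ValueError(
                    f"infeasible configuration: lexicon entry of {longest} chars cannot fit "
                    f"a {section} sentence of at most {profile.chars_max} chars (chars_max)"
                )

    @classmethod
    def uniform_rates(
        cls,
        p_fn: float,
        p_fp: float,
        p_flip: float,
        p_boundary: float,
        *,
        seed: int = 0,
        n_records: int = 60,
        **kwargs,
    ) -> "GeneratorConfig":
        """Config with one shared error-rate vector across all four sections."""
        sections = {
            sec: replace(prof, p_fn=p_fn, p_fp=p_fp, p_flip=p_flip, p_boundary=p_boundary)
            for sec, prof in _default_profiles().items()
        }
        return cls(seed=seed, n_records=n_records, sections=sections, **kwargs)


@dataclass
class SyntheticCorpus:
    """Generated records plus gold/system annotations and the corruption log."""

    config: GeneratorConfig
    records: list[CareRecord]
    dosing: list[DosingCourse]
    sentences: list[Sentence]
    gold: list[EntitySpan]
    system: list[EntitySpan]
    truth_log: list[dict]

    def expected_counts(self) -> dict[Section, "SectionCounts"]:
        """Section-level count table derived from the corruption log alone.

        Valid only for the default disjoint-spurious regime, in which the
        gold/system overlap graph is exactly one-to-one: every retained system
        span matches its originating gold span and nothing else.
        """
        from .metrics_agreement import SectionCounts

        if self.config.allow_overlapping_spurious:
            raise ValueError(
                "expected_counts is exact only when spurious spans are disjoint from gold"
            )
        acc: dict[Section, list[int]] = {}
        for entry in self.truth_log:
            section = Section(entry["section"])
            counts = acc.setdefault(section, [0, 0, 0, 0])  # system, gold, ner, pn
            if entry["op"] == "spurious":
                counts[0] += 1
                continue
            counts[1] += 1
            if not entry["deleted"]:
                counts[0] += 1
                counts[2] += 1
                if not entry["flipped"]:
                    counts[3] += 1
        return {sec: SectionCounts(*vals) for sec, vals in acc.items()}


@dataclass(frozen=True)
class ParameterEstimates:
    """Error-injection rates recovered from the downstream evaluation."""

    p_fn: float
    precision_loss: float  # share of system spans that are spurious (p_fp proxy)
    p_flip: float
    p_boundary: float


def _draw_count(rng: np.random.Generator, median: float, lo: int, hi: int) -> int:
    return int(np.clip(rng.poisson(median), lo, hi))


def _make_sentence_text(
    rng: np.random.Generator,
    profile: SectionProfile,
    lexicon: Sequence[str],
    positive_rate: float,
) -> tuple[str, list[tuple[int, int, str, Polarity]]]:
    """Build one sentence: filler-separated lexicon surfaces plus a 。 delimiter."""
    k = int(min(rng.poisson(profile.entity_rate), 3))
    target = _draw_count(rng, profile.chars_median, profile.chars_min, profile.chars_max)
    surfaces = [lexicon[int(rng.integers(len(lexicon)))] for _ in range(k)]
    entity_chars = sum(len(s) for s in surfaces)
    # content excludes the trailing delimiter; every gap >= 1 filler char
    content_len = max(target - 1, entity_chars + k + 1)
    filler_total = content_len - entity_chars
    gaps = np.ones(k + 1, dtype=int)
    extra = filler_total - (k + 1)
    if extra > 0:
        gaps += rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))

    pieces: list[str] = []
    spans: list[tuple[int, int, str, Polarity]] = []
    pos = 0
    for idx, surface in enumerate(surfaces):
        filler = "".join(rng.choice(list(_FILLER), size=int(gaps[idx])))
        pieces.append(filler)
        pos += len(filler)
        polarity = Polarity.POSITIVE if rng.random() < positive_rate else Polarity.NEGATIVE
        spans.append((pos, pos + len(surface), surface, polarity))
        pieces.append(surface)
        pos += len(surface)
    pieces.append("".join(rng.choice(list(_FILLER), size=int(gaps[k]))))
    pieces.append("。")
    return "".join(pieces), spans


def _shift_candidates(
    start: int,
    end: int,
    lo_bound: int,
    hi_bound: int,
    max_shift: int,
) -> list[tuple[int, int]]:
    """All boundary variants within ±max_shift that stay in (lo_bound, hi_bound),
    keep >= 1 char of overlap with the original, and actually change the span."""
    out = []
    for s2 in range(max(lo_bound, start - max_shift), start + max_shift + 1):
        for e2 in range(end - max_shift, min(hi_bound, end + max_shift) + 1):
            if s2 < e2 and (s2, e2) != (start, end) and s2 < end and e2 > start:
                out.append((s2, e2))
    return out


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a seeded corpus with gold annotations and corrupted system output.

    Draw order per sentence: sentence layout (entity count, length, surfaces,
    gap sizes, filler, polarities), then per gold span a deletion draw, then
    for survivors a polarity-flip draw followed by a boundary-shift draw (and
    candidate choice), then the per-sentence spurious-insertion draw.
    """
    rng = np.random.default_rng(config.seed)
    records: list[CareRecord] = []
    dosing: list[DosingCourse] = []
    sentences: list[Sentence] = []
    gold: list[EntitySpan] = []
    system: list[EntitySpan] = []
    truth_log: list[dict] = []

    for r in range(config.n_records):
        record_id = f"R{r:04d}"
        patient_id = f"P{r:04d}"
        first_dose = config.first_record_date + datetime.timedelta(days=int(rng.integers(0, 300)))
        last_dose = first_dose + datetime.timedelta(days=int(rng.integers(0, 6)))
        record_date = first_dose + datetime.timedelta(
            days=int(rng.integers(0, (last_dose - first_dose).days + 12 + 1))
        )
        dosing.append(DosingCourse(patient_id, first_dose, last_dose))

        section_texts: dict[Section, str] = {Section.FREE_TEXT: "CEZ投与中。"}
        for section in SOAP_SECTIONS:
            profile = config.sections[section]
            n_sent = _draw_count(
                rng, profile.sentences_median, profile.sentences_min, profile.sentences_max
            )
            offset = 0
            texts: list[str] = []
            for s_idx in range(n_sent):
                text, raw_spans = _make_sentence_text(
                    rng, profile, config.lexicon, config.polarity_positive_rate
                )
                sentence = Sentence(
                    record_id=record_id,
                    section=section,
                    sentence_index=s_idx,
                    text=text,
                    char_start=offset,
                    char_end=offset + len(text),
                )
                sentences.append(sentence)
                texts.append(text)
                offset += len(text)

                gold_here: list[EntitySpan] = []
                for start, end, surface, polarity in raw_spans:
                    span = EntitySpan(
                        record_id=record_id,
                        section=section,
                        sentence_index=s_idx,
                        char_start=start,
                        char_end=end,
                        surface=surface,
                        polarity=polarity,
                        source=SpanSource.GOLD,
                    )
                    gold.append(span)
                    gold_here.append(span)

                # corruption: deletions, then flips and boundary shifts
                survivors = [(g, rng.random() >= profile.p_fn) for g in gold_here]
                content_end = len(text) - 1  # exclude the trailing delimiter
                sys_here: list[EntitySpan] = []
                prev_sys_end = 0
                for idx, (g, kept) in enumerate(survivors):
                    entry = {
                        "op": "gold",
                        "record_id": record_id,
                        "section": section.value,
                        "sentence_index": s_idx,
                        "char_start": g.char_start,
                        "char_end": g.char_end,
                        "polarity": g.polarity.value,
                        "deleted": not kept,
                        "flipped": False,
                        "shifted": False,
                        "system_start": None,
                        "system_end": None,
                    }
                    if not kept:
                        truth_log.append(entry)
                        continue
                    flipped = rng.random() < profile.p_flip
                    polarity = g.polarity
                    if flipped:
                        polarity = (
                            Polarity.NEGATIVE
                            if polarity is Polarity.POSITIVE
                            else Polarity.POSITIVE
                        )
                    start2, end2 = g.char_start, g.char_end
                    shifted = False
                    if rng.random() < profile.p_boundary:
                        lo_bound = max(
                            prev_sys_end,
                            gold_here[idx - 1].char_end if idx > 0 else 0,
                        )
                        hi_bound = (
                            gold_here[idx + 1].char_start
                            if idx + 1 < len(gold_here)
                            else content_end
                        )
                        candidates = _shift_candidates(
                            start2, end2, lo_bound, hi_bound, config.boundary_shift_max
                        )
                        if candidates:
                            start2, end2 = candidates[int(rng.integers(len(candidates)))]
                            shifted = True
                    sys_span = EntitySpan(
                        record_id=record_id,
                        section=section,
                        sentence_index=s_idx,
                        char_start=start2,
                        char_end=end2,
                        surface=text[start2:end2],
                        polarity=polarity,
                        source=SpanSource.SYSTEM,
                    )
                    sys_here.append(sys_span)
                    prev_sys_end = end2
                    entry.update(
                        flipped=flipped,
                        shifted=shifted,
                        system_start=start2,
                        system_end=end2,
                    )
                    truth_log.append(entry)

                if rng.random() < profile.p_fp:
                    spurious = _place_spurious(
                        rng,
                        text,
                        content_end,
                        gold_here,
                        sys_here,
                        config.allow_overlapping_spurious,
                    )
                    if spurious is not None:
                        s_start, s_end = spurious
                        polarity = (
                            Polarity.POSITIVE
                            if rng.random() < config.polarity_positive_rate
                            else Polarity.NEGATIVE
                        )
                        sys_here.append(
                            EntitySpan(
                                record_id=record_id,
                                section=section,
                                sentence_index=s_idx,
                                char_start=s_start,
                                char_end=s_end,
                                surface=text[s_start:s_end],
                                polarity=polarity,
                                source=SpanSource.SYSTEM,
                            )
                        )
                        truth_log.append(
                            {
                                "op": "spurious",
                                "record_id": record_id,
                                "section": section.value,
                                "sentence_index": s_idx,
                                "char_start": s_start,
                                "char_end": s_end,
                            }
                        )
                system.extend(sorted(sys_here, key=lambda sp: sp.char_start))
            section_texts[section] = "".join(texts)

        records.append(
            CareRecord(
                record_id=record_id,
                patient_id=patient_id,
                record_date=record_date,
                sections=section_texts,
            )
        )

    return SyntheticCorpus(
        config=config,
        records=records,
        dosing=dosing,
        sentences=sentences,
        gold=gold,
        system=system,
        truth_log=truth_log,
    )


def _place_spurious(
    rng: np.random.Generator,
    text: str,
    content_end: int,
    gold_here: Sequence[EntitySpan],
    sys_here: Sequence[EntitySpan],
    allow_overlap_gold: bool,
) -> "tuple[int, int] | None":
    """Pick a 2–4 char spurious span; by default disjoint from every existing span."""
    blocked = list(sys_here) if allow_overlap_gold else list(gold_here) + list(sys_here)
    occupied = sorted((sp.char_start, sp.char_end) for sp in blocked)
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for start, end in occupied:
        if start - cursor >= 2:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if content_end - cursor >= 2:
        gaps.append((cursor, content_end))
    if not gaps:
        return None
    g_start, g_end = gaps[int(rng.integers(len(gaps)))]
    length = int(rng.integers(2, min(4, g_end - g_start) + 1))
    start = int(rng.integers(g_start, g_end - length + 1))
    return start, start + length


def recover_parameters(
    corpus: SyntheticCorpus,
    metrics: "MetricsReport",
    errors: "ErrorCategoryReport",
) -> ParameterEstimates:
    """Estimate the generating error rates from the downstream evaluation.

    The deletion rate is the category-1 share of gold terms, the polarity-flip
    and boundary-shift rates are the category-3 and category-4 shares of
    matched terms, and the spurious-insertion rate is summarized as the
    category-2 share of system terms (the precision loss it induces).
    """
    totals = errors.overall
    counts = metrics.counts("all")
    if counts.n_gold == 0:
        raise ValueError("degenerate corpus: no gold spans to recover parameters from")
    matched = counts.n_matched_ner
    return ParameterEstimates(
        p_fn=totals.category_1 / counts.n_gold,
        precision_loss=totals.category_2 / counts.n_system if counts.n_system else 0.0,
        p_flip=totals.category_3 / matched if matched else 0.0,
        p_boundary=totals.category_4 / matched if matched else 0.0,
    )


def build_structured_annotations(
    n_gold: int,
    n_system: int,
    n_matched: int,
    n_discordant: int,
    n_partial: int,
    *,
    section: "Section | str" = Section.ASSESSMENT,
    record_id: str = "structured",
) -> tuple[list[Sentence], list[EntitySpan], list[EntitySpan]]:
    """Construct sentences realizing an exact one-to-one count structure.

    Produces ``n_matched`` one-pair sentences (the first ``n_discordant``
    polarity-discordant with exact boundaries, the next ``n_partial``
    boundary-shifted with concordant polarity, the rest exact and concordant),
    then gold-only and system-only sentences for the residues.  Useful for
    reproducing printed count tables span-by-span.
    """
    if n_matched > min(n_gold, n_system):
        raise ValueError("n_matched cannot exceed min(n_gold, n_system)")
    if n_discordant + n_partial > n_matched:
        raise ValueError("n_discordant + n_partial cannot exceed n_matched")
    section = coerce_section(section)

    sentences: list[Sentence] = []
    gold: list[EntitySpan] = []
    system: list[EntitySpan] = []
    text = "に疼痛あり。"  # gold span [1,3); partial system variant [1,4)

    def add_sentence(idx: int) -> Sentence:
        s = Sentence(
            record_id=record_id,
            section=section,
            sentence_index=idx,
            text=text,
            char_start=0,
            char_end=len(text),
        )
        sentences.append(s)
        return s

    def make_span(idx: int, start: int, end: int, polarity: Polarity, source: SpanSource) -> EntitySpan:
        return EntitySpan(
            record_id=record_id,
            section=section,
            sentence_index=idx,
            char_start=start,
            char_end=end,
            surface=text[start:end],
            polarity=polarity,
            source=source,
        )

    idx = 0
    for k in range(n_matched):
        add_sentence(idx)
        gold.append(make_span(idx, 1, 3, Polarity.POSITIVE, SpanSource.GOLD))
        if k < n_discordant:
            system.append(make_span(idx, 1, 3, Polarity.NEGATIVE, SpanSource.SYSTEM))
        elif k < n_discordant + n_partial:
            system.append(make_span(idx, 1, 4, Polarity.POSITIVE, SpanSource.SYSTEM))
        else:
            system.append(make_span(idx, 1, 3, Polarity.POSITIVE, SpanSource.SYSTEM))
        idx += 1
    for _ in range(n_gold - n_matched):
        add_sentence(idx)
        gold.append(make_span(idx, 1, 3, Polarity.POSITIVE, SpanSource.GOLD))
        idx += 1
    for _ in range(n_system - n_matched):
        add_sentence(idx)
        system.append(make_span(idx, 1, 3, Polarity.POSITIVE, SpanSource.SYSTEM))
        idx += 1
    return sentences, gold, system


def write_corpus(corpus: SyntheticCorpus, out_dir: "str | Path") -> dict[str, Path]:
    """Write records.jsonl, dosing.csv, gold.tsv, system.tsv and truth_log.jsonl."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.jsonl",
        "dosing": out / "dosing.csv",
        "gold": out / "gold.tsv",
        "system": out / "system.tsv",
        "truth_log": out / "truth_log.jsonl",
    }
    write_records_jsonl(corpus.records, paths["records"])
    write_dosing_csv(corpus.dosing, paths["dosing"])
    write_spans_tsv(corpus.gold, paths["gold"])
    write_spans_tsv(corpus.system, paths["system"])
    with paths["truth_log"].open("w", encoding="utf-8") as handle:
        for entry in corpus.truth_log:
            handle.write(json.dumps(entry, ensure_ascii=False) + "\n")
    return paths
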