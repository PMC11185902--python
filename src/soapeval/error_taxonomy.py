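"""Four-category mismatch taxonomy for gold/system span discrepancies.

Every discrepancy between the gold annotation and the system output is
assigned to one or more cause categories:

1. system extraction failure — a gold span the system missed entirely
   (no character overlap with any system span in the sentence);
2. incorrect extraction by the system — a system span overlapping no gold
   span;
3. difference in P-N classification — terms in an overlapping configuration
   whose polarity labels disagree;
4. difference in the length of the extracted terms — terms in an overlapping
   configuration whose boundaries are not identical.

Partial overlaps count as matches for categories 1–3 but as mismatches for
category 4, and categories 3 and 4 are not mutually exclusive, so the four
percentages need not sum to 100%.  For categories 3 and 4 the mismatch can be
counted in gold-side or system-side units; the convention is the unit that
yields the larger count, evaluated per connected component of the sentence's
overlap graph.  Percentages are taken over the total extracted terms
(n_system + n_gold − n_matched) of the section.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .records import Section, Sentence
from .span_matching import EntitySpan, MatchResult, overlap_length

__all__ = [
    "CATEGORY_LABELS",
    "CategorizedTerm",
    "SectionErrorCounts",
    "ErrorCategoryReport",
    "SubcategoryRule",
    "DEFAULT_SUBCATEGORY_RULES",
    "categorize_errors",
    "tag_subcategories",
    "load_rules_yaml",
    "dump_rules_yaml",
]

CATEGORY_LABELS: dict[int, str] = {
    1: "system extraction failure",
    2: "incorrect extraction by the system",
    3: "difference in P-N classification",
    4: "difference in the length of the extracted terms",
}


@dataclass(frozen=True)
class CategorizedTerm:
    """One mismatched term, with the sentence context when available."""

    span: EntitySpan
    category: int
    sentence_text: "str | None" = None


@dataclass
class SectionErrorCounts:
    category_1: int = 0
    category_2: int = 0
    category_3: int = 0
    category_4: int = 0
    n_system: int = 0
    n_gold: int = 0
    n_matched: int = 0

    @property
    def total_extracted_terms(self) -> int:
        """Denominator: system terms + gold terms − matched terms."""
        return self.n_system + self.n_gold - self.n_matched

    def category(self, k: int) -> int:
        return getattr(self, f"category_{k}")

    @property
    def percentages(self) -> dict[int, float]:
        denom = self.total_extracted_terms
        return {k: (self.category(k) / denom if denom else 0.0) for k in CATEGORY_LABELS}

    def __iadd__(self, other: "SectionErrorCounts") -> "SectionErrorCounts":
        for name in (
            "category_1",
            "category_2",
            "category_3",
            "category_4",
            "n_system",
            "n_gold",
            "n_matched",
        ):
            setattr(self, name, getattr(self, name) + getattr(other, name))
        return self


@dataclass
class ErrorCategoryReport:
    sections: dict[Section, SectionErrorCounts]
    members: list[CategorizedTerm]

    @property
    def overall(self) -> SectionErrorCounts:
        total = SectionErrorCounts()
        for counts in self.sections.values():
            total += counts
        return total

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        labels = [(s.value, c) for s, c in self.sections.items()] + [("all", self.overall)]
        for label, counts in labels:
            row = {"section": label, "total_extracted_terms": counts.total_extracted_terms}
            for k in CATEGORY_LABELS:
                row[f"category_{k}"] = counts.category(k)
                row[f"category_{k}_pct"] = counts.percentages[k]
            rows.append(row)
        return pd.DataFrame(rows)


def _components(
    gold: Sequence[EntitySpan], system: Sequence[EntitySpan]
) -> tuple[list[tuple[list[int], list[int]]], set[int], set[int]]:
    """Connected components of the bipartite overlap graph within one sentence.

    Returns (components as (gold indices, system indices) pairs, gold indices
    with ≥1 edge, system indices with ≥1 edge).
    """
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(len(gold)):
        parent[("g", i)] = ("g", i)
    for j in range(len(system)):
        parent[("s", j)] = ("s", j)

    linked_g: set[int] = set()
    linked_s: set[int] = set()
    for i, g in enumerate(gold):
        for j, s in enumerate(system):
            if overlap_length(g, s) >= 1:
                union(("g", i), ("s", j))
                linked_g.add(i)
                linked_s.add(j)

    groups: dict[tuple[str, int], tuple[list[int], list[int]]] = {}
    for i in linked_g:
        groups.setdefault(find(("g", i)), ([], []))[0].append(i)
    for j in linked_s:
        groups.setdefault(find(("s", j)), ([], []))[1].append(j)
    return list(groups.values()), linked_g, linked_s


def categorize_errors(
    results: Iterable[MatchResult],
    sentences: "Iterable[Sentence] | None" = None,
) -> ErrorCategoryReport:
    """Classify every gold/system discrepancy into the four cause categories.

    Categories 1 and 2 are overlap-free spans of the gold and system side
    respectively.  Categories 3 (polarity) and 4 (boundary) are counted per
    connected component of the overlap graph, in the unit — gold-side or
    system-side — that maximizes the mismatch count.  The report also carries
    the categorized terms themselves for downstream subcategory tagging.
    """
    sentence_map = {s.scope: s for s in sentences} if sentences is not None else {}
    sections: dict[Section, SectionErrorCounts] = {}
    members: list[CategorizedTerm] = []
    seen = set()

    for result in results:
        if result.scope in seen:
            raise ValueError(f"overlapping scopes in aggregation: {result.scope}")
        seen.add(result.scope)
        section = result.scope[1]
        counts = sections.setdefault(section, SectionErrorCounts())
        context = sentence_map.get(result.scope)
        text = context.text if context is not None else None

        gold = result.gold_spans
        system = result.system_spans
        counts.n_gold += len(gold)
        counts.n_system += len(system)
        counts.n_matched += result.n_matched_ner

        components, linked_g, linked_s = _components(gold, system)

        for i, g in enumerate(gold):
            if i not in linked_g:
                counts.category_1 += 1
                members.append(CategorizedTerm(span=g, category=1, sentence_text=text))
        for j, s in enumerate(system):
            if j not in linked_s:
                counts.category_2 += 1
                members.append(CategorizedTerm(span=s, category=2, sentence_text=text))

        for g_idx, s_idx in components:
            discordant_g = [
                i
                for i in g_idx
                if any(
                    overlap_length(gold[i], system[j]) >= 1
                    and gold[i].polarity != system[j].polarity
                    for j in s_idx
                )
            ]
            discordant_s = [
                j
                for j in s_idx
                if any(
                    overlap_length(gold[i], system[j]) >= 1
                    and gold[i].polarity != system[j].polarity
                    for i in g_idx
                )
            ]
            partial_g = [
                i
                for i in g_idx
                if any(
                    overlap_length(gold[i], system[j]) >= 1
                    and (gold[i].char_start, gold[i].char_end)
                    != (system[j].char_start, system[j].char_end)
                    for j in s_idx
                )
            ]
            partial_s = [
                j
                for j in s_idx
                if any(
                    overlap_length(gold[i], system[j]) >= 1
                    and (gold[i].char_start, gold[i].char_end)
                    != (system[j].char_start, system[j].char_end)
                    for i in g_idx
                )
            ]
            for cat, g_side, s_side in ((3, discordant_g, discordant_s), (4, partial_g, partial_s)):
                if len(g_side) >= len(s_side):
                    chosen = [gold[i] for i in g_side]
                else:
                    chosen = [system[j] for j in s_side]
                setattr(counts, f"category_{cat}", counts.category(cat) + len(chosen))
                members.extend(
                    CategorizedTerm(span=sp, category=cat, sentence_text=text) for sp in chosen
                )

    return ErrorCategoryReport(sections=sections, members=members)


# --- subcategory rule engine ------------------------------------------------

@dataclass(frozen=True)
class SubcategoryRule:
    """A configurable surface predicate over categorized mismatch terms.

    ``lexicon`` matches when the term surface is exactly one of its entries;
    ``pattern`` is a regex searched in the surface; ``context_pattern`` is a
    regex searched in the sentence context (terms without context never match
    it).  A rule with ``category`` set applies only to terms of that cause
    category.  A term may satisfy several rules.
    """

    rule_id: str
    label: str
    category: "int | None" = None
    lexicon: "frozenset[str] | None" = None
    pattern: "str | None" = None
    context_pattern: "str | None" = None

    def __post_init__(self) -> None:
        if self.lexicon is None and self.pattern is None and self.context_pattern is None:
            raise ValueError(f"rule {self.rule_id!r}: needs a lexicon or a pattern")
        if self.lexicon is not None:
            object.__setattr__(self, "lexicon", frozenset(self.lexicon))

    def matches(self, term: CategorizedTerm) -> bool:
        if self.category is not None and term.category != self.category:
            return False
        if self.lexicon is not None and term.span.surface not in self.lexicon:
            return False
        if self.pattern is not None and not re.search(self.pattern, term.span.surface):
            return False
        if self.context_pattern is not None:
            if term.sentence_text is None:
                return False
            if not re.search(self.context_pattern, term.sentence_text):
                return False
        return True


def tag_subcategories(
    report: ErrorCategoryReport, rules: Sequence[SubcategoryRule]
) -> dict[str, int]:
    """Count categorized terms satisfying each rule (a term may hit several)."""
    ids = [r.rule_id for r in rules]
    if len(set(ids)) != len(ids):
        raise ValueError("rule_id values must be unique")
    return {
        rule.rule_id: sum(1 for term in report.members if rule.matches(term)) for rule in rules
    }


#: Starter rules modelled on recurrent mismatch features in pharmacist notes:
#: colloquial predicate forms, normality statements about monitored functions,
#: as-needed dosage lines, wording about laboratory-value trends, and bare
#: template item names.
DEFAULT_SUBCATEGORY_RULES: tuple[SubcategoryRule, ...] = (
    SubcategoryRule(
        rule_id="predicate_forms",
        label="verbs, adjectives, and adverbs",
        category=1,
        pattern="(痛い|眠れな|だるい|つらい|かゆい|悪く)",
    ),
    SubcategoryRule(
        rule_id="hard_to_grasp",
        label="expressions that are difficult to grasp as diseases or symptoms",
        category=1,
        lexicon=frozenset({"腎機能", "肝機能", "電解質", "睡眠", "お通じ", "食欲", "腎機能、肝機能"}),
    ),
    SubcategoryRule(
        rule_id="prn_dosage",
        label="lists of dosages (medication to be taken as needed)",
        category=1,
        context_pattern="(不眠時|疼痛時|指示簿|頓用)",
    ),
    SubcategoryRule(
        rule_id="lab_value_wording",
        label="linguistic representation of laboratory values",
        category=1,
        pattern="(ＩＮＲ|ＷＢＣ|ＣＲＰ|高値|低値|減少傾向|上昇傾向)",
    ),
    SubcategoryRule(
        rule_id="item_names",
        label="item names",
        lexicon=frozenset({"副作用"}),
    ),
)


def load_rules_yaml(path: "str | Path") -> list[SubcategoryRule]:
    """Load subcategory rules from YAML (a list of rule mappings)."""
    with Path(path).open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or []
    rules = []
    for entry in raw:
        rules.append(
            SubcategoryRule(
                rule_id=entry["rule_id"],
                label=entry.get("label", entry["rule_id"]),
                category=entry.get("category"),
                lexicon=frozenset(entry["lexicon"]) if entry.get("lexicon") else None,
                pattern=entry.get("pattern"),
                context_pattern=entry.get("context_pattern"),
            )
        )
    return rules


def dump_rules_yaml(rules: Sequence[SubcategoryRule], path: "str | Path") -> None:
    payload = []
    for rule in rules:
        entry: dict = {"rule_id": rule.rule_id, "label": rule.label}
        if rule.category is not None:
            entry["category"] = rule.category
        if rule.lexicon is not None:
            entry["lexicon"] = sorted(rule.lexicon)
        if rule.pattern is not None:
            entry["pattern"] = rule.pattern
        if rule.context_pattern is not None:
            entry["context_pattern"] = rule.context_pattern
        payload.append(entry)
    with Path(path).open("w", encoding="utf-8") as handle:
        yaml.safe_dump(payload, handle, allow_unicode=True, sort_keys=False)
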