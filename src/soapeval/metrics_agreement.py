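"""Precision/recall/F1, per-record summaries, Cohen's κ, and sample size.

Evaluation is reported at two levels: NER alone (a matched pair is any
exact or partial span alignment) and NER plus P-N classification (the pair
must also agree on polarity).  With TP the matched-term count, FP the
system's surplus and FN the gold surplus,

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 P R / (P + R),

with the usual zero conventions on empty denominators.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import SOAP_SECTIONS, Section, coerce_section
from .span_matching import MatchResult

__all__ = [
    "LEVELS",
    "CountTriple",
    "SectionCounts",
    "RecordCounts",
    "Metrics",
    "MetricsReport",
    "PerRecordSummary",
    "AgreementTable",
    "precision_recall_f1",
    "round_metric",
    "per_record_summary",
    "cohens_kappa",
    "sample_size_for_proportion",
]

#: Evaluation levels: span match only, and span match plus polarity agreement.
LEVELS: tuple[str, str] = ("ner_only", "ner_plus_pn")

#: Row label for the pooled four-section aggregate.
ALL_SECTIONS = "all"


@dataclass(frozen=True)
class CountTriple:
    """System / gold / matched term counts at one evaluation level."""

    n_system: int
    n_gold: int
    n_matched: int

    def __post_init__(self) -> None:
        if min(self.n_system, self.n_gold, self.n_matched) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_matched > min(self.n_system, self.n_gold):
            raise ValueError(
                f"matched count {self.n_matched} exceeds min(system={self.n_system}, "
                f"gold={self.n_gold})"
            )

    def __add__(self, other: "CountTriple") -> "CountTriple":
        return CountTriple(
            self.n_system + other.n_system,
            self.n_gold + other.n_gold,
            self.n_matched + other.n_matched,
        )


@dataclass(frozen=True)
class SectionCounts:
    """Both-level counts for one section (mirrors one column of a count table)."""

    n_system: int
    n_gold: int
    n_matched_ner: int
    n_matched_pn: int

    def __post_init__(self) -> None:
        if self.n_matched_pn > self.n_matched_ner:
            raise ValueError("polarity-concordant matches cannot exceed NER matches")
        self.triple("ner_only")  # validates bounds

    def triple(self, level: str) -> CountTriple:
        matched = self.n_matched_ner if level == "ner_only" else self.n_matched_pn
        return CountTriple(self.n_system, self.n_gold, matched)

    def __add__(self, other: "SectionCounts") -> "SectionCounts":
        return SectionCounts(
            self.n_system + other.n_system,
            self.n_gold + other.n_gold,
            self.n_matched_ner + other.n_matched_ner,
            self.n_matched_pn + other.n_matched_pn,
        )


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


def precision_recall_f1(c: CountTriple) -> Metrics:
    """Precision, recall and F1 from a count triple (zero on empty denominators)."""
    p = c.n_matched / c.n_system if c.n_system else 0.0
    r = c.n_matched / c.n_gold if c.n_gold else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(precision=p, recall=r, f1=f1)


def round_metric(x: float) -> float:
    """Display rounding: half-up to 2 decimals, or 2 significant figures below 0.095.

    Proportions of ordinary size print with two decimals (0.6712 → 0.67);
    small ones keep two significant figures so they do not collapse to 0.0x
    (0.0540… → 0.054, 0.0769… → 0.077).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"metric {x} outside [0, 1]")
    if x == 0.0:
        return 0.0
    d = Decimal(repr(float(x)))
    if x >= 0.095:
        q = Decimal("0.01")
    else:
        exponent = math.floor(math.log10(x))
        q = Decimal(1).scaleb(exponent - 1)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Per-section and pooled precision/recall/F1 at both evaluation levels."""

    sections: dict[Section, SectionCounts]

    def __post_init__(self) -> None:
        self.sections = {coerce_section(k): v for k, v in self.sections.items()}

    @classmethod
    def from_match_results(cls, results: Iterable[MatchResult]) -> "MetricsReport":
        acc: dict[Section, SectionCounts] = {}
        seen = set()
        for result in results:
            if result.scope in seen:
                raise ValueError(f"overlapping scopes in aggregation: {result.scope}")
            seen.add(result.scope)
            section = result.scope[1]
            counts = SectionCounts(
                n_system=len(result.system_spans),
                n_gold=len(result.gold_spans),
                n_matched_ner=result.n_matched_ner,
                n_matched_pn=result.n_matched_pn,
            )
            acc[section] = acc[section] + counts if section in acc else counts
        return cls(sections=acc)

    def counts(self, section: "Section | str") -> SectionCounts:
        if isinstance(section, str) and section.lower() == ALL_SECTIONS:
            total = SectionCounts(0, 0, 0, 0)
            for c in self.sections.values():
                total = total + c
            return total
        return self.sections.get(coerce_section(section), SectionCounts(0, 0, 0, 0))

    def metrics(self, section: "Section | str", level: str) -> Metrics:
        return precision_recall_f1(self.counts(section).triple(level))

    def section_labels(self) -> list[str]:
        labels = [s.value for s in SOAP_SECTIONS if s in self.sections]
        labels += [s.value for s in self.sections if s not in SOAP_SECTIONS]
        return labels + [ALL_SECTIONS]

    def to_dataframe(self, rounded: bool = False) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            for label in self.section_labels():
                m = self.metrics(label, level)
                c = self.counts(label)
                fmt = round_metric if rounded else (lambda v: v)
                rows.append(
                    {
                        "level": level,
                        "section": label,
                        "n_system": c.n_system,
                        "n_gold": c.n_gold,
                        "n_matched": c.triple(level).n_matched,
                        "precision": fmt(m.precision),
                        "recall": fmt(m.recall),
                        "f1": fmt(m.f1),
                    }
                )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out: dict = {}
        for level in LEVELS:
            out[level] = {}
            for label in self.section_labels():
                m = self.metrics(label, level)
                c = self.counts(label)
                out[level][label] = {
                    "n_system": c.n_system,
                    "n_gold": c.n_gold,
                    "n_matched": c.triple(level).n_matched,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "precision_display": round_metric(m.precision),
                    "recall_display": round_metric(m.recall),
                    "f1_display": round_metric(m.f1),
                }
        return out


# --- per-record summaries ---------------------------------------------------

@dataclass(frozen=True)
class RecordCounts:
    """Gold/matched/polarity-matched term counts for one record."""

    n_gold: int
    n_matched: int
    n_matched_pn: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched_pn <= self.n_matched <= self.n_gold:
            raise ValueError("per-record counts must satisfy 0 <= pn <= matched <= gold")


@dataclass(frozen=True)
class PerRecordSummary:
    mean_gold: float
    sd_gold: float
    mean_matched: float
    sd_matched: float
    mean_pn_matched: float
    sd_pn_matched: float
    extract_fraction: float
    pn_fraction: float


def _mean_sd(values: Sequence[int]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def per_record_summary(per_record_counts: Sequence[RecordCounts]) -> PerRecordSummary:
    """Means and sample SDs of per-record term counts, plus the two fractions.

    ``extract_fraction`` is the mean matched count over the mean gold count
    (the share of documented findings the system extracted);
    ``pn_fraction`` is the mean polarity-concordant count over the mean
    matched count (the share of extractions also classified correctly).
    """
    if not per_record_counts:
        raise ValueError("per_record_summary requires at least one record")
    mean_g, sd_g = _mean_sd([c.n_gold for c in per_record_counts])
    mean_m, sd_m = _mean_sd([c.n_matched for c in per_record_counts])
    mean_p, sd_p = _mean_sd([c.n_matched_pn for c in per_record_counts])
    return PerRecordSummary(
        mean_gold=mean_g,
        sd_gold=sd_g,
        mean_matched=mean_m,
        sd_matched=sd_m,
        mean_pn_matched=mean_p,
        sd_pn_matched=sd_p,
        extract_fraction=mean_m / mean_g if mean_g else 0.0,
        pn_fraction=mean_p / mean_m if mean_m else 0.0,
    )


# --- inter-annotator agreement ---------------------------------------------

@dataclass
class AgreementTable:
    """Square contingency table of two raters' judgments over shared units."""

    counts: np.ndarray
    labels: "Sequence[str] | None" = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("agreement table must be square")
        if (self.counts < 0).any():
            raise ValueError("agreement table cells must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("agreement table must have a positive total")
        if self.labels is not None and len(self.labels) != self.counts.shape[0]:
            raise ValueError("label count disagrees with table size")

    @classmethod
    def from_ratings(
        cls, rater_a: Sequence, rater_b: Sequence, labels: "Sequence | None" = None
    ) -> "AgreementTable":
        if len(rater_a) != len(rater_b):
            raise ValueError("raters must judge the same units")
        if labels is None:
            labels = sorted(set(rater_a) | set(rater_b), key=str)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)))
        for a, b in zip(rater_a, rater_b):
            counts[index[a], index[b]] += 1
        return cls(counts=counts, labels=[str(lab) for lab in labels])


def cohens_kappa(t: AgreementTable) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    p_o is the observed agreement (diagonal mass) and p_e the agreement
    expected from the marginals alone.  A degenerate table in which both
    raters use a single category has p_e = 1 and, necessarily, p_o = 1;
    κ is defined as 1 there.
    """
    total = t.counts.sum()
    p_o = np.trace(t.counts) / total
    marg_a = t.counts.sum(axis=1) / total
    marg_b = t.counts.sum(axis=0) / total
    p_e = float(np.dot(marg_a, marg_b))
    if p_e >= 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


# --- sample size ------------------------------------------------------------

def sample_size_for_proportion(p: float, margin: float, confidence: float = 0.95) -> int:
    """Patients needed to estimate a proportion within ±margin at a confidence level.

    Normal-approximation sample size n = ⌈z² p(1−p) / margin²⌉ with z the
    two-sided standard-normal quantile; the ceiling guarantees the stated
    half-width.  E.g. detecting an adverse-event frequency of 0.5% within
    ±0.2% at 95% confidence requires 4778 patients.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must lie strictly between 0 and 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    z = norm.ppf(0.5 + confidence / 2.0)
    return math.ceil(z * z * p * (1.0 - p) / (margin * margin))
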