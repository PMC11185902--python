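"""End-to-end evaluation orchestration and report writers.

Two entry modes exist.  The span-level mode runs the full pipeline — record
inclusion filtering, normalization, sentence segmentation, gold/system span
alignment, metrics and error taxonomy — from files on disk.  The counts-only
mode starts from a per-section count table (system terms, gold terms, matched
terms at both levels) and recomputes the metric table, which is the route by
which published count tables can be re-evaluated without the underlying text.

All reports are written as CSV plus one machine-readable JSON bundle, with
both raw proportions and display-rounded values so rounding stays auditable.
"""
from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .error_taxonomy import (
    DEFAULT_SUBCATEGORY_RULES,
    ErrorCategoryReport,
    SubcategoryRule,
    categorize_errors,
    tag_subcategories,
)
from .metrics_agreement import LEVELS, MetricsReport, SectionCounts, round_metric
from .records import (
    DEFAULT_KEYWORDS,
    DEFAULT_WINDOW_DAYS,
    CareRecord,
    Section,
    Sentence,
    coerce_section,
    filter_records,
    normalize_text,
    read_dosing_csv,
    read_records_jsonl,
    segment_sentences,
)
from .span_matching import MatchResult, SpanSource, match_corpus, read_spans_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "EvaluationResult",
    "prepare_sentences",
    "run_evaluation",
    "evaluate_spans",
    "metrics_from_counts",
    "read_counts_csv",
    "write_counts_csv",
    "write_reports",
]


@dataclass
class RunConfig:
    """Input paths and options for one span-level evaluation run."""

    records_path: Path
    gold_path: Path
    system_path: Path
    dosing_path: "Path | None" = None
    out_dir: "Path | None" = None
    keywords: Sequence[str] = DEFAULT_KEYWORDS
    window_days: int = DEFAULT_WINDOW_DAYS
    rules: Sequence[SubcategoryRule] = DEFAULT_SUBCATEGORY_RULES

    def __post_init__(self) -> None:
        for name in ("records_path", "gold_path", "system_path", "dosing_path"):
            value = getattr(self, name)
            if value is not None:
                path = Path(value)
                setattr(self, name, path)
                if not path.exists():
                    raise FileNotFoundError(f"{name.replace('_path', '')} file not found: {path}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)


@dataclass
class EvaluationResult:
    metrics: MetricsReport
    errors: ErrorCategoryReport
    match_results: list[MatchResult]
    subcategory_counts: dict[str, int]
    artifacts: dict[str, Path] = field(default_factory=dict)


def prepare_sentences(records: Iterable[CareRecord]) -> list[Sentence]:
    """Normalize every section of every record and segment it into sentences."""
    sentences: list[Sentence] = []
    for record in records:
        for section, raw in record.sections.items():
            normalized = normalize_text(raw)
            sentences.extend(
                segment_sentences(normalized, record_id=record.record_id, section=section)
            )
    return sentences


def evaluate_spans(
    sentences: Sequence[Sentence],
    gold,
    system,
    rules: Sequence[SubcategoryRule] = DEFAULT_SUBCATEGORY_RULES,
) -> EvaluationResult:
    """Match gold against system spans and derive metrics plus error taxonomy."""
    results = match_corpus(gold, system, sentences)
    metrics = MetricsReport.from_match_results(results)
    errors = categorize_errors(results, sentences)
    subcounts = tag_subcategories(errors, rules)
    return EvaluationResult(
        metrics=metrics, errors=errors, match_results=results, subcategory_counts=subcounts
    )


def run_evaluation(config: RunConfig) -> EvaluationResult:
    """Execute filter → normalize → segment → match → metrics → errors.

    Records are read from JSON Lines and annotations from standoff TSV; every
    annotation must reference an existing sentence of a retained record.  When
    an output directory is configured the count, metric and error tables are
    written as CSV along with a JSON bundle.
    """
    records = read_records_jsonl(config.records_path)
    if config.dosing_path is not None:
        courses = read_dosing_csv(config.dosing_path)
        records = filter_records(records, courses, config.keywords, config.window_days)
        logger.info("retained %d records after inclusion filtering", len(records))
    sentences = prepare_sentences(records)
    gold = read_spans_tsv(config.gold_path, SpanSource.GOLD)
    system = read_spans_tsv(config.system_path, SpanSource.SYSTEM)
    result = evaluate_spans(sentences, gold, system, config.rules)
    if config.out_dir is not None:
        result.artifacts = write_reports(result, config.out_dir)
    return result


# --- counts-only mode -------------------------------------------------------

_COUNT_COLUMNS = ["section", "n_system", "n_gold", "n_matched_ner", "n_matched_pn"]


def metrics_from_counts(counts: Mapping["Section | str", SectionCounts]) -> MetricsReport:
    """Metric table from a per-section count table (counts-only mode)."""
    return MetricsReport(sections={coerce_section(k): v for k, v in counts.items()})


def read_counts_csv(path: "str | Path") -> MetricsReport:
    """Read a per-section count table: section, n_system, n_gold, n_matched_ner, n_matched_pn."""
    frame = pd.read_csv(path)
    missing = [c for c in _COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    counts = {
        row["section"]: SectionCounts(
            int(row["n_system"]),
            int(row["n_gold"]),
            int(row["n_matched_ner"]),
            int(row["n_matched_pn"]),
        )
        for _, row in frame.iterrows()
    }
    return metrics_from_counts(counts)


def write_counts_csv(metrics: MetricsReport, path: "str | Path") -> None:
    rows = []
    for section, counts in metrics.sections.items():
        rows.append(
            {
                "section": section.value,
                "n_system": counts.n_system,
                "n_gold": counts.n_gold,
                "n_matched_ner": counts.n_matched_ner,
                "n_matched_pn": counts.n_matched_pn,
            }
        )
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, index=False)


# --- report writing ---------------------------------------------------------

def write_reports(result: EvaluationResult, out_dir: "str | Path") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "metrics_raw": out / "metrics_raw.csv",
        "metrics_display": out / "metrics_display.csv",
        "errors": out / "error_categories.csv",
        "bundle": out / "report.json",
    }
    write_counts_csv(result.metrics, paths["counts"])
    result.metrics.to_dataframe(rounded=False).to_csv(paths["metrics_raw"], index=False)
    result.metrics.to_dataframe(rounded=True).to_csv(paths["metrics_display"], index=False)
    result.errors.to_dataframe().to_csv(paths["errors"], index=False)
    bundle = {
        "metrics": result.metrics.to_json_dict(),
        "error_categories": result.errors.to_dataframe().to_dict(orient="records"),
        "subcategories": result.subcategory_counts,
    }
    with paths["bundle"].open("w", encoding="utf-8") as handle:
        json.dump(bundle, handle, ensure_ascii=False, indent=2)
    return paths
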