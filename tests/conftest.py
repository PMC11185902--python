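import numpy as np
import pytest

from soapeval.records import Section, Sentence
from soapeval.span_matching import EntitySpan, Polarity, SpanSource


def make_span(
    start,
    end,
    *,
    source=SpanSource.GOLD,
    polarity=Polarity.POSITIVE,
    record_id="R0",
    section=Section.SUBJECTIVE,
    sentence_index=0,
    surface=None,
):
    return EntitySpan(
        record_id=record_id,
        section=section,
        sentence_index=sentence_index,
        char_start=start,
        char_end=end,
        surface=surface if surface is not None else "ん" * (end - start),
        polarity=polarity,
        source=source,
    )


def random_disjoint_spans(rng, *, max_spans=8, sentence_len=20, source=SpanSource.GOLD):
    """Non-overlapping random spans in one sentence, in random number and layout."""
    spans = []
    pos = int(rng.integers(0, 3))
    while pos < sentence_len - 1 and len(spans) < max_spans:
        if rng.random() < 0.55:
            length = int(rng.integers(1, 5))
            end = min(pos + length, sentence_len)
            polarity = Polarity.POSITIVE if rng.random() < 0.5 else Polarity.NEGATIVE
            spans.append(make_span(pos, end, source=source, polarity=polarity))
            pos = end
        pos += int(rng.integers(0, 4))
    return spans


def oracle_max_matching(gold, system):
    """Exhaustive maximum one-to-one matching size over >=1-char-overlap edges."""
    edges = [
        [max(0, min(g.char_end, s.char_end) - max(g.char_start, s.char_start)) >= 1 for s in system]
        for g in gold
    ]

    def best(i, used):
        if i == len(gold):
            return 0
        score = best(i + 1, used)
        for j in range(len(system)):
            if edges[i][j] and not used & (1 << j):
                score = max(score, 1 + best(i + 1, used | (1 << j)))
        return score

    return best(0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240604)
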