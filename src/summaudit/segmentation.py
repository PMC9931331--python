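"""Sentence and clinical-segment splitting, plus symbolic-segment filtering.

Documents are first cut into sentences at end marks and line breaks, then
each sentence is partitioned into finer *clinical segments* by a pluggable
segmenter.  The default segmenter is rule based (commas, Japanese pause
marks, and a small connective lexicon); any callable satisfying
:class:`SegmenterContract` may be substituted, e.g. a learned model.

All spans are 0-based half-open offsets into the input string.
"""

from __future__ import annotations

import re
from typing import Iterable, Protocol, Sequence

__all__ = [
    "SegmenterContract",
    "SegmenterContractError",
    "RuleSegmenter",
    "DEFAULT_DELIMITERS",
    "DEFAULT_SPLIT_CHARS",
    "DEFAULT_CONNECTIVES",
    "DEFAULT_SYMBOL_PATTERNS",
    "split_sentences",
    "split_clinical_segments",
    "segment_document",
    "flag_symbolic",
]

Span = tuple[int, int]

#: Sentence end marks; a line break always terminates a sentence.
DEFAULT_DELIMITERS = frozenset({"。", ".", "!", "?", "！", "？", "\n"})

#: In-sentence split characters (attach to the preceding segment).
DEFAULT_SPLIT_CHARS = frozenset({"、", "，", ","})

#: Connective words that open a new clinical segment mid-sentence.
DEFAULT_CONNECTIVES = (
    "ため",  # ため
    "ので",  # ので
    "また",  # また
    "しかし",  # しかし
    "and then",
    "because",
)


class SegmenterContractError(ValueError):
    """A segmenter returned parts that do not partition the sentence."""


class SegmenterContract(Protocol):
    """Maps one sentence to an ordered list of substrings covering it.

    The concatenation of the returned parts must reconstruct the input
    sentence exactly; empty parts are not allowed.
    """

    def __call__(self, sentence: str) -> Sequence[str]: ...


def split_sentences(
    text: str, delimiters: Iterable[str] = DEFAULT_DELIMITERS
) -> list[Span]:
    """Split text into sentence spans at end marks and line breaks.

    Returns 0-based half-open spans over maximal delimiter-free runs;
    delimiter characters are not part of any span and empty runs are
    dropped.  Deliberately primitive: no abbreviation or quote handling.
    """
    delims = frozenset(delimiters)
    spans: list[Span] = []
    start = None
    for i, ch in enumerate(text):
        if ch in delims:
            if start is not None:
                spans.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        spans.append((start, len(text)))
    return [s for s in spans if text[s[0] : s[1]].strip()]


class RuleSegmenter:
    """Rule-based clinical segmenter.

    Splits after runs of ``split_chars`` (the split character stays with the
    preceding segment) and before occurrences of connective words.  This is a
    stand-in for a learned fine-grained segmenter behind the same contract.
    """

    name = "rule"

    def __init__(
        self,
        split_chars: Iterable[str] = DEFAULT_SPLIT_CHARS,
        connectives: Sequence[str] = DEFAULT_CONNECTIVES,
    ):
        self.split_chars = frozenset(split_chars)
        self.connectives = tuple(c for c in connectives if c)
        self._conn_re = (
            re.compile("|".join(re.escape(c) for c in self.connectives))
            if self.connectives
            else None
        )

    def _cut_points(self, sentence: str) -> list[int]:
        cuts: set[int] = set()
        for i, ch in enumerate(sentence):
            # cut after the last split char of a run
            if ch in self.split_chars and i + 1 < len(sentence):
                if sentence[i + 1] not in self.split_chars:
                    cuts.add(i + 1)
        if self._conn_re is not None:
            for m in self._conn_re.finditer(sentence):
                if 0 < m.start() < len(sentence):
                    cuts.add(m.start())
        return sorted(cuts)

    def __call__(self, sentence: str) -> list[str]:
        if not sentence:
            return []
        bounds = [0, *self._cut_points(sentence), len(sentence)]
        return [
            sentence[a:b] for a, b in zip(bounds, bounds[1:]) if b > a
        ]


def _as_spans(sentence: str, parts: Sequence[str]) -> list[Span]:
    if "".join(parts) != sentence:
        raise SegmenterContractError(
            "segmenter output does not concatenate to the input sentence"
        )
    spans: list[Span] = []
    pos = 0
    for part in parts:
        if not part:
            raise SegmenterContractError("segmenter returned an empty part")
        spans.append((pos, pos + len(part)))
        pos += len(part)
    return spans


def split_clinical_segments(
    sentence: str, segmenter: SegmenterContract | None = None
) -> list[Span]:
    """Partition one sentence into clinical-segment spans.

    The returned spans tile ``[0, len(sentence))`` exactly.  Raises
    :class:`SegmenterContractError` if the segmenter violates its contract.
    """
    if not sentence:
        return []
    segmenter = segmenter if segmenter is not None else RuleSegmenter()
    return _as_spans(sentence, list(segmenter(sentence)))


def segment_document(
    text: str,
    segmenter: SegmenterContract | None = None,
    delimiters: Iterable[str] = DEFAULT_DELIMITERS,
) -> list[Span]:
    """Sentence-split then segment a whole document; spans are document-level."""
    out: list[Span] = []
    for s0, s1 in split_sentences(text, delimiters):
        for a, b in split_clinical_segments(text[s0:s1], segmenter):
            out.append((s0 + a, s0 + b))
    return out


#: Symbolic-segment patterns: bracket headers and date/time strings.
DEFAULT_SYMBOL_PATTERNS = (
    r"【.*】",  # 【…】 headers
    r"[\d\s./:\-年月日時分,()（）~〜]+",  # dates/times
)


def flag_symbolic(
    segment_text: str, patterns: Sequence[str] = DEFAULT_SYMBOL_PATTERNS
) -> bool:
    """True for segments that carry no clinical prose.

    Flags bracket headers, date-like strings, and any text without a letter
    character (pure punctuation, numbers, system symbols).  Patterns are
    configurable because the underlying rule is inherently open ended.
    """
    t = segment_text.strip()
    if not t:
        return True
    for pat in patterns:
        if re.fullmatch(pat, t):
            return True
    if not any(ch.isalpha() for ch in t):
        return True
    return False
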