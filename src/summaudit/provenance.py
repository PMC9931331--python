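"""Bi-gram coverage provenance: is a summary segment sourced from the records?

For each case a set of word bi-grams is built from all of its inpatient
records (bi-grams never cross sentence boundaries by default).  Each
discharge-summary segment is scored by the fraction of its own bi-gram
occurrences found in that set, and classified:

* ``excluded``  — symbolic segments, middle-subjectivity segments, and
  (by default) segments too short to form a bi-gram;
* ``sourced``   — coverage >= threshold (default 0.5);
* ``unsourced`` — coverage below threshold; these carry a bin index over
  ``[0, threshold)`` for the bin-curve analysis and are the candidates for
  the second, gold/manual step.

The word tokenizer is pluggable; the default splits on whitespace and on
Unicode script-class changes so it behaves sensibly on both spaced text and
unsegmented Japanese.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Protocol, Sequence

from .corpus import Case, DocKind, Origin, Segment, Subjectivity
from .segmentation import DEFAULT_DELIMITERS, split_sentences

__all__ = [
    "TokenizerContract",
    "ScriptTokenizer",
    "default_tokenizer",
    "BigramSet",
    "ProvenanceConfig",
    "ProvenanceResult",
    "build_bigram_set",
    "coverage_ratio",
    "classify_origin",
    "analyze_case",
    "final_origins",
    "bin_unsourced_proportions",
    "document_unsourced_rate",
    "BinStat",
]


class TokenizerContract(Protocol):
    """Deterministic map from a string to an ordered list of word tokens."""

    def __call__(self, text: str) -> Sequence[str]: ...


def _script_class(ch: str) -> str:
    if ch.isspace():
        return "space"
    if ch.isdigit():
        return "digit"
    o = ord(ch)
    if 0x3040 <= o <= 0x309F:
        return "hiragana"
    if 0x30A0 <= o <= 0x30FF:
        return "katakana"
    if 0x4E00 <= o <= 0x9FFF or 0x3400 <= o <= 0x4DBF:
        return "cjk"
    if ch.isalpha():
        return "latin"
    return "other"


class ScriptTokenizer:
    """Split on whitespace and Unicode script-class changes; drop symbols.

    A token is a maximal run of characters sharing a script class
    (latin letters, digits, hiragana, katakana, CJK ideographs).  Runs of
    punctuation and other symbols are discarded.
    """

    name = "script"

    def __call__(self, text: str) -> list[str]:
        tokens: list[str] = []
        cur: list[str] = []
        cur_cls = ""
        for ch in text:
            cls = _script_class(ch)
            if cls != cur_cls:
                if cur and cur_cls not in ("space", "other"):
                    tokens.append("".join(cur))
                cur = []
                cur_cls = cls
            cur.append(ch)
        if cur and cur_cls not in ("space", "other"):
            tokens.append("".join(cur))
        return tokens


def default_tokenizer() -> ScriptTokenizer:
    return ScriptTokenizer()


Bigram = tuple[str, str]


@dataclass(frozen=True)
class BigramSet:
    """All word bi-grams of one case's inpatient records."""

    case_id: str
    bigrams: frozenset[Bigram]
    source_doc_count: int

    def __contains__(self, pair: Bigram) -> bool:
        return pair in self.bigrams

    def __len__(self) -> int:
        return len(self.bigrams)


@dataclass(frozen=True)
class ProvenanceConfig:
    """Parameters of the first (automatic) provenance step."""

    threshold: float = 0.5
    n_bins: int = 5
    #: what to do with segments that tokenize to fewer than 2 tokens
    short_segment_policy: str = "excluded"  # or "unsourced"
    #: "occurrences" counts duplicated bi-grams; "types" counts unique ones
    count_mode: str = "occurrences"
    #: whether record bi-grams may span sentence boundaries
    cross_sentence: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.short_segment_policy not in ("excluded", "unsourced"):
            raise ValueError("short_segment_policy must be 'excluded' or 'unsourced'")
        if self.count_mode not in ("occurrences", "types"):
            raise ValueError("count_mode must be 'occurrences' or 'types'")


@dataclass(frozen=True)
class ProvenanceResult:
    """Coverage and first-step origin decision for one summary segment."""

    segment_id: str
    coverage: Optional[float]
    origin: Origin
    bin_index: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "segment_id": self.segment_id,
            "coverage": self.coverage,
            "origin": self.origin.value,
            "bin_index": self.bin_index,
        }


def _sentence_token_lists(
    text: str, tokenizer: TokenizerContract, cross_sentence: bool
) -> list[list[str]]:
    if cross_sentence:
        return [list(tokenizer(text))]
    return [
        list(tokenizer(text[a:b])) for a, b in split_sentences(text, DEFAULT_DELIMITERS)
    ]


def build_bigram_set(
    case: Case,
    tokenizer: TokenizerContract | None = None,
    cross_sentence: bool = False,
) -> BigramSet:
    """Union of adjacent-token pairs over all inpatient records of a case."""
    tokenizer = tokenizer or default_tokenizer()
    pairs: set[Bigram] = set()
    for doc in case.inpatient_records:
        for toks in _sentence_token_lists(doc.text, tokenizer, cross_sentence):
            pairs.update(zip(toks, toks[1:]))
    return BigramSet(
        case_id=case.case_id,
        bigrams=frozenset(pairs),
        source_doc_count=len(case.inpatient_records),
    )


def coverage_ratio(
    segment: Segment,
    bigrams: BigramSet,
    tokenizer: TokenizerContract | None = None,
    count_mode: str = "occurrences",
) -> Optional[float]:
    """Fraction of the segment's bi-grams found in the record bi-gram set.

    Counts token-position occurrences by default (a repeated bi-gram counts
    each time); ``count_mode="types"`` switches to unique bi-grams.  Returns
    ``None`` when the segment has fewer than two tokens.
    """
    if segment.doc_kind is not DocKind.DISCHARGE_SUMMARY:
        raise ValueError("coverage is defined for discharge summary segments only")
    tokenizer = tokenizer or default_tokenizer()
    toks = list(tokenizer(segment.text))
    pairs = list(zip(toks, toks[1:]))
    if not pairs:
        return None
    if count_mode == "types":
        uniq = set(pairs)
        return sum(1 for p in uniq if p in bigrams.bigrams) / len(uniq)
    return sum(1 for p in pairs if p in bigrams.bigrams) / len(pairs)


def _effective_subjectivity(
    segment: Segment, predicted_subjectivity: Optional[Subjectivity]
) -> Optional[Subjectivity]:
    if segment.gold_labels is not None:
        return segment.gold_labels.effective_subjectivity
    return predicted_subjectivity


def classify_origin(
    coverage: Optional[float],
    segment: Segment,
    cfg: ProvenanceConfig = ProvenanceConfig(),
    predicted_subjectivity: Optional[Subjectivity] = None,
) -> ProvenanceResult:
    """First-step origin decision for one summary segment.

    Excludes symbolic and middle-subjectivity segments (gold labels win over
    ``predicted_subjectivity`` when both exist) and, by default, segments
    with undefined coverage.  Otherwise sourced iff coverage >= threshold;
    below-threshold segments get a bin index over ``[0, threshold)``.
    """
    subj = _effective_subjectivity(segment, predicted_subjectivity)
    if segment.is_symbolic or subj is Subjectivity.MIDDLE:
        return ProvenanceResult(segment.segment_id, coverage, Origin.EXCLUDED)
    if coverage is None:
        if cfg.short_segment_policy == "excluded":
            return ProvenanceResult(segment.segment_id, None, Origin.EXCLUDED)
        return ProvenanceResult(segment.segment_id, None, Origin.UNSOURCED, None)
    if coverage >= cfg.threshold:
        return ProvenanceResult(segment.segment_id, coverage, Origin.SOURCED)
    bin_index = min(int(coverage * cfg.n_bins / cfg.threshold), cfg.n_bins - 1)
    return ProvenanceResult(segment.segment_id, coverage, Origin.UNSOURCED, bin_index)


def analyze_case(
    case: Case,
    cfg: ProvenanceConfig = ProvenanceConfig(),
    tokenizer: TokenizerContract | None = None,
    predicted: Optional[Mapping[str, Subjectivity]] = None,
) -> list[ProvenanceResult]:
    """Run the first provenance step over every summary segment of a case."""
    tokenizer = tokenizer or default_tokenizer()
    bigrams = build_bigram_set(case, tokenizer, cross_sentence=cfg.cross_sentence)
    out: list[ProvenanceResult] = []
    for seg in case.summary_segments():
        cov = coverage_ratio(seg, bigrams, tokenizer, count_mode=cfg.count_mode)
        subj = predicted.get(seg.segment_id) if predicted else None
        out.append(classify_origin(cov, seg, cfg, predicted_subjectivity=subj))
    return out


class MissingGoldOriginError(KeyError):
    def __init__(self, segment_id: str):
        self.segment_id = segment_id
        super().__init__(
            f"segment {segment_id!r}: below-threshold segment lacks a gold origin"
        )


def final_origins(
    results: Iterable[ProvenanceResult],
    gold: Mapping[str, Origin],
) -> dict[str, Origin]:
    """Two-step decision: gold overrides the machine's below-threshold calls.

    Machine-sourced and excluded segments keep their machine decision;
    machine-unsourced segments take the gold (in the study: manual) origin.
    """
    out: dict[str, Origin] = {}
    for res in results:
        if res.origin is Origin.UNSOURCED:
            if res.segment_id not in gold:
                raise MissingGoldOriginError(res.segment_id)
            out[res.segment_id] = Origin(gold[res.segment_id])
        else:
            out[res.segment_id] = res.origin
    return out


@dataclass(frozen=True)
class BinStat:
    bin_index: int
    proportion_unsourced: Optional[float]
    n: int


def bin_unsourced_proportions(
    results: Iterable[ProvenanceResult],
    gold: Mapping[str, Origin],
    cfg: ProvenanceConfig = ProvenanceConfig(),
) -> list[BinStat]:
    """Per coverage bin, the fraction of gold-unsourced segments.

    Only below-threshold, non-excluded segments with a defined bin enter;
    empty bins are reported with an undefined proportion.
    """
    counts = [0] * cfg.n_bins
    unsourced = [0] * cfg.n_bins
    for res in results:
        if res.origin is not Origin.UNSOURCED or res.bin_index is None:
            continue
        if res.segment_id not in gold:
            raise MissingGoldOriginError(res.segment_id)
        counts[res.bin_index] += 1
        if Origin(gold[res.segment_id]) is Origin.UNSOURCED:
            unsourced[res.bin_index] += 1
    return [
        BinStat(k, (unsourced[k] / counts[k]) if counts[k] else None, counts[k])
        for k in range(cfg.n_bins)
    ]


def document_unsourced_rate(
    cases: Iterable[Case],
    finals: Mapping[str, Origin],
) -> float:
    """Fraction of summaries containing >= 1 final-unsourced segment."""
    n_docs = 0
    n_hit = 0
    for case in cases:
        n_docs += 1
        if any(
            finals.get(seg.segment_id) is Origin.UNSOURCED
            for seg in case.summary_segments()
        ):
            n_hit += 1
    return n_hit / n_docs if n_docs else 0.0
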