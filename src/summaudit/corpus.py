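"""Domain types and JSON Lines I/O for paired record/summary corpora.

A corpus is a sequence of :class:`Case` objects, one JSON object per line
(UTF-8).  Each case pairs one or more free-text inpatient records with a
single discharge summary, plus a list of :class:`Segment` annotations that
may carry gold labels (three-task label set, origin, and external-source
attributions).

Serialization is canonical: keys are emitted in a fixed, documented order
(see ``_CASE_KEYS`` and ``_SEGMENT_KEYS``) with compact separators, so
equal inputs always produce byte-identical files and ``read -> write`` is
the identity on validated corpora.  Unknown fields survive round-trips via
per-object ``extras`` maps.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Optional

__all__ = [
    "Subjectivity",
    "ClinicalRole",
    "SourceGroup",
    "SourceDocLabel",
    "DocKind",
    "Section",
    "Origin",
    "LabelSet",
    "Document",
    "Segment",
    "Case",
    "CorpusError",
    "CorpusParseError",
    "CorpusValidationError",
    "ROLE_TIER",
    "SOURCE_GROUP",
    "read_corpus",
    "write_corpus",
    "iter_corpus",
    "case_to_dict",
    "case_from_dict",
]


class CorpusError(Exception):
    """Base error for corpus I/O and validation."""


class CorpusParseError(CorpusError):
    """A line of the JSONL file is not valid JSON."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class CorpusValidationError(CorpusError):
    """A case or segment violates a schema invariant."""

    def __init__(self, case_id: str, fld: str, message: str):
        self.case_id = case_id
        self.field = fld
        super().__init__(f"case {case_id!r}, field {fld!r}: {message}")


class Subjectivity(str, Enum):
    """Three-tier subjectivity grading of a clinical statement."""

    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"


class ClinicalRole(str, Enum):
    """Nine-way role of a clinical segment.

    ``probable`` is deliberately *not* a member: probabilistic hedging is a
    separate binary flag on :class:`LabelSet` that promotes the effective
    subjectivity to high.
    """

    DESCRIPTION = "description"
    ACTION = "action"
    OTHERS = "others"
    RESULT = "result"
    UNDEFINABLE = "undefinable"
    EVALUATION = "evaluation"
    DIAG = "diag"
    PLAN = "plan"
    NONFACT = "nonfact"

    @property
    def tier(self) -> Subjectivity:
        return ROLE_TIER[self]


#: Total, surjective mapping from role to subjectivity tier.
ROLE_TIER: Mapping[ClinicalRole, Subjectivity] = {
    ClinicalRole.DESCRIPTION: Subjectivity.LOW,
    ClinicalRole.ACTION: Subjectivity.LOW,
    ClinicalRole.OTHERS: Subjectivity.LOW,
    ClinicalRole.RESULT: Subjectivity.MIDDLE,
    ClinicalRole.UNDEFINABLE: Subjectivity.MIDDLE,
    ClinicalRole.EVALUATION: Subjectivity.HIGH,
    ClinicalRole.DIAG: Subjectivity.HIGH,
    ClinicalRole.PLAN: Subjectivity.HIGH,
    ClinicalRole.NONFACT: Subjectivity.HIGH,
}


class SourceGroup(str, Enum):
    PAST_HISTORY = "past_history"
    CURRENT_ADMISSION = "current_admission"
    OTHERS = "others"


class SourceDocLabel(str, Enum):
    """External document type an unsourced segment was attributed to."""

    PATIENT_REFERRAL = "patient_referral"
    OUTPATIENT_RECORDS = "outpatient_records"
    EMERGENCY_ROOM_RECORDS = "emergency_room_records"
    PAST_CLINICAL_RECORDS = "past_clinical_records"
    PRESCRIPTIONS = "prescriptions"
    NURSING_RECORDS = "nursing_records"
    EXAMINATION_RESULTS = "examination_results"
    ECG_REPORTS = "ecg_reports"
    REHABILITATION_REPORTS = "rehabilitation_reports"
    SURGICAL_NOTES = "surgical_notes"
    ANESTHESIA_RECORDS = "anesthesia_records"
    OTHER_PATIENTS_RECORDS = "other_patients_records"
    OTHER_DOCUMENTS = "other_documents"
    NO_DOCUMENT = "no_document"

    @property
    def group(self) -> SourceGroup:
        return SOURCE_GROUP[self]


SOURCE_GROUP: Mapping[SourceDocLabel, SourceGroup] = {
    SourceDocLabel.PATIENT_REFERRAL: SourceGroup.PAST_HISTORY,
    SourceDocLabel.OUTPATIENT_RECORDS: SourceGroup.PAST_HISTORY,
    SourceDocLabel.EMERGENCY_ROOM_RECORDS: SourceGroup.PAST_HISTORY,
    SourceDocLabel.PAST_CLINICAL_RECORDS: SourceGroup.PAST_HISTORY,
    SourceDocLabel.PRESCRIPTIONS: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.NURSING_RECORDS: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.EXAMINATION_RESULTS: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.ECG_REPORTS: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.REHABILITATION_REPORTS: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.SURGICAL_NOTES: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.ANESTHESIA_RECORDS: SourceGroup.CURRENT_ADMISSION,
    SourceDocLabel.OTHER_PATIENTS_RECORDS: SourceGroup.OTHERS,
    SourceDocLabel.OTHER_DOCUMENTS: SourceGroup.OTHERS,
    SourceDocLabel.NO_DOCUMENT: SourceGroup.OTHERS,
}


class DocKind(str, Enum):
    INPATIENT_RECORD = "inpatient_record"
    DISCHARGE_SUMMARY = "discharge_summary"


class Section(str, Enum):
    PRE_HOSPITAL = "pre_hospital"
    IN_HOSPITAL = "in_hospital"
    UNKNOWN = "unknown"


class Origin(str, Enum):
    """Provenance decision for a summary segment.

    Gold annotations may only use ``sourced``/``unsourced``; ``excluded`` is
    produced by the automatic pre-filter (symbols, middle subjectivity,
    too-short segments).
    """

    SOURCED = "sourced"
    UNSOURCED = "unsourced"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class LabelSet:
    """The three task labels attached to one segment."""

    subjectivity: Subjectivity
    role: ClinicalRole
    probable: bool = False

    @property
    def effective_subjectivity(self) -> Subjectivity:
        """Subjectivity used in aggregation: probable promotes to high."""
        if self.probable:
            return Subjectivity.HIGH
        return self.subjectivity

    def to_dict(self) -> dict:
        return {
            "subjectivity": self.subjectivity.value,
            "role": self.role.value,
            "probable": self.probable,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LabelSet":
        return cls(
            subjectivity=Subjectivity(d["subjectivity"]),
            role=ClinicalRole(d["role"]),
            probable=bool(d["probable"]),
        )


@dataclass
class Document:
    """One free-text document with an optional date tag."""

    text: str
    date: Optional[str] = None

    def to_dict(self) -> dict:
        return {"date": self.date, "text": self.text}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Document":
        return cls(text=d["text"], date=d.get("date"))


_SEGMENT_KEYS = (
    "segment_id",
    "case_id",
    "doc_kind",
    "doc_index",
    "char_span",
    "text",
    "section",
    "is_symbolic",
    "gold_labels",
    "gold_origin",
    "gold_sources",
)


@dataclass
class Segment:
    """A clinical segment: the atomic unit of the analysis."""

    segment_id: str
    case_id: str
    doc_kind: DocKind
    text: str
    char_span: tuple[int, int]
    section: Section = Section.UNKNOWN
    is_symbolic: bool = False
    doc_index: int = 0
    gold_labels: Optional[LabelSet] = None
    gold_origin: Optional[Origin] = None
    gold_sources: Optional[frozenset[SourceDocLabel]] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "segment_id": self.segment_id,
            "case_id": self.case_id,
            "doc_kind": self.doc_kind.value,
            "doc_index": self.doc_index,
            "char_span": list(self.char_span),
            "text": self.text,
            "section": self.section.value,
            "is_symbolic": self.is_symbolic,
        }
        if self.gold_labels is not None:
            d["gold_labels"] = self.gold_labels.to_dict()
        if self.gold_origin is not None:
            d["gold_origin"] = self.gold_origin.value
        if self.gold_sources is not None:
            d["gold_sources"] = sorted(s.value for s in self.gold_sources)
        for k in sorted(self.extras):
            if k not in _SEGMENT_KEYS:
                d[k] = self.extras[k]
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Segment":
        extras = {k: v for k, v in d.items() if k not in _SEGMENT_KEYS}
        gold_sources = None
        if d.get("gold_sources") is not None:
            gold_sources = frozenset(SourceDocLabel(s) for s in d["gold_sources"])
        return cls(
            segment_id=d["segment_id"],
            case_id=d["case_id"],
            doc_kind=DocKind(d["doc_kind"]),
            doc_index=int(d.get("doc_index", 0)),
            char_span=(int(d["char_span"][0]), int(d["char_span"][1])),
            text=d["text"],
            section=Section(d.get("section", "unknown")),
            is_symbolic=bool(d.get("is_symbolic", False)),
            gold_labels=(
                LabelSet.from_dict(d["gold_labels"])
                if d.get("gold_labels") is not None
                else None
            ),
            gold_origin=(
                Origin(d["gold_origin"]) if d.get("gold_origin") is not None else None
            ),
            gold_sources=gold_sources,
            extras=extras,
        )


_CASE_KEYS = (
    "case_id",
    "hospital_id",
    "inpatient_records",
    "discharge_summary",
    "segments",
)


@dataclass
class Case:
    """One admission: inpatient records, a discharge summary, and segments."""

    case_id: str
    hospital_id: str
    inpatient_records: list[Document]
    discharge_summary: Document
    segments: list[Segment] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.inpatient_records:
            raise CorpusValidationError(
                self.case_id, "inpatient_records", "at least one inpatient record required"
            )
        for seg in self.segments:
            self._validate_segment(seg)

    def _parent_text(self, seg: Segment) -> str:
        if seg.doc_kind is DocKind.DISCHARGE_SUMMARY:
            return self.discharge_summary.text
        if not (0 <= seg.doc_index < len(self.inpatient_records)):
            raise CorpusValidationError(
                self.case_id, "doc_index", f"segment {seg.segment_id}: index out of range"
            )
        return self.inpatient_records[seg.doc_index].text

    def _validate_segment(self, seg: Segment) -> None:
        cid = self.case_id
        if seg.case_id != cid:
            raise CorpusValidationError(
                cid, "case_id", f"segment {seg.segment_id} carries case_id {seg.case_id!r}"
            )
        start, end = seg.char_span
        if not end > start:
            raise CorpusValidationError(
                cid, "char_span", f"segment {seg.segment_id}: end must exceed start"
            )
        parent = self._parent_text(seg)
        if parent[start:end] != seg.text:
            raise CorpusValidationError(
                cid,
                "char_span",
                f"segment {seg.segment_id}: text does not match parent document span",
            )
        if seg.doc_kind is not DocKind.DISCHARGE_SUMMARY:
            if seg.gold_origin is not None or seg.gold_sources is not None:
                raise CorpusValidationError(
                    cid,
                    "gold_origin",
                    f"segment {seg.segment_id}: origin annotations only on summary segments",
                )
        if seg.gold_origin is Origin.EXCLUDED:
            raise CorpusValidationError(
                cid, "gold_origin", f"segment {seg.segment_id}: gold origin must be sourced/unsourced"
            )
        has_sources = bool(seg.gold_sources)
        if seg.gold_origin is Origin.UNSOURCED and not has_sources:
            raise CorpusValidationError(
                cid, "gold_sources", f"segment {seg.segment_id}: unsourced segment needs sources"
            )
        if has_sources and seg.gold_origin is not Origin.UNSOURCED:
            raise CorpusValidationError(
                cid, "gold_sources", f"segment {seg.segment_id}: sources only on unsourced segments"
            )

    # -- convenience --------------------------------------------------------

    def summary_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.doc_kind is DocKind.DISCHARGE_SUMMARY]


def case_to_dict(case: Case) -> dict:
    d: dict[str, Any] = {
        "case_id": case.case_id,
        "hospital_id": case.hospital_id,
        "inpatient_records": [doc.to_dict() for doc in case.inpatient_records],
        "discharge_summary": case.discharge_summary.to_dict(),
        "segments": [seg.to_dict() for seg in case.segments],
    }
    for k in sorted(case.extras):
        if k not in _CASE_KEYS:
            d[k] = case.extras[k]
    return d


def case_from_dict(d: Mapping[str, Any]) -> Case:
    extras = {k: v for k, v in d.items() if k not in _CASE_KEYS}
    return Case(
        case_id=d["case_id"],
        hospital_id=d["hospital_id"],
        inpatient_records=[Document.from_dict(r) for r in d["inpatient_records"]],
        discharge_summary=Document.from_dict(d["discharge_summary"]),
        segments=[Segment.from_dict(s) for s in d.get("segments", [])],
        extras=extras,
    )


def _dumps(obj: Any) -> str:
    return json.dumps(obj, ensure_ascii=False, separators=(",", ":"))


def iter_corpus(path: str | Path) -> Iterator[Case]:
    """Stream validated cases from a JSONL file, in file order."""
    with io.open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(lineno, str(exc)) from exc
            case = case_from_dict(obj)
            case.validate()
            yield case


def read_corpus(path: str | Path) -> list[Case]:
    """Read and validate every case of a JSONL corpus."""
    return list(iter_corpus(path))


def write_corpus(cases: Iterable[Case], path: str | Path) -> None:
    """Write cases as canonical JSONL; deterministic bytes for equal input."""
    path = Path(path)
    lines = []
    for case in cases:
        case.validate()
        lines.append(_dumps(case_to_dict(case)))
    payload = "".join(line + "\n" for line in lines)
    path.write_text(payload, encoding="utf-8")
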