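import numpy as np
import pytest

from summaudit.corpus import (
    Case,
    ClinicalRole,
    DocKind,
    Document,
    LabelSet,
    Origin,
    ROLE_TIER,
    Section,
    Segment,
    SourceDocLabel,
    Subjectivity,
)


def build_case(case_id="c1", hospital_id="H01", records=("a b c\nd e f",), seg_specs=()):
    """Assemble a valid Case whose summary is the newline-join of segment texts.

    ``seg_specs`` entries are dicts: text (required), section, is_symbolic,
    labels (LabelSet), origin (Origin), sources (iterable of SourceDocLabel).
    """
    texts = [s["text"] for s in seg_specs]
    summary = "\n".join(texts)
    case = Case(
        case_id=case_id,
        hospital_id=hospital_id,
        inpatient_records=[Document(text=r) for r in records],
        discharge_summary=Document(text=summary),
    )
    pos = 0
    for i, spec in enumerate(seg_specs):
        text = spec["text"]
        start, end = pos, pos + len(text)
        pos = end + 1
        sources = spec.get("sources")
        case.segments.append(
            Segment(
                segment_id=f"{case_id}-s{i:03d}",
                case_id=case_id,
                doc_kind=DocKind.DISCHARGE_SUMMARY,
                text=text,
                char_span=(start, end),
                section=spec.get("section", Section.UNKNOWN),
                is_symbolic=spec.get("is_symbolic", False),
                gold_labels=spec.get("labels"),
                gold_origin=spec.get("origin"),
                gold_sources=frozenset(sources) if sources else None,
            )
        )
    case.validate()
    return case


def labels(role=ClinicalRole.DESCRIPTION, probable=False, subjectivity=None):
    subj = subjectivity
    if subj is None:
        subj = Subjectivity.HIGH if probable else ROLE_TIER[role]
    return LabelSet(subjectivity=subj, role=role, probable=probable)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_case():
    return build_case(
        records=("aa bb cc dd\nee ff gg",),
        seg_specs=[
            {
                "text": "aa bb cc dd",
                "labels": labels(),
                "origin": Origin.SOURCED,
                "section": Section.PRE_HOSPITAL,
            },
            {
                "text": "xx yy zz ww",
                "labels": labels(ClinicalRole.DIAG),
                "origin": Origin.UNSOURCED,
                "sources": [SourceDocLabel.PAST_CLINICAL_RECORDS],
                "section": Section.IN_HOSPITAL,
            },
            {
                "text": "2020/04/10",
                "is_symbolic": True,
                "labels": labels(ClinicalRole.OTHERS),
            },
        ],
    )
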