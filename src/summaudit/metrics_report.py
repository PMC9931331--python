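"""Evaluation metrics and stratified unsourced-rate / attribution tables.

Two families live here:

* :func:`evaluate` — per-class and macro precision/recall/F1 for the three
  labeling tasks (zero-denominator conventions: P, R, F1 are 0).
* breakdown builders — unsourced rates stratified by label tier and role,
  by pre-/in-hospital section, and by hospital; the multi-label attribution
  of unsourced segments over the 14 external-source document types; and the
  overall share-of-information breakdown combining the sourced rate with
  the attribution mixture.

Excluded segments (symbols, middle subjectivity, too short) never enter any
rate.  Stratification labels default to each segment's gold labels; a
mapping of predicted labels may be supplied instead, mirroring the use of
an automatic labeler on unannotated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .corpus import (
    ClinicalRole,
    LabelSet,
    Origin,
    Section,
    Segment,
    SourceDocLabel,
    Subjectivity,
)

__all__ = [
    "ClassMetrics",
    "MetricReport",
    "BreakdownRow",
    "BreakdownTable",
    "evaluate",
    "unsourced_by_label",
    "unsourced_by_section",
    "unsourced_by_hospital",
    "attribution_breakdown",
    "overall_breakdown",
]


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _prf(tp: int, fp: int, fn: int) -> ClassMetrics:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * r * p / (r + p) if r + p else 0.0
    return ClassMetrics(tp, fp, fn, p, r, f1)


@dataclass
class MetricReport:
    """Per-class and macro P/R/F1 for subjectivity, role, and probable."""

    per_class: dict  # task -> {class value -> ClassMetrics}
    macro_f1: dict  # task -> float

    def to_dict(self) -> dict:
        return {
            "per_class": {
                task: {
                    str(cls): vars(m) for cls, m in classes.items()
                }
                for task, classes in self.per_class.items()
            },
            "macro_f1": dict(self.macro_f1),
        }


def _task_values(ls: LabelSet) -> dict:
    return {
        "subjectivity": ls.effective_subjectivity.value,
        "role": ls.role.value,
        "probable": ls.probable,
    }


def evaluate(pred: Sequence[LabelSet], gold: Sequence[LabelSet]) -> MetricReport:
    """Count-based P/R/F1 per class and macro average per task.

    Macro averages run over the classes present in gold or predictions.
    Subjectivity is compared after the probable-promotes-to-high rule.
    """
    if len(pred) != len(gold):
        raise ValueError("prediction and gold lists differ in length")
    per_class: dict = {}
    macro: dict = {}
    for task in ("subjectivity", "role", "probable"):
        pv = [_task_values(p)[task] for p in pred]
        gv = [_task_values(g)[task] for g in gold]
        classes = sorted(set(pv) | set(gv), key=str)
        stats = {}
        for cls in classes:
            tp = sum(1 for a, b in zip(pv, gv) if a == cls and b == cls)
            fp = sum(1 for a, b in zip(pv, gv) if a == cls and b != cls)
            fn = sum(1 for a, b in zip(pv, gv) if a != cls and b == cls)
            stats[cls] = _prf(tp, fp, fn)
        per_class[task] = stats
        macro[task] = (
            sum(m.f1 for m in stats.values()) / len(stats) if stats else 0.0
        )
    return MetricReport(per_class=per_class, macro_f1=macro)


# ---------------------------------------------------------------------------
# stratified breakdowns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakdownRow:
    key: str
    n: int
    rate: Optional[float]
    extra: tuple = ()  # extra (name, value) pairs, e.g. high-subjectivity rate

    def to_dict(self) -> dict:
        d = {"key": self.key, "n": self.n, "rate": self.rate}
        d.update(dict(self.extra))
        return d


@dataclass
class BreakdownTable:
    name: str
    rows: list[BreakdownRow] = field(default_factory=list)

    def row(self, key: str) -> BreakdownRow:
        for r in self.rows:
            if r.key == key:
                return r
        raise KeyError(key)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.to_dict() for r in self.rows])


def _labels_for(
    segments: Sequence[Segment], labels: Optional[Mapping[str, LabelSet]]
) -> dict[str, LabelSet]:
    out: dict[str, LabelSet] = {}
    for seg in segments:
        if labels is not None and seg.segment_id in labels:
            out[seg.segment_id] = labels[seg.segment_id]
        elif seg.gold_labels is not None:
            out[seg.segment_id] = seg.gold_labels
        else:
            raise ValueError(
                f"segment {seg.segment_id!r} has neither gold nor supplied labels"
            )
    return out


def _rate(unsourced: int, n: int) -> Optional[float]:
    return unsourced / n if n else None


def _included(seg: Segment, finals: Mapping[str, Origin]) -> bool:
    # symbolic segments can never enter a rate, whatever their final origin
    if seg.is_symbolic:
        return False
    return finals.get(seg.segment_id) in (Origin.SOURCED, Origin.UNSOURCED)


def unsourced_by_label(
    segments: Sequence[Segment],
    finals: Mapping[str, Origin],
    labels: Optional[Mapping[str, LabelSet]] = None,
) -> BreakdownTable:
    """Unsourced rates per subjectivity tier, per role, and for probable.

    Middle-subjectivity and excluded segments never enter.  The ``all`` row
    is the weighted average of the low and high tiers; role rows and tier
    rows are computed independently of each other (the label tasks are
    separate), and ``probable`` is its own row.
    """
    lab = _labels_for(segments, labels)
    table = BreakdownTable("unsourced_by_label")

    def add(key: str, members: list[Segment]) -> None:
        n = len(members)
        uns = sum(
            1 for s in members if finals[s.segment_id] is Origin.UNSOURCED
        )
        table.rows.append(BreakdownRow(key, n, _rate(uns, n)))

    included = [s for s in segments if _included(s, finals)]
    low = [
        s for s in included
        if lab[s.segment_id].effective_subjectivity is Subjectivity.LOW
    ]
    high = [
        s for s in included
        if lab[s.segment_id].effective_subjectivity is Subjectivity.HIGH
    ]
    add("all", low + high)
    add("low", low)
    add("high", high)
    for role in (
        ClinicalRole.DESCRIPTION,
        ClinicalRole.ACTION,
        ClinicalRole.OTHERS,
        ClinicalRole.EVALUATION,
        ClinicalRole.DIAG,
        ClinicalRole.PLAN,
        ClinicalRole.NONFACT,
    ):
        add(role.value, [s for s in included if lab[s.segment_id].role is role])
    add("probable", [s for s in included if lab[s.segment_id].probable])
    return table


def unsourced_by_section(
    segments: Sequence[Segment],
    finals: Mapping[str, Origin],
    labels: Optional[Mapping[str, LabelSet]] = None,
) -> BreakdownTable:
    """Unsourced and high-subjectivity rates for pre-/in-hospital sections.

    Segments with unknown section are reported in neither row.
    """
    lab = _labels_for(segments, labels)
    included = [s for s in segments if _included(s, finals)]
    table = BreakdownTable("unsourced_by_section")
    for section in (Section.PRE_HOSPITAL, Section.IN_HOSPITAL):
        members = [s for s in included if s.section is section]
        n = len(members)
        uns = sum(1 for s in members if finals[s.segment_id] is Origin.UNSOURCED)
        hi = sum(
            1
            for s in members
            if lab[s.segment_id].effective_subjectivity is Subjectivity.HIGH
        )
        table.rows.append(
            BreakdownRow(
                section.value,
                n,
                _rate(uns, n),
                extra=(("high_subjectivity_rate", _rate(hi, n)),),
            )
        )
    return table


def unsourced_by_hospital(
    cases: Iterable,
    finals: Mapping[str, Origin],
    labels: Optional[Mapping[str, LabelSet]] = None,
) -> BreakdownTable:
    """Unsourced and high-subjectivity rates per hospital.

    Hospitals whose segments are all excluded are omitted (a warning-level
    situation surfaced by n=0 absence, not an error).
    """
    by_hosp: dict[str, list[Segment]] = {}
    all_segments: list[Segment] = []
    for case in cases:
        segs = [s for s in case.summary_segments()]
        by_hosp.setdefault(case.hospital_id, []).extend(segs)
        all_segments.extend(segs)
    lab = _labels_for(all_segments, labels)
    table = BreakdownTable("unsourced_by_hospital")
    for hosp in sorted(by_hosp):
        members = [s for s in by_hosp[hosp] if _included(s, finals)]
        n = len(members)
        if n == 0:
            continue
        uns = sum(1 for s in members if finals[s.segment_id] is Origin.UNSOURCED)
        hi = sum(
            1
            for s in members
            if lab[s.segment_id].effective_subjectivity is Subjectivity.HIGH
        )
        table.rows.append(
            BreakdownRow(
                hosp,
                n,
                _rate(uns, n),
                extra=(("high_subjectivity_rate", _rate(hi, n)),),
            )
        )
    return table


_ATTRIB_STRATA = ("all", "low_subj", "high_subj", "pre_hosp", "in_hosp")


def attribution_breakdown(
    segments: Sequence[Segment],
    finals: Mapping[str, Origin],
    labels: Optional[Mapping[str, LabelSet]] = None,
) -> BreakdownTable:
    """Percentage of each of the 14 external sources among assigned labels.

    Runs over final-unsourced segments; each segment may carry several
    source labels and every assigned label counts once, so percentages are
    relative to the total number of assigned labels per stratum (overall,
    low/high subjectivity, pre-/in-hospital).
    """
    lab = _labels_for(segments, labels)
    unsourced = [
        s for s in segments if finals.get(s.segment_id) is Origin.UNSOURCED
    ]
    counts = {stratum: {l: 0 for l in SourceDocLabel} for stratum in _ATTRIB_STRATA}
    totals = {stratum: 0 for stratum in _ATTRIB_STRATA}
    for seg in unsourced:
        if not seg.gold_sources:
            raise ValueError(
                f"segment {seg.segment_id!r}: unsourced segment with no source labels"
            )
        strata = ["all"]
        subj = lab[seg.segment_id].effective_subjectivity
        if subj is Subjectivity.LOW:
            strata.append("low_subj")
        elif subj is Subjectivity.HIGH:
            strata.append("high_subj")
        if seg.section is Section.PRE_HOSPITAL:
            strata.append("pre_hosp")
        elif seg.section is Section.IN_HOSPITAL:
            strata.append("in_hosp")
        for src in sorted(seg.gold_sources, key=lambda s: s.value):
            for stratum in strata:
                counts[stratum][src] += 1
                totals[stratum] += 1
    table = BreakdownTable("attribution")
    for src in SourceDocLabel:
        extra = []
        for stratum in _ATTRIB_STRATA[1:]:
            pct = (
                100.0 * counts[stratum][src] / totals[stratum]
                if totals[stratum]
                else None
            )
            extra.append((stratum + "_pct", pct))
        extra.append(("group", src.group.value))
        table.rows.append(
            BreakdownRow(
                src.value,
                counts["all"][src],
                (
                    100.0 * counts["all"][src] / totals["all"]
                    if totals["all"]
                    else None
                ),
                extra=tuple(extra),
            )
        )
    return table


def overall_breakdown(
    sourced_rate: float, attribution: BreakdownTable
) -> list[tuple[str, float]]:
    """Share of each information source in the summaries (conserves mass).

    The inpatient-record share equals the sourced rate; each external source
    takes ``(1 - sourced_rate)`` times its attribution share.  Shares sum to
    1 whenever the attribution percentages sum to 100.
    """
    if not (0.0 <= sourced_rate <= 1.0):
        raise ValueError("sourced_rate must be in [0, 1]")
    out: list[tuple[str, float]] = [("inpatient_records", sourced_rate)]
    for row in attribution.rows:
        pct = row.rate or 0.0
        out.append((row.key, (1.0 - sourced_rate) * pct / 100.0))
    return out
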