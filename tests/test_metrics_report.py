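import numpy as np
import pytest

from summaudit.corpus import (
    ClinicalRole,
    LabelSet,
    Origin,
    Section,
    SourceDocLabel,
    Subjectivity,
)
from summaudit.metrics_report import (
    BreakdownTable,
    attribution_breakdown,
    evaluate,
    overall_breakdown,
    unsourced_by_hospital,
    unsourced_by_label,
    unsourced_by_section,
)

from conftest import build_case, labels


def ls(role=ClinicalRole.DESCRIPTION, probable=False):
    return labels(role=role, probable=probable)


class TestEvaluate:
    def test_perfect_predictions(self):
        gold = [ls(), ls(ClinicalRole.DIAG), ls(probable=True)]
        rep = evaluate(gold, gold)
        for task in ("subjectivity", "role", "probable"):
            assert rep.macro_f1[task] == 1.0
            for m in rep.per_class[task].values():
                assert m.f1 == 1.0

    def test_f1_equals_p_when_p_equals_r(self):
        # one description <-> diag swap in each direction keeps P == R
        gold = [ls(), ls(ClinicalRole.DIAG), ls(), ls(ClinicalRole.DIAG)]
        pred = [ls(ClinicalRole.DIAG), ls(), ls(), ls(ClinicalRole.DIAG)]
        rep = evaluate(pred, gold)
        m = rep.per_class["role"]["description"]
        assert m.precision == m.recall == m.f1 == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([ls()], [])

    def test_zero_denominator_convention(self):
        gold = [ls(ClinicalRole.NONFACT)]
        pred = [ls(ClinicalRole.DIAG)]
        rep = evaluate(pred, gold)
        assert rep.per_class["role"]["nonfact"].f1 == 0.0
        assert rep.per_class["role"]["diag"].precision == 0.0

    def test_matches_sklearn_confusion_oracle(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        roles = list(ClinicalRole)
        gold = [ls(roles[i]) for i in rng.integers(0, 9, size=200)]
        pred = [ls(roles[i]) for i in rng.integers(0, 9, size=200)]
        rep = evaluate(pred, gold)
        gv = [g.role.value for g in gold]
        pv = [p.role.value for p in pred]
        classes = sorted(set(gv) | set(pv))
        p, r, f, _ = precision_recall_fscore_support(
            gv, pv, labels=classes, zero_division=0
        )
        for cls, pi, ri, fi in zip(classes, p, r, f):
            m = rep.per_class["role"][cls]
            assert m.precision == pytest.approx(pi)
            assert m.recall == pytest.approx(ri)
            assert m.f1 == pytest.approx(fi)
        assert rep.macro_f1["role"] == pytest.approx(float(np.mean(f)))


def make_strata_fixture():
    """20 segments: 8 low (4 unsourced), 8 high (4 unsourced), 2 middle, 2 symbolic."""
    specs = []
    finals = {}
    src = [SourceDocLabel.PAST_CLINICAL_RECORDS]
    for i in range(8):
        uns = i < 4
        specs.append(
            {
                "text": f"low seg {i}",
                "labels": ls(ClinicalRole.DESCRIPTION),
                "origin": Origin.UNSOURCED if uns else Origin.SOURCED,
                "sources": src if uns else None,
                "section": Section.PRE_HOSPITAL,
            }
        )
    for i in range(8):
        uns = i < 4
        specs.append(
            {
                "text": f"high seg {i}",
                "labels": ls(ClinicalRole.DIAG),
                "origin": Origin.UNSOURCED if uns else Origin.SOURCED,
                "sources": src if uns else None,
                "section": Section.IN_HOSPITAL,
            }
        )
    for i in range(2):
        specs.append({"text": f"mid seg {i}", "labels": ls(ClinicalRole.RESULT)})
    for i in range(2):
        specs.append(
            {"text": f"2020/0{i+1}/01", "labels": ls(ClinicalRole.OTHERS), "is_symbolic": True}
        )
    case = build_case(records=("rec a b",), seg_specs=specs)
    for seg in case.summary_segments():
        if seg.is_symbolic or seg.gold_labels.role is ClinicalRole.RESULT:
            finals[seg.segment_id] = Origin.EXCLUDED
        else:
            finals[seg.segment_id] = seg.gold_origin
    return case, finals


class TestUnsourcedByLabel:
    def test_hand_computed_rates(self):
        case, finals = make_strata_fixture()
        table = unsourced_by_label(case.summary_segments(), finals)
        assert table.row("all").rate == 0.5
        assert table.row("all").n == 16
        assert table.row("low").rate == 0.5
        assert table.row("high").rate == 0.5
        assert table.row("description").rate == 0.5
        assert table.row("diag").rate == 0.5
        assert table.row("nonfact").n == 0 and table.row("nonfact").rate is None

    def test_all_row_weighted_average(self):
        # all low unsourced, all high sourced, equal n -> All = 0.5
        specs = []
        for i in range(5):
            specs.append(
                {
                    "text": f"l{i} x",
                    "labels": ls(),
                    "origin": Origin.UNSOURCED,
                    "sources": [SourceDocLabel.NO_DOCUMENT],
                }
            )
            specs.append(
                {"text": f"h{i} x", "labels": ls(ClinicalRole.PLAN), "origin": Origin.SOURCED}
            )
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: s.gold_origin for s in case.summary_segments()}
        table = unsourced_by_label(case.summary_segments(), finals)
        assert table.row("all").rate == 0.5
        assert table.row("low").rate == 1.0
        assert table.row("high").rate == 0.0

    def test_middle_and_symbolic_never_change_all(self):
        """Origins assigned to middle/symbolic segments cannot move 'all'."""
        case, finals = make_strata_fixture()
        base = unsourced_by_label(case.summary_segments(), finals).row("all")
        middle_ids = {
            s.segment_id
            for s in case.summary_segments()
            if s.gold_labels.role is ClinicalRole.RESULT
        }
        for flip in (Origin.SOURCED, Origin.UNSOURCED):
            flipped = {
                sid: (flip if sid in middle_ids else o) for sid, o in finals.items()
            }
            table = unsourced_by_label(case.summary_segments(), flipped)
            assert table.row("all").rate == base.rate
            assert table.row("all").n == base.n

    def test_probable_row(self):
        specs = [
            {
                "text": "p1 x",
                "labels": ls(probable=True),
                "origin": Origin.UNSOURCED,
                "sources": [SourceDocLabel.NO_DOCUMENT],
            },
            {"text": "p2 x", "labels": ls(probable=True), "origin": Origin.SOURCED},
            {"text": "d x", "labels": ls(), "origin": Origin.SOURCED},
        ]
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: s.gold_origin for s in case.summary_segments()}
        table = unsourced_by_label(case.summary_segments(), finals)
        assert table.row("probable").n == 2
        assert table.row("probable").rate == 0.5


class TestUnsourcedBySection:
    def test_rates_and_high_subjectivity(self):
        case, finals = make_strata_fixture()
        table = unsourced_by_section(case.summary_segments(), finals)
        pre = table.row("pre_hospital")
        inh = table.row("in_hospital")
        assert pre.n == 8 and pre.rate == 0.5
        assert dict(pre.extra)["high_subjectivity_rate"] == 0.0
        assert inh.n == 8 and inh.rate == 0.5
        assert dict(inh.extra)["high_subjectivity_rate"] == 1.0

    def test_single_section_corpus(self):
        specs = [
            {
                "text": "a x",
                "labels": ls(),
                "origin": Origin.SOURCED,
                "section": Section.PRE_HOSPITAL,
            }
        ]
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: Origin.SOURCED for s in case.summary_segments()}
        table = unsourced_by_section(case.summary_segments(), finals)
        assert table.row("in_hospital").n == 0
        assert table.row("in_hospital").rate is None

    def test_unknown_section_excluded_from_both(self):
        specs = [
            {"text": "u x", "labels": ls(), "origin": Origin.SOURCED},  # unknown
            {
                "text": "p x",
                "labels": ls(),
                "origin": Origin.SOURCED,
                "section": Section.PRE_HOSPITAL,
            },
        ]
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: Origin.SOURCED for s in case.summary_segments()}
        table = unsourced_by_section(case.summary_segments(), finals)
        assert table.row("pre_hospital").n == 1
        assert table.row("in_hospital").n == 0


class TestUnsourcedByHospital:
    def test_single_hospital_equals_global(self):
        case, finals = make_strata_fixture()
        table = unsourced_by_hospital([case], finals)
        assert len(table.rows) == 1
        assert table.rows[0].key == "H01"
        assert table.rows[0].rate == 0.5

    def test_empty_hospital_omitted(self):
        case, finals = make_strata_fixture()
        empty = build_case(
            case_id="c9",
            hospital_id="H99",
            seg_specs=[{"text": "2020/01/01", "is_symbolic": True, "labels": ls(ClinicalRole.OTHERS)}],
        )
        finals = dict(finals)
        finals[empty.segments[0].segment_id] = Origin.EXCLUDED
        table = unsourced_by_hospital([case, empty], finals)
        assert [r.key for r in table.rows] == ["H01"]


class TestAttribution:
    def test_all_no_document(self):
        specs = [
            {
                "text": f"s{i} x",
                "labels": ls(),
                "origin": Origin.UNSOURCED,
                "sources": [SourceDocLabel.NO_DOCUMENT],
            }
            for i in range(3)
        ]
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: Origin.UNSOURCED for s in case.summary_segments()}
        table = attribution_breakdown(case.summary_segments(), finals)
        assert table.row("no_document").rate == 100.0
        assert table.row("patient_referral").rate == 0.0

    def test_multi_label_counts_in_denominator(self):
        specs = [
            {
                "text": "s1 x",
                "labels": ls(),
                "origin": Origin.UNSOURCED,
                "sources": [
                    SourceDocLabel.PATIENT_REFERRAL,
                    SourceDocLabel.PAST_CLINICAL_RECORDS,
                ],
            },
            {
                "text": "s2 x",
                "labels": ls(),
                "origin": Origin.UNSOURCED,
                "sources": [SourceDocLabel.NO_DOCUMENT],
            },
        ]
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: Origin.UNSOURCED for s in case.summary_segments()}
        table = attribution_breakdown(case.summary_segments(), finals)
        # 3 assigned labels total
        assert table.row("patient_referral").rate == pytest.approx(100 / 3)
        assert table.row("no_document").rate == pytest.approx(100 / 3)

    def test_percentages_sum_to_100(self):
        case, finals = make_strata_fixture()
        table = attribution_breakdown(case.summary_segments(), finals)
        total = sum(r.rate for r in table.rows)
        assert total == pytest.approx(100.0, abs=0.1)

    def test_unsourced_without_sources_errors(self):
        specs = [{"text": "s x", "labels": ls(), "origin": Origin.SOURCED}]
        case = build_case(seg_specs=specs)
        finals = {s.segment_id: Origin.UNSOURCED for s in case.summary_segments()}
        with pytest.raises(ValueError, match="no source labels"):
            attribution_breakdown(case.summary_segments(), finals)


class TestOverallBreakdown:
    def _attribution(self, pcts):
        from summaudit.metrics_report import BreakdownRow

        table = BreakdownTable("attribution")
        for k, v in pcts.items():
            table.rows.append(BreakdownRow(k, 0, v))
        return table

    def test_reference_share(self):
        # sourced 0.613 with 43.3% attribution -> past-records share ~17%
        table = self._attribution({"past_clinical_records": 43.3, "other": 56.7})
        shares = dict(overall_breakdown(0.613, table))
        assert shares["inpatient_records"] == 0.613
        assert shares["past_clinical_records"] == pytest.approx(0.1676, abs=5e-4)

    def test_fully_sourced_single_nonzero_entry(self):
        table = self._attribution({"no_document": 100.0})
        shares = overall_breakdown(1.0, table)
        nonzero = [(k, v) for k, v in shares if v > 0]
        assert nonzero == [("inpatient_records", 1.0)]

    def test_conservation(self, rng):
        for _ in range(50):
            raw = rng.random(14)
            pcts = {f"l{i}": 100 * v / raw.sum() for i, v in enumerate(raw)}
            rate = float(rng.random())
            shares = overall_breakdown(rate, self._attribution(pcts))
            assert sum(v for _, v in shares) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            overall_breakdown(1.5, self._attribution({}))
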