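"""Synthetic paired-corpus generator with planted, recoverable ground truth.

Cases are built from synthetic token sequences (not natural language): every
downstream computation — bi-gram coverage, template-based classification,
stratified rates — is content agnostic given the tokenizer and encoder
contracts.  The generator plants:

* provenance: sourced summary segments are token-perturbed copies of record
  sentences (realized coverage is re-checked and kept >= the threshold);
  unsourced segments draw their content tokens from per-source external
  vocabularies disjoint from the record vocabulary, so their coverage stays
  below threshold;
* labels: each role has distinctive marker tokens, mirroring cue words, so
  classifier recovery is well posed; the probable flag promotes gold
  subjectivity to high; symbolic/date segments are injected at a configured
  rate;
* strata: per-tier, per-section, and per-hospital unsourced probabilities,
  a 14-way attribution mixture with optional multi-labels.

Fixed seeds give byte-identical corpora through the canonical writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import (
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
from .provenance import BigramSet, build_bigram_set, default_tokenizer

__all__ = [
    "SynthConfig",
    "HospitalProfile",
    "GenerationError",
    "DEFAULT_ROLE_MIX",
    "DEFAULT_ATTRIBUTION_MIXTURE",
    "generate_corpus",
    "generate_gradient_corpus",
    "table_preset",
]


class GenerationError(ValueError):
    """The generator configuration is invalid or infeasible."""


#: Role frequencies loosely shaped like a manually annotated record set.
DEFAULT_ROLE_MIX: dict[ClinicalRole, float] = {
    ClinicalRole.DESCRIPTION: 0.37,
    ClinicalRole.ACTION: 0.20,
    ClinicalRole.OTHERS: 0.02,
    ClinicalRole.RESULT: 0.08,
    ClinicalRole.UNDEFINABLE: 0.09,
    ClinicalRole.EVALUATION: 0.07,
    ClinicalRole.DIAG: 0.06,
    ClinicalRole.PLAN: 0.07,
    ClinicalRole.NONFACT: 0.04,
}

#: Default 14-way external-source mixture (sums to 1).
DEFAULT_ATTRIBUTION_MIXTURE: dict[SourceDocLabel, float] = {
    SourceDocLabel.PATIENT_REFERRAL: 0.184,
    SourceDocLabel.OUTPATIENT_RECORDS: 0.066,
    SourceDocLabel.EMERGENCY_ROOM_RECORDS: 0.039,
    SourceDocLabel.PAST_CLINICAL_RECORDS: 0.433,
    SourceDocLabel.PRESCRIPTIONS: 0.020,
    SourceDocLabel.NURSING_RECORDS: 0.015,
    SourceDocLabel.EXAMINATION_RESULTS: 0.057,
    SourceDocLabel.ECG_REPORTS: 0.000,
    SourceDocLabel.REHABILITATION_REPORTS: 0.015,
    SourceDocLabel.SURGICAL_NOTES: 0.007,
    SourceDocLabel.ANESTHESIA_RECORDS: 0.000,
    SourceDocLabel.OTHER_PATIENTS_RECORDS: 0.035,
    SourceDocLabel.OTHER_DOCUMENTS: 0.020,
    SourceDocLabel.NO_DOCUMENT: 0.109,
}

_ROLE_CODES: dict[ClinicalRole, str] = {
    ClinicalRole.DESCRIPTION: "des",
    ClinicalRole.ACTION: "act",
    ClinicalRole.OTHERS: "oth",
    ClinicalRole.RESULT: "res",
    ClinicalRole.UNDEFINABLE: "und",
    ClinicalRole.EVALUATION: "eva",
    ClinicalRole.DIAG: "dia",
    ClinicalRole.PLAN: "pla",
    ClinicalRole.NONFACT: "non",
}

_MARKERS_PER_ROLE = 4


@dataclass(frozen=True)
class HospitalProfile:
    hospital_id: str
    unsourced_prob: Optional[float] = None
    weight: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; see module docstring for semantics.

    When several unsourced-probability knobs are set at once, they combine
    multiplicatively relative to the base ``unsourced_prob`` (each override
    alone reproduces its planted rate exactly; combined they shape gradients
    qualitatively).  Probabilities are clipped to [0, 1].
    """

    n_cases: int = 100
    records_per_case: int = 3
    segments_per_summary: int = 10
    distractor_sentences_per_record: int = 3
    unsourced_prob: float = 0.387
    tier_unsourced_probs: Optional[dict[str, float]] = None  # {"low":…, "high":…}
    section_unsourced_probs: Optional[dict[str, float]] = None  # {"pre_hospital":…,…}
    section_mix: float = 0.5
    attribution_mixture: dict[SourceDocLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTION_MIXTURE)
    )
    multi_label_prob: float = 0.1
    symbolic_prob: float = 0.05
    middle_prob: Optional[float] = None
    probable_prob: float = 0.1
    role_mix: dict[ClinicalRole, float] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_MIX)
    )
    hospital_profiles: tuple[HospitalProfile, ...] = (HospitalProfile("H01"),)
    coverage_noise: float = 0.1
    threshold: float = 0.5
    vocab_size: int = 300
    external_vocab_size: int = 120
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.unsourced_prob,
            self.section_mix,
            self.multi_label_prob,
            self.symbolic_prob,
            self.probable_prob,
            self.coverage_noise,
        ]
        if self.middle_prob is not None:
            probs.append(self.middle_prob)
        if self.tier_unsourced_probs:
            probs.extend(self.tier_unsourced_probs.values())
        if self.section_unsourced_probs:
            probs.extend(self.section_unsourced_probs.values())
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise GenerationError(f"probability {p} outside [0, 1]")
        if len(self.attribution_mixture) != len(SourceDocLabel):
            raise GenerationError("attribution_mixture must cover all 14 source labels")
        total = sum(self.attribution_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"attribution_mixture sums to {total}, expected 1")
        if min(self.n_cases, self.records_per_case, self.segments_per_summary) < 1:
            raise GenerationError("counts must be positive")
        if not (0.0 < self.threshold <= 1.0):
            raise GenerationError("threshold must be in (0, 1]")
        if not self.hospital_profiles:
            raise GenerationError("at least one hospital profile required")


def table_preset(seed: int = 0, n_cases: int = 200) -> SynthConfig:
    """A preset whose planted rates echo a realistic multi-hospital audit:

    overall unsourced 0.387, tiers 0.376/0.439, sections 0.434/0.318, five
    hospitals spanning 0.231-0.596, and the default attribution mixture.
    """
    return SynthConfig(
        n_cases=n_cases,
        seed=seed,
        unsourced_prob=0.387,
        tier_unsourced_probs={"low": 0.376, "high": 0.439},
        section_unsourced_probs={"pre_hospital": 0.434, "in_hospital": 0.318},
        hospital_profiles=(
            HospitalProfile("HI", 0.596),
            HospitalProfile("HII", 0.289),
            HospitalProfile("HIII", 0.231),
            HospitalProfile("HIV", 0.461),
            HospitalProfile("HV", 0.360),
        ),
    )


# ---------------------------------------------------------------------------
# token helpers
# ---------------------------------------------------------------------------


def _letters(i: int) -> str:
    out = []
    i = int(i)
    while True:
        out.append(chr(ord("a") + i % 26))
        i //= 26
        if i == 0:
            break
    return "".join(reversed(out))


def _marker(role: ClinicalRole, j: int) -> str:
    return f"m{_ROLE_CODES[role]}{_letters(j)}"


def _probable_marker(j: int) -> str:
    return f"mprb{_letters(j)}"


class _TokenPools:
    def __init__(self, cfg: SynthConfig):
        self.internal = [f"w{_letters(i)}" for i in range(cfg.vocab_size)]
        self.external = {
            lab: [
                f"x{_letters(li)}{_letters(i)}"
                for i in range(cfg.external_vocab_size)
            ]
            for li, lab in enumerate(SourceDocLabel)
        }
        self._fresh = 0

    def fresh(self) -> str:
        tok = f"zz{_letters(self._fresh)}"
        self._fresh += 1
        return tok


# ---------------------------------------------------------------------------
# segment planning
# ---------------------------------------------------------------------------


def _role_probs(cfg: SynthConfig) -> tuple[list[ClinicalRole], np.ndarray]:
    roles = list(ClinicalRole)
    w = np.array([cfg.role_mix.get(r, 0.0) for r in roles], dtype=float)
    if w.sum() <= 0:
        raise GenerationError("role_mix has no mass")
    w = w / w.sum()
    if cfg.middle_prob is not None:
        mid = np.array([ROLE_TIER[r] is Subjectivity.MIDDLE for r in roles])
        mid_mass = w[mid].sum()
        oth_mass = w[~mid].sum()
        if cfg.middle_prob > 0 and mid_mass == 0:
            raise GenerationError("middle_prob > 0 but middle roles have no mass")
        if cfg.middle_prob < 1 and oth_mass == 0:
            raise GenerationError("middle_prob < 1 but non-middle roles have no mass")
        w = w.copy()
        if mid_mass > 0:
            w[mid] *= cfg.middle_prob / mid_mass
        if oth_mass > 0:
            w[~mid] *= (1.0 - cfg.middle_prob) / oth_mass
    return roles, w


def _unsourced_prob(
    cfg: SynthConfig,
    tier: Subjectivity,
    section: Section,
    hospital: HospitalProfile,
) -> float:
    base = cfg.unsourced_prob
    p = base
    if cfg.tier_unsourced_probs is not None and tier.value in cfg.tier_unsourced_probs:
        p = cfg.tier_unsourced_probs[tier.value]
    if cfg.section_unsourced_probs is not None and base > 0:
        sp = cfg.section_unsourced_probs.get(section.value)
        if sp is not None:
            p = p * sp / base
    if hospital.unsourced_prob is not None and base > 0:
        p = p * hospital.unsourced_prob / base
    return float(np.clip(p, 0.0, 1.0))


def _sample_sources(
    cfg: SynthConfig, rng: np.random.Generator
) -> frozenset[SourceDocLabel]:
    labels = list(SourceDocLabel)
    w = np.array([cfg.attribution_mixture[l] for l in labels], dtype=float)
    w = w / w.sum()
    first = labels[rng.choice(len(labels), p=w)]
    picked = {first}
    if rng.random() < cfg.multi_label_prob:
        for _ in range(20):
            second = labels[rng.choice(len(labels), p=w)]
            if second not in picked:
                picked.add(second)
                break
    return frozenset(picked)


def _template_tokens(
    role: ClinicalRole,
    probable: bool,
    content_pool: Sequence[str],
    rng: np.random.Generator,
    n_content: int = 3,
) -> list[str]:
    """Marker/content interleaving; markers are never mutually adjacent."""
    toks: list[str] = []
    for _ in range(n_content):
        toks.append(_marker(role, int(rng.integers(_MARKERS_PER_ROLE))))
        toks.append(content_pool[int(rng.integers(len(content_pool)))])
    if probable:
        for _ in range(2):
            toks.append(_probable_marker(int(rng.integers(2))))
            toks.append(content_pool[int(rng.integers(len(content_pool)))])
    return toks


def _symbolic_text(rng: np.random.Generator, pools: _TokenPools) -> str:
    if rng.random() < 0.5:
        y = 2015 + int(rng.integers(10))
        m = 1 + int(rng.integers(12))
        d = 1 + int(rng.integers(28))
        return f"{y}/{m:02d}/{d:02d}"
    word = pools.internal[int(rng.integers(len(pools.internal)))]
    return f"【{word}】"


@dataclass
class _Plan:
    """One planned summary segment before text materialization."""

    symbolic: bool
    role: ClinicalRole = ClinicalRole.OTHERS
    probable: bool = False
    section: Section = Section.UNKNOWN
    origin: Optional[Origin] = None
    sources: Optional[frozenset[SourceDocLabel]] = None
    tokens: list[str] = field(default_factory=list)
    text: str = ""
    record_index: int = 0  # record hosting the source sentence (sourced only)


def _plan_segments(
    cfg: SynthConfig,
    rng: np.random.Generator,
    pools: _TokenPools,
    hospital: HospitalProfile,
) -> list[_Plan]:
    roles, role_w = _role_probs(cfg)
    plans: list[_Plan] = []
    for _ in range(cfg.segments_per_summary):
        if rng.random() < cfg.symbolic_prob:
            plan = _Plan(symbolic=True, section=Section.UNKNOWN)
            plan.text = _symbolic_text(rng, pools)
            plans.append(plan)
            continue
        role = roles[rng.choice(len(roles), p=role_w)]
        probable = rng.random() < cfg.probable_prob
        section = (
            Section.PRE_HOSPITAL
            if rng.random() < cfg.section_mix
            else Section.IN_HOSPITAL
        )
        tier = Subjectivity.HIGH if probable else ROLE_TIER[role]
        p_uns = _unsourced_prob(cfg, tier, section, hospital)
        unsourced = rng.random() < p_uns
        plan = _Plan(
            symbolic=False,
            role=role,
            probable=probable,
            section=section,
            origin=Origin.UNSOURCED if unsourced else Origin.SOURCED,
        )
        if unsourced:
            plan.sources = _sample_sources(cfg, rng)
            primary = sorted(plan.sources, key=lambda s: s.value)[0]
            plan.tokens = _template_tokens(
                role, probable, pools.external[primary], rng
            )
            plan.text = " ".join(plan.tokens)
        else:
            plan.tokens = _template_tokens(role, probable, pools.internal, rng)
            plan.record_index = int(rng.integers(cfg.records_per_case))
        plans.append(plan)
    return plans


def _distractor_sentence(
    cfg: SynthConfig, rng: np.random.Generator, pools: _TokenPools
) -> str:
    roles, role_w = _role_probs(cfg)
    role = roles[rng.choice(len(roles), p=role_w)]
    return " ".join(_template_tokens(role, False, pools.internal, rng))


def _perturb_sourced(
    plan: _Plan,
    bigrams: BigramSet,
    cfg: SynthConfig,
    rng: np.random.Generator,
    pools: _TokenPools,
    tokenizer,
) -> str:
    """Copy of the planted record sentence with bounded token noise.

    Replacement tokens are fresh (never reused), so each replacement only
    removes bi-grams; replacements are reverted greedily until the realized
    coverage is back at or above the threshold, which is always feasible
    because the unperturbed copy has coverage 1.
    """
    toks = list(plan.tokens)
    replaced: list[int] = []
    for i in range(len(toks)):
        if rng.random() < cfg.coverage_noise:
            toks[i] = pools.fresh()
            replaced.append(i)

    def realized(ts: list[str]) -> float:
        pairs = list(zip(ts, ts[1:]))
        return sum(1 for p in pairs if p in bigrams.bigrams) / len(pairs)

    while replaced and realized(toks) < cfg.threshold:
        i = replaced.pop()
        toks[i] = plan.tokens[i]
    if realized(toks) < cfg.threshold:
        raise GenerationError(
            "sourced segment cannot reach the coverage threshold; "
            "check records/threshold configuration"
        )
    return " ".join(toks)


def _hospital_for(
    cfg: SynthConfig, rng: np.random.Generator
) -> HospitalProfile:
    w = np.array([h.weight for h in cfg.hospital_profiles], dtype=float)
    if w.sum() <= 0:
        raise GenerationError("hospital weights have no mass")
    return cfg.hospital_profiles[rng.choice(len(cfg.hospital_profiles), p=w / w.sum())]


def _assemble_case(
    case_id: str,
    hospital: HospitalProfile,
    plans: list[_Plan],
    record_sentences: list[list[str]],
    cfg: SynthConfig,
    rng: np.random.Generator,
    pools: _TokenPools,
) -> Case:
    tokenizer = default_tokenizer()
    records = [Document(text="\n".join(sents), date=f"2020-01-{di+1:02d}") for di, sents in enumerate(record_sentences)]
    case = Case(
        case_id=case_id,
        hospital_id=hospital.hospital_id,
        inpatient_records=records,
        discharge_summary=Document(text="", date="2020-02-01"),
    )
    bigrams = build_bigram_set(case, tokenizer)
    # materialize sourced texts now that the records (and bi-grams) are fixed
    for plan in plans:
        if not plan.symbolic and plan.origin is Origin.SOURCED:
            plan.text = _perturb_sourced(plan, bigrams, cfg, rng, pools, tokenizer)
    summary_text = "\n".join(p.text for p in plans)
    case.discharge_summary = Document(text=summary_text, date="2020-02-01")
    pos = 0
    for si, plan in enumerate(plans):
        start = pos
        end = pos + len(plan.text)
        pos = end + 1  # newline
        labels = (
            LabelSet(Subjectivity.LOW, ClinicalRole.OTHERS, False)
            if plan.symbolic
            else LabelSet(
                Subjectivity.HIGH if plan.probable else ROLE_TIER[plan.role],
                plan.role,
                plan.probable,
            )
        )
        case.segments.append(
            Segment(
                segment_id=f"{case_id}-s{si:03d}",
                case_id=case_id,
                doc_kind=DocKind.DISCHARGE_SUMMARY,
                text=plan.text,
                char_span=(start, end),
                section=plan.section,
                is_symbolic=plan.symbolic,
                gold_labels=labels,
                gold_origin=None if plan.symbolic else plan.origin,
                gold_sources=plan.sources,
            )
        )
    case.validate()
    return case


def generate_corpus(cfg: SynthConfig) -> list[Case]:
    """Generate a fully gold-labeled corpus with planted provenance."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pools = _TokenPools(cfg)
    cases: list[Case] = []
    for ci in range(cfg.n_cases):
        case_id = f"case{ci:05d}"
        hospital = _hospital_for(cfg, rng)
        plans = _plan_segments(cfg, rng, pools, hospital)
        record_sentences: list[list[str]] = [
            [
                _distractor_sentence(cfg, rng, pools)
                for _ in range(cfg.distractor_sentences_per_record)
            ]
            for _ in range(cfg.records_per_case)
        ]
        for plan in plans:
            if not plan.symbolic and plan.origin is Origin.SOURCED:
                record_sentences[plan.record_index].append(" ".join(plan.tokens))
        cases.append(
            _assemble_case(case_id, hospital, plans, record_sentences, cfg, rng, pools)
        )
    return cases


def generate_gradient_corpus(
    cfg: SynthConfig, bin_curve: Sequence[float], n_bins: int = 5
) -> list[Case]:
    """Corpus whose non-symbolic segments sit below threshold in known bins.

    Each segment is assigned a coverage bin uniformly at random; its text is
    a record-sentence prefix (giving an exact planted coverage at the bin
    midpoint) completed with external tokens (gold unsourced, probability
    ``bin_curve[bin]``) or with fresh never-matching tokens (gold sourced —
    information from the records, rewritten).
    """
    cfg.validate()
    if len(bin_curve) != n_bins:
        raise GenerationError(f"bin_curve must have {n_bins} entries")
    for p in bin_curve:
        if not (0.0 <= p <= 1.0):
            raise GenerationError("bin_curve entries must be in [0, 1]")
    # sentence length chosen so every bin midpoint is exactly representable
    T = 4 * n_bins + 1  # bigram count 4*n_bins
    rng = np.random.default_rng(cfg.seed)
    pools = _TokenPools(cfg)
    roles, role_w = _role_probs(cfg)
    cases: list[Case] = []
    for ci in range(cfg.n_cases):
        case_id = f"case{ci:05d}"
        hospital = _hospital_for(cfg, rng)
        plans: list[_Plan] = []
        record_sentences: list[list[str]] = [
            [
                _distractor_sentence(cfg, rng, pools)
                for _ in range(cfg.distractor_sentences_per_record)
            ]
            for _ in range(cfg.records_per_case)
        ]
        for _ in range(cfg.segments_per_summary):
            if rng.random() < cfg.symbolic_prob:
                plan = _Plan(symbolic=True)
                plan.text = _symbolic_text(rng, pools)
                plans.append(plan)
                continue
            role = roles[rng.choice(len(roles), p=role_w)]
            probable = rng.random() < cfg.probable_prob
            section = (
                Section.PRE_HOSPITAL
                if rng.random() < cfg.section_mix
                else Section.IN_HOSPITAL
            )
            k = int(rng.integers(n_bins))
            unsourced = rng.random() < bin_curve[k]
            base = _template_tokens(role, probable, pools.internal, rng)
            while len(base) < T:
                base.append(pools.internal[int(rng.integers(len(pools.internal)))])
            base = base[:T]
            record_sentences[int(rng.integers(cfg.records_per_case))].append(
                " ".join(base)
            )
            keep = 2 * k + 2  # matched bigrams keep-1 => coverage (2k+1)/(4*n_bins)
            plan = _Plan(
                symbolic=False,
                role=role,
                probable=probable,
                section=section,
                origin=Origin.UNSOURCED if unsourced else Origin.SOURCED,
            )
            if unsourced:
                plan.sources = _sample_sources(cfg, rng)
                primary = sorted(plan.sources, key=lambda s: s.value)[0]
                pool = pools.external[primary]
                suffix = [pool[int(rng.integers(len(pool)))] for _ in range(T - keep)]
            else:
                suffix = [pools.fresh() for _ in range(T - keep)]
            plan.text = " ".join(base[:keep] + suffix)
            plan.tokens = base[:keep] + suffix
            plans.append(plan)
        records = [
            Document(text="\n".join(sents), date=f"2020-01-{di+1:02d}")
            for di, sents in enumerate(record_sentences)
        ]
        case = Case(
            case_id=case_id,
            hospital_id=hospital.hospital_id,
            inpatient_records=records,
            discharge_summary=Document(text="\n".join(p.text for p in plans)),
        )
        pos = 0
        for si, plan in enumerate(plans):
            start, end = pos, pos + len(plan.text)
            pos = end + 1
            labels = (
                LabelSet(Subjectivity.LOW, ClinicalRole.OTHERS, False)
                if plan.symbolic
                else LabelSet(
                    Subjectivity.HIGH if plan.probable else ROLE_TIER[plan.role],
                    plan.role,
                    plan.probable,
                )
            )
            case.segments.append(
                Segment(
                    segment_id=f"{case_id}-s{si:03d}",
                    case_id=case_id,
                    doc_kind=DocKind.DISCHARGE_SUMMARY,
                    text=plan.text,
                    char_span=(start, end),
                    section=plan.section,
                    is_symbolic=plan.symbolic,
                    gold_labels=labels,
                    gold_origin=None if plan.symbolic else plan.origin,
                    gold_sources=plan.sources,
                )
            )
        case.validate()
        cases.append(case)
    return cases
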