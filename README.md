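# summaudit

Can a hospital discharge summary be reconstructed from the inpatient
records of the same admission?  `summaudit` is a tested, reusable pipeline
for auditing exactly that question on paired corpora of free-text inpatient
records and discharge summaries:

* **segmentation** — sentences are split at end marks/line breaks, then
  partitioned into fine *clinical segments* by a pluggable segmenter
  (rule-based default); symbolic segments (dates, bracket headers, pure
  punctuation) are flagged and excluded from all rates.
* **provenance** — a word bi-gram set is built from each case's inpatient
  records; every summary segment is scored by the fraction of its bi-gram
  occurrences found in that set and classified sourced (coverage ≥ 0.5),
  unsourced, or excluded.  Below-threshold segments carry a 5-bin coverage
  index and are finalized against gold (in the original study: manual)
  origin labels — the two-step design.
* **classifier** — a multitask model labels each segment with subjectivity
  (low/middle/high), one of nine clinical roles, and a binary *probable*
  flag (which promotes effective subjectivity to high).  The objective is
  the weighted sum `L_all = λ_sub·L_sub + λ_role·L_role + λ_prob·L_prob`
  with λ summing to 1; a 16-point quarter-step grid search over λ is
  provided.  The default encoder is a deterministic hashed bag-of-tokens
  projection with a trainable tanh tail (pure NumPy, no downloads); any
  encoder satisfying the contract (e.g. a pretrained transformer) can be
  plugged in.
* **reporting** — per-class/macro P/R/F1, unsourced rates stratified by
  label tier and role, by pre-/in-hospital section, and by hospital; the
  multi-label attribution of unsourced segments over 14 external-source
  document types; and an overall share-of-information breakdown.
* **synthetic data** — a seeded generator that plants recoverable ground
  truth (provenance, labels, sections, hospitals, attribution mixtures, a
  coverage-bin gradient), so every stage is testable offline.

## CLI

```sh
summaudit generate --seed 7 --n-cases 100 --out corpus.jsonl
summaudit segment --corpus raw.jsonl --out segmented.jsonl
summaudit provenance --corpus corpus.jsonl --threshold 0.5 --bins 5 --out prov.jsonl
summaudit train --corpus corpus.jsonl --weights 0.5,0.25,0.25 --seed 7 --out model.json
summaudit gridsearch --corpus corpus.jsonl --out grid.csv
summaudit report --corpus corpus.jsonl --provenance prov.jsonl --out reports/
summaudit run-all --seed 7 --out runs/demo
```

`run-all` writes `corpus.jsonl`, `provenance.jsonl`, `model.json`, the five
report CSVs (`t5_labels.csv`, `t6_sections.csv`, `t7_attribution.csv`,
`t8_hospitals.csv`, `fig6_breakdown.csv`), `report.json`, and an echo of the
effective configuration.  Reruns with the same seed reproduce identical
bytes.  Configuration files (YAML or JSON) accept the full `RunConfig`
schema; see `summaudit.cli.RunConfig`.

## Corpus format

JSON Lines, one case per line: `case_id`, `hospital_id`,
`inpatient_records` (list of `{date, text}`), `discharge_summary`, and
`segments` with 0-based half-open `char_span` offsets, section tags,
symbolic flags, and optional gold labels (`gold_labels`, `gold_origin`,
`gold_sources`).  Serialization is canonical (fixed key order, UTF-8), so
read→write is the identity and equal inputs give byte-identical files.

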