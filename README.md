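# promscan

Detection and analysis of patient-reported outcome and experience measures
(PROMs/PREMs) in clinical-trial registry outcome texts.

The package implements two complementary detectors over the "what is the
study measuring?" sections of registry study records, together with the
workflow around them:

- **registry_model** — parse registry-dialect JSON study records, apply
  eligibility filters (date window, outcome presence/description), and
  explode studies into individually analyzable outcome descriptions.
- **lexicon_matcher** — the expert rule: word-boundary search for instrument
  full names, acronyms (with a case guard on short acronyms) and a fixed
  list of 11 generic PROM/PREM terms.
- **annotation** — the gold-standard workflow: stratified subset sampling,
  seeded annotator-pair assignment, Cohen's kappa, and consensus
  adjudication of disagreements.
- **outcome_classifier** — the trainable detector: balanced classes,
  61/12/27 stratified split (explicit counts also accepted), a
  hyperparameter grid with accuracy-based selection, 512-token head-first
  truncation. The default backend is a desk-scale term-frequency linear
  model; a transformer backend can be plugged in behind the same
  text-in/probability-out contract.
- **evaluation** — confusion matrix, accuracy/sensitivity/specificity/
  PPV/NPV with Wald or Wilson 95% CIs, percent rounding half away from
  zero, and the between-algorithm chi-square on correctness counts. The
  published benchmark confusion cells ship as built-in fixtures.
- **instrument_ner** — which instrument is named: BIO span tagging, a
  rule-assisted mention extractor with short-gap merging of fragmented
  multiword names, character-trigram cosine normalization to the canonical
  lexicon (default threshold 0.85), and study-level frequency tables.
- **site_recoder** — free-text cancer-condition recoding: seeded k-means
  with top-10-word cluster naming, plus a prototype (few-shot style)
  cosine classifier.
- **study_analytics** — study-level aggregation, yearly trend score test,
  bivariate chi-squares, stratified multivariate logistic regression with
  Wald CIs on the OR scale, and a regression-based MCAR check.
- **synthetic_corpus** — seeded synthetic registry corpora with exact
  ground truth (planted instrument mentions, configurable corruption
  variants, trap phrases, covariate-driven uptake model), so everything is
  testable without any download.

A packaged fixture lexicon of ~40 oncology instruments stands in for the
proprietary 346-entry source lexicon.

## CLI

All functionality is exposed through the `promscan` command:

```bash
promscan simulate --seed 1 --out corpus/           # synthetic corpus + truth
promscan ingest --records corpus/records.jsonl \
    --start 2012-01-01 --end 2022-01-01 --out outcomes.tsv
promscan match --outcomes outcomes.tsv --out matches.tsv
promscan sample --matches matches.tsv --seed 1 --out subset.tsv
promscan kappa --labels-a a.tsv --labels-b b.tsv
promscan adjudicate --labels-a a.tsv --labels-b b.tsv --out gold.tsv
promscan train --labels gold.tsv --out model/
promscan predict --model model/ --outcomes outcomes.tsv --out predictions.tsv
promscan evaluate --pred predictions.tsv --gold gold.tsv --ci wald
promscan extract --outcomes outcomes.tsv --threshold 0.85 --out mentions.jsonl
promscan recode --conditions conditions.tsv --prototypes sites.tsv --out recoded.tsv
promscan analyze --table studies.tsv --stratum interventional \
    --predictors phase,allocation,primary_purpose
```

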