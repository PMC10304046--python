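# Methods

## Problem and pipeline

The unit of analysis is a *keyword occurrence*: one token of a clinical
note that case-folds to one of 83 lexicon surface forms covering 44
supplement categories. The pipeline decides for each occurrence whether it
indicates active supplement use, then aggregates: a patient is a user of a
category if at least one in-window occurrence is classified positive, and
patient-level calls are scored against survey self-report.

Matching is deliberately permissive — whole-token, case-insensitive
equality, never substring — so that lab values ("Calcium is 8.1"), allergy
lines, food mentions and compound drug names ("ATORVASTATIN CALCIUM") all
*match* and are then adjudicated by the learned classifier. Hand-coded
negation or section rules are intentionally absent; the design premise is
that the surrounding bigrams carry that signal.

## Tokenizer

Notes are split on whitespace runs; every punctuation character becomes a
token of its own, with three intra-word exceptions: `/` and `-` between
alphanumerics (`CAP/TAB`, `QID-INSULIN`) and `.` between digits (`0.97`).
Asterisks always separate (`qday*Glargine` → `qday * Glargine`), which
recovers the items of asterisk-delimited medication runs. Original casing
is preserved on the token; matching and featurization case-fold on demand.
The output round-trips: joining tokens with single spaces and re-tokenizing
is the identity. There is no sentence splitting — these notes are too
non-grammatical for it to be reliable — and "word" for the ±20 context
window means token under this scheme.

A consequence of keeping intra-word slashes: a keyword embedded in a
slash-compound (`ACIDOPHILUS/SPOROGENES`) is one token and does not match.
We accept this as the cost of preserving tokens like `CAP/TAB` and
`579.0/57`; the lexicon's surface forms are bare words, and the synthetic
templates write compounds without slashes.

## Features and classifier

The feature space is built from training observations only: all unique
ordered adjacent case-folded token pairs (binary presence, lexicographic
column order), plus one categorical keyword feature one-hot encoded with an
explicit unknown level. Presence rather than counts: snippets are at most
41 tokens, so a bigram rarely repeats, and presence is the natural reading
of "unique bigrams as features". Bigrams unseen at training are ignored at
inference.

The classifier is a linear soft-margin SVM (hinge loss + L2, C = 1.0
default) fitted with the SMO-style dual solver; for a linear kernel the fit
is deterministic, and the recorded seed governs only fold shuffling. No
feature selection, probability calibration, class weighting or
hyperparameter tuning is performed — the bigram space is high-dimensional
and near-linearly separable, and an untuned margin classifier is the
baseline of record. Cross-validation is stratified k-fold (default k = 10)
with vectorizer and SVM refitted per fold, so no test-fold token ever
contributes a feature column or weight. Metrics are per-class
precision/recall/F1 plus a support-weighted average; zero-denominator
ratios are NaN, never silently 0. Models serialize to versioned JSON
(feature space plus the dense weight vector); floats survive the
round-trip bit-exactly.

## Roll-up and agreement conventions

The survey-anchored window is [survey − 365 days, survey + 30 days], both
bounds inclusive; day counts, not calendar arithmetic, and both are
configurable. An observation's category comes from the lexicon with
one-token lookahead for generic vitamin stems.

Agreement treats the survey as the reference standard. This matters for
interpretation: self-report is itself imperfect (see the discordance
mechanism below), so survey-referenced precision conflates NLP false
positives with survey under-reporting. Micro averages pool confusion
counts across categories; macro averages are unweighted arithmetic means
of per-category metrics — in particular macro F1 is the mean of
per-category F1 values, *not* the harmonic mean of macro precision and
recall (the two differ; the packaged reference table is consistent only
with mean-of-F1). The prevalence filter keeps categories reported by
strictly more than 10% of participants (threshold configurable); undefined
per-category metrics are excluded from macro means with a warning.
Chance-corrected agreement (kappa) is deliberately not computed.

## Synthetic data: what it emulates, and what it does not

The generator assembles each note from template sections of seven
families: positive — numbered active-medication lists (`(14) MELATONIN 5MG
TAB ACTIVE Give: …`), asterisk-delimited med runs, narrative current use —
and negative — all-caps allergy lines, chemistry panels whose analyte
names collide with supplement keywords (calcium, creatinine, potassium,
Fe), food/diet mentions (baked fish, ginger ale, weak tea), and compound
drug or diagnosis names (atorvastatin calcium, iron-deficiency anemia,
flex catheter tips). Every emitted keyword occurrence carries its family's
polarity as ground truth, and generation validates itself against the
matcher, so templates cannot leak unlabeled occurrences. Filler sentences
contain no keywords.

Defaults are the study conditions: 377 surveyed patients, all notes dated
inside the roll-up window, and a positive share of keyword occurrences of
0.58. Because polarity is drawn per section while families differ in
keyword yield, the section-level probability is rescaled by per-family
expected yields (estimated once with a fixed private RNG) so the
occurrence-level positive fraction matches the configured rate; the
measured share at defaults is 0.573. Four notes per patient keeps the
default corpus at roughly 4,500 observations — large enough for stable
per-category counts while the whole chain runs in seconds.

Survey discordance: `underreport_prescribed` flips true→false for
prescribed-style categories (folic acid, melatonin, multivitamin by
default) — modelling patients who do not count physician-prescribed items
as supplements — and `overreport` flips false→true anywhere. With an
oracle classifier, under-reporting surfaces as survey-referenced false
positives: precision and F1 degrade while corpus-truth recall stays 1.0.
That is the mechanism's signature, and the directional property the tests
assert.

What passing tests on this corpus do **not** show: real notes have longer
and more variable documents, templated boilerplate the generator does not
model, misspellings outside the fixed lexicon variants, real base-rate
structure across supplements (the generator samples categories uniformly
within a family), and genuinely ambiguous mentions with no clean ground
truth. Results here demonstrate that the machinery is correct and the
mechanisms behave directionally as expected — not that any particular F1
transfers to real clinical text.

## Fixtures and problem sizes

The "separable fixture" used for the classifier-competence check is
generated with exactly one template section per note. In the default
multi-section corpus the ±20-token window spans section boundaries, so a
negative lab mention can sit inside positive med-list context — realistic,
and deliberately *not* linearly separable (10-fold CV weighted F1 ≈ 0.93
at defaults). With one section per note every snippet's context comes from
a single family and the problem is exactly separable (verified by
linear-program feasibility in the tests; CV weighted F1 = 1.000 on 1,000
observations).

Test and acceptance runs use 25–377 patients, up to ~4,700 observations,
and 1,000-table random checks for the metric oracles; the full suite and
the acceptance script each complete in a few seconds on one CPU.

## Known limitations

- The keyword→category mapping ships as curated data; ambiguous surface
  forms (`flex`, `tea`, `yeast`, `retinal`) reflect our reading, and the
  file can be replaced via `--lexicon`.
- The vitamin-stem lookahead is one token; "vitamin B complex" resolves to
  multivitamin, and a stem at the end of a line can be refined by the next
  line's first token.
- No dosage, duration or start-date extraction; a single positive mention
  makes the patient a user of the category.
- The any-positive roll-up is maximally sensitive by construction; its
  precision depends entirely on the snippet classifier.
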