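# Methods

## Problem and design

`hcmnlp` extracts a hypertrophic cardiomyopathy (HCM) diagnosis and fourteen
phenotype concepts from narrative cardiac MR (CMR) reports. The design is a
classic two-tier rule-based system: tier 1 decides the report-level diagnosis
status; tier 2 — gated on a positive tier-1 call — extracts the categorical
and numeric phenotype concepts used for HCM classification. All linguistic
knowledge lives in editable data files (`src/hcmnlp/data/`): a concept
lexicon TSV, a section-header alias table, and an assertion-scope config.

## Report model

Reports are parsed into sections from a closed label set (HISTORY,
TECHNIQUE, FINDINGS, MEASUREMENTS, IMPRESSION, UNKNOWN). A header is an
alias that starts a line and ends with `:`, or appears fully uppercase
followed by `:`, or stands alone uppercase on a line; text before the first
header falls into an UNKNOWN section. Offsets are 0-based half-open spans
into the raw text; sections tile the text and every sentence span re-slices
to its exact source string, so downstream matches are fully traceable.

Sentence segmentation splits on `.?!` followed by whitespace and a capital
or digit, or a line break, with guards for decimal numbers ("1.5 cm"), a
small abbreviation list ("Dr.", "vs."), and numbered-list markers ("1. ..."),
which begin sentences rather than end them. Measurement decimals must never
split sentences, since the numeric extractor searches within one sentence.

## Matching and assertion

Concept targets are literal phrases (case-insensitive, word-boundary
anchored, flexible internal whitespace) or regexes. Overlapping hits of the
same concept resolve leftmost-longest; distinct concepts may overlap (one
sentence can assert both LV obstruction and its location). Short acronyms
("SAM", "LGE") are boundary-anchored so they never fire inside longer words.

Assertion status follows NegEx-style scope rules: default ASSERTED; NEGATED
when a negation cue precedes the target within **6 tokens** or follows
within **4 tokens**, unless a pseudo-negation ("not ruled out", "no change
in") overlaps the cue or a termination token ("but", "however", ";")
intervenes; POSSIBLE when a hedge cue is in scope and no negation applies.
When both cue kinds are in scope, the cue closer to the target wins and ties
resolve to NEGATED. The window sizes are standard NegEx-type defaults and
are configurable (`assertion.yaml`). "No significant X" counts as negated; a
separate qualified-normal status is deliberately not modelled. Hypothetical,
family-history and historical dimensions of ConText, and cross-sentence
coreference, are out of scope.

The shipped hedge vocabulary ("possible", "probable", "suggestive of",
"cannot exclude", "borderline", ...) is a curated reconstruction — clinical
systems rarely publish their full cue lists — and is editable data.

## Report-level resolution

* Diagnosis: total order **YES > POSSIBLE > NO > NOT_MENTIONED** over the
  statuses of all diagnosis mentions. Any affirmation beats negation, since
  impressions typically assert the final read after negating alternatives.
* Binary concepts: **PRESENT** if any asserted-or-hedged mention, else
  **ABSENT_NEGATED** if any negated mention, else **NOT_MENTIONED**. A hedged
  mention counts as present, consistent with treating "possible HCM" as
  positive in evaluation.
* Subtype: the last-asserted label in document order wins on conflict (a
  warning is logged); obstruction location prefers LVOT when both LVOT and
  mid-ventricular phrasings are asserted.
* Tier-2 gating: POSSIBLE reports are phenotyped, matching the positive
  binarization; reports called NO or NOT_MENTIONED carry NOT_EVALUATED in
  every tier-2 field — explicitly encoded in outputs, never omitted.
* "Hypertrophic obstructive cardiomyopathy" both asserts the diagnosis and
  contributes an LV-obstruction target, by lexical containment.

## Numeric extraction

For each anchor-phrase match the extractor takes the first number within the
same sentence at most 80 characters past the anchor, covering the patterns
"anchor ... is 22 mm", "anchor = 426 g", "anchor: 61%", "anchor; 83%". The
unit token must convert to the concept's canonical unit (mm, g, g/m², %;
cm→×10, kg→×1000); a number with a foreign or missing unit is skipped with a
structured warning, which also cleanly rejects "LV mass" anchors matching
inside "LV mass index = 186 g/m2" sentences (anchor containment between
numeric concepts is additionally suppressed). Values outside plausibility
ranges — wall thickness 3–60 mm, LV mass 30–1000 g, mass index 10–400 g/m²,
EF 5–95% (editable config) — are logged and dropped. With several surviving
candidates, a value in MEASUREMENTS beats FINDINGS beats first occurrence,
because text recorded in the wrong section is a known error source; whether
multiple wall-thickness readings should instead be maximised is unknowable
from published descriptions, so section preference is the documented choice.

## Evaluation

Each concept is scored per report as a binary task: diagnosis binarizes
YES/POSSIBLE vs NO/NOT_MENTIONED; categoricals PRESENT vs rest; multiclass
concepts count a report positive when any label is emitted, and a true
positive requires the label to equal gold (a wrong label scores as a false
positive, keeping tp+fp+fn+tn = n; per-label contingency tables are provided
separately). Numeric concepts are positive when a value was extracted, with
a true positive requiring agreement within `numeric_tolerance` (default
exact, since gold values are transcribed numbers).

Metrics are accuracy, sensitivity, specificity, PPV, NPV and
F1 = 2·PPV·Se/(PPV+Se). Zero-denominator metrics are reported as an explicit
undefined marker. Confidence intervals are Clopper–Pearson exact (beta
quantiles), chosen because exact intervals behave correctly at the tiny
positive counts typical of rare findings such as apical pouch; the Wilson
score interval is available as an option. Display rounding is 2 decimals,
half-up.

## Synthetic corpus generator

The generator emits sectioned reports (HISTORY / TECHNIQUE / FINDINGS /
MEASUREMENTS / IMPRESSION) rendered from per-concept template pools with
asserted, negated and hedged variants, distractor sentences, and integer
measurements with units. Gold labels are sampled first and the text is
rendered from them, so gold is consistent with the text by construction.
Per-report randomness derives from `(seed, index)`, making corpora
reproducible under parallel generation.

Defaults are anchored to published test-set summaries of HCM-positive CMR
reports: concept prevalences (e.g. SAM 61/83, apical pouch 9/83), subtype
mix (sigmoid 34, reverse curve 14, apical 12, neutral 2 of 62),
numeric distributions (wall thickness 20.9 ± 4.5 mm, LV mass 198.2 ± 70.4 g,
mass index 97.4 ± 30.1 g/m², LVEF 71.4 ± 7.9%, RVEF 61.0 ± 7.5%; truncated
normals over the plausibility ranges) and per-concept reporting rates
(e.g. thickness reported in 77/83 positives). Two quantities are not
published and are package choices: the four-way diagnosis split
(YES 0.36 / POSSIBLE 0.04 / NO 0.35 / NOT_MENTIONED 0.25, preserving the
≈0.40 positive fraction of a mixed referral population) and the obstruction
location mix (LVOT 0.982 / mid-ventricular 0.018, pooled across the
published sets so the rarer label is exercised at all).

Two injectors emulate documented real-world error modes, each defaulting to
rate 0.05: **ambiguity** replaces a concept sentence with a paraphrase
deliberately excluded from the lexicon ("a cavity gradient is appreciated"),
creating honest false negatives; **wrong-section** plants an HCM mention in
the HISTORY of a diagnosis-negative report (a false-positive trap, since the
matcher does not discount history text) or relocates a measurement into
TECHNIQUE. Each injection is recorded in `injected_errors`.

What passing clean-corpus tests shows — and does not show. With both rates
at 0 the pipeline reproduces gold with accuracy 1.0 on all 15 concepts; this
verifies the internal consistency of rules, resolution and gating end to
end, not performance on real prose. Real reports contain phrasing diversity,
typos, complex sentences and institution-specific conventions the template
pools do not model; accuracy on real data is expected to be lower and must
be measured against manually annotated gold standards.

## Problem sizes and numerical choices

The default test suite uses corpora of 40–2000 synthetic reports (200 for
the round-trip fidelity check, 2000 for the law-of-large-numbers marginals,
20 seeds × 40 reports for degradation monotonicity), sizes at which the
binomial checks have comfortable power while the whole suite runs in well
under a minute. Statistical checks use 3-SD bands or central 99% binomial
intervals so seeded runs are stable. Metric identities are asserted to
1e-12; interval computations use scipy's beta quantiles directly.

## Known limitations

* The lexicon is a curated reconstruction, not a replication of any
  production rule set built on UMLS lexical variants; recall on real text
  depends on local extension of the TSV.
* Negation scope is intra-sentential and window-based; long coordinated
  sentences can defeat it.
* One value per numeric concept per report; longitudinal reconciliation
  across a patient's reports is out of scope, as are ICD-code cohort
  construction, de-identification, and HL7/FHIR ingestion.
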