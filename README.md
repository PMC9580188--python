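# hcmnlp

Rule-based extraction of hypertrophic cardiomyopathy (HCM) findings from
cardiac magnetic resonance (CMR) report text.

CMR is central to diagnosing HCM and stratifying sudden-cardiac-death risk,
but its findings live in narrative radiology prose. Collecting them across
hundreds of reports by manual chart review is slow and error-prone. `hcmnlp`
is a two-tier rule-based clinical NLP system for that task, aimed at EHR
phenotyping and cohort-building work:

* **Tier 1** classifies each report's HCM diagnosis status as
  `YES / POSSIBLE / NO / NOT_MENTIONED` from dictionary and regex matches with
  NegEx-style assertion handling (negation cues, hedge cues, pseudo-negations,
  termination tokens, bounded token scope).
* **Tier 2**, run only on diagnosis-positive reports, extracts nine
  categorical concepts — morphologic subtype (sigmoid / reverse curve /
  neutral / apical), systolic anterior motion of the mitral valve, mitral
  regurgitation, LV obstruction and its location (LVOT / mid-ventricular),
  apical pouch, LV delayed enhancement, left and right atrial enlargement —
  and five numeric ones: maximal LV wall thickness (mm), LV mass (g), LV mass
  index (g/m²), LV and RV ejection fraction (%), with unit normalisation
  (cm→mm, kg→g) and plausibility-range guards.

Because real CMR reports are protected health data, the package ships a
seeded synthetic-report generator that emits sectioned radiology prose with
known gold labels, plus an evaluation harness computing sensitivity,
specificity, PPV, NPV, accuracy and F1 (`F1 = 2·PPV·Se/(PPV+Se)`) with
Clopper–Pearson exact 95% confidence intervals. Every rule is editable data
(a lexicon TSV, YAML configs), not code.

## Worked example

```python
from hcmnlp import load_lexicon, parse_report, run_pipeline

report = """\
FINDINGS: Systolic anterior motion of the mitral valve is present.
There is turbulent flow in the left ventricular outflow tract.
MEASUREMENTS: The maximal thickness of the myocardium measured in diastole is 22 mm.
IMPRESSION: Findings consistent with hypertrophic cardiomyopathy.
"""
result = run_pipeline(parse_report("r1", report), load_lexicon())
print(result.diagnosis, result.obstruction_location,
      result.categoricals["SAM"], result.numerics["MAX_LV_WALL_THICKNESS"])
```

prints

```
YES LVOT PRESENT 22.0
```

— the impression asserts HCM (tier 1 → `YES`), so tier 2 ran: SAM is
`PRESENT`, the obstruction localises to the LV outflow tract, and the wall
thickness is returned as 22.0 in its canonical unit (mm). On a
diagnosis-negative report every tier-2 field is the explicit marker
`NOT_EVALUATED`.

The `examples/` directory holds short narrative scripts: single-report
annotation, generate-annotate-score round trips, and metric/CI computation.
A thin CLI wraps the same library:

```bash
hcmnlp generate --n 100 --seed 7 --out-dir corpus/
hcmnlp annotate --corpus corpus/corpus.jsonl --out results.json
hcmnlp evaluate --pred results.json --gold corpus/gold.csv --out-prefix metrics
hcmnlp summarize --pred results.json
```

## Documentation

`docs/methods.md` describes the extraction rules, assertion scope model,
generator design and its known limitations.
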