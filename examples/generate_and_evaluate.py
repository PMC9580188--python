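"""Generate a synthetic gold-labelled corpus, annotate it, and score it.

With both error injectors at zero the extractor reproduces the generator's
gold labels exactly (every accuracy 1.0).  Raising ``ambiguity_rate`` swaps
some sentences for paraphrases outside the lexicon and the scores degrade —
the same failure mode ambiguous phrasing causes on real reports.
"""

from hcmnlp import (
    GeneratorProfile,
    evaluate_all,
    generate_corpus,
    load_lexicon,
    render_metrics_text,
    run_pipeline,
)

lexicon = load_lexicon()

for rate in (0.0, 0.3):
    profile = GeneratorProfile(n_reports=100, seed=11,
                               ambiguity_rate=rate, misplaced_section_rate=0.0)
    records = generate_corpus(profile)
    predictions = [run_pipeline(r.document, lexicon) for r in records]
    table = evaluate_all(predictions, [r.gold for r in records])
    print(f"\n=== ambiguity_rate={rate} ===")
    print(render_metrics_text(table))

# Each row is one phenotype concept; cells show the point estimate with its
# 95% exact binomial confidence interval.  At rate 0.0 every metric is 1.00;
# at 0.3 sensitivity drops first because paraphrases create false negatives.
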