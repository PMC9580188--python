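"""Performance metrics with exact binomial confidence intervals.

Builds a confusion-count object directly and prints the six metrics.  The
intervals are Clopper–Pearson exact, which is conservative at small n — note
how wide the PPV interval is with only 9 predicted positives.
"""

from hcmnlp import ConfusionCounts, compute_metrics, proportion_ci

counts = ConfusionCounts(tp=7, fp=2, fn=0, tn=91)
ms = compute_metrics(counts)

for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1"):
    value = getattr(ms, name)
    ci = ms.cis.get(name)
    if ci is None:
        print(f"{name:12s} {value:.3f}")
    else:
        print(f"{name:12s} {value:.3f}  (95% CI {ci[0]:.3f}, {ci[1]:.3f})")

# A rare finding (7 true positives) keeps sensitivity at 1.0 but its interval
# is wide; compare the exact and Wilson intervals for the same proportion:
print("exact :", proportion_ci(7, 7))
print("wilson:", proportion_ci(7, 7, method="wilson"))
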