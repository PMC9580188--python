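"""Corpus-level summaries over HCM-positive reports.

Mirrors the usual presentation of extracted phenotypes: counts of
Present / Absent-Negated per categorical concept, and n, mean ± SD per
numeric concept, restricted to reports the pipeline called diagnosis-positive
(YES or POSSIBLE).  SD is the sample (n−1) standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import binarize_diagnosis
from .extraction import ABSENT_NEGATED, NOT_EVALUATED, PRESENT, ReportResult
from .lexicon import CATEGORICAL_CONCEPTS, MULTICLASS_CONCEPTS, NUMERIC_CONCEPTS


def summarize_results(results: list[ReportResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (categorical_counts, numeric_summary) DataFrames.

    Categorical rows include the two multiclass concepts, counted as
    mentioned-with-a-label vs not.  Empty result lists yield empty tables
    with headers intact.
    """
    positive = [r for r in results if binarize_diagnosis(r.diagnosis)]

    cat_rows = []
    for cid in MULTICLASS_CONCEPTS:
        vals = [getattr(r, "subtype" if cid == "HCM_SUBTYPE" else "obstruction_location")
                for r in positive]
        n_present = sum(v not in ("NOT_MENTIONED", NOT_EVALUATED) for v in vals)
        cat_rows.append({"concept": cid, "present": n_present,
                         "absent_negated": 0, "not_mentioned": len(vals) - n_present})
    for cid in CATEGORICAL_CONCEPTS:
        vals = [r.categoricals.get(cid) for r in positive]
        cat_rows.append({
            "concept": cid,
            "present": sum(v == PRESENT for v in vals),
            "absent_negated": sum(v == ABSENT_NEGATED for v in vals),
            "not_mentioned": sum(v not in (PRESENT, ABSENT_NEGATED) for v in vals),
        })
    cat = pd.DataFrame(cat_rows, columns=["concept", "present", "absent_negated", "not_mentioned"])
    cat = cat.set_index("concept")

    num_rows = []
    for cid in NUMERIC_CONCEPTS:
        vals = [
            float(r.numerics[cid]) for r in positive
            if isinstance(r.numerics.get(cid), (int, float))
        ]
        num_rows.append({
            "concept": cid,
            "n": len(vals),
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        })
    num = pd.DataFrame(num_rows, columns=["concept", "n", "mean", "sd"]).set_index("concept")
    return cat, num
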