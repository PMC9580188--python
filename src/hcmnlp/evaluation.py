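"""Evaluation against gold annotations: confusion counts, the six standard
performance metrics, and exact binomial confidence intervals.

Each of the 15 phenotype concepts is scored as a binary task per report:

* diagnosis — YES/POSSIBLE count as positive, NO/NOT_MENTIONED as negative;
* binary categorical concepts — PRESENT vs everything else;
* multiclass concepts (subtype, location) — a report is predicted positive
  when any label is emitted; a true positive additionally requires the label
  to match gold, so a wrong label on a gold-positive report scores as a false
  positive (keeping tp+fp+fn+tn = n);
* numeric concepts — positive when a value was extracted; a true positive
  requires agreement with the gold value within ``numeric_tolerance``
  (default exact).

Metrics: accuracy = (TP+TN)/(TP+TN+FP+FN); PPV = TP/(TP+FP);
sensitivity = TP/(TP+FN); NPV = TN/(TN+FN); specificity = TN/(TN+FP);
F1 = 2·PPV·sensitivity/(PPV+sensitivity).  Zero denominators yield an
explicit ``None`` (undefined), never a silent 0.  Confidence intervals are
Clopper–Pearson exact by default, Wilson score on request.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy import stats

from .assertion import POSSIBLE
from .extraction import (
    ABSENT_NEGATED,
    NOT_EVALUATED,
    NOT_MENTIONED,
    PRESENT,
    ReportResult,
    YES,
)
from .lexicon import (
    CATEGORICAL_CONCEPTS,
    CONCEPT_ORDER,
    CONCEPTS,
    DIAGNOSIS_CONCEPT,
    MULTICLASS_CONCEPTS,
    NUMERIC_CONCEPTS,
)

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "f1", "npv", "accuracy")


class EvaluationError(ValueError):
    pass


@dataclass
class GoldAnnotation:
    """Manually-assigned (or generator-emitted) labels, same shape as
    :class:`~hcmnlp.extraction.ReportResult`."""

    report_id: str
    diagnosis: str
    subtype: str = NOT_MENTIONED
    obstruction_location: str = NOT_MENTIONED
    categoricals: dict[str, str] = field(default_factory=dict)
    numerics: dict[str, float | str | None] = field(default_factory=dict)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Point estimates (None when undefined) with 95% CIs (F1 carries none)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    f1: float | None
    cis: dict[str, tuple[float, float] | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Binarization


def binarize_diagnosis(status: str) -> bool:
    """YES and POSSIBLE count as HCM positive; NO and NOT_MENTIONED negative."""
    if status in (YES, POSSIBLE):
        return True
    if status in ("NO", NOT_MENTIONED, NOT_EVALUATED):
        return False
    raise EvaluationError(f"invalid diagnosis status {status!r}")


def _value_for(obj: ReportResult | GoldAnnotation, concept_id: str):
    if concept_id == DIAGNOSIS_CONCEPT:
        return obj.diagnosis
    if concept_id == "HCM_SUBTYPE":
        return obj.subtype
    if concept_id == "OBSTRUCTION_LOCATION":
        return obj.obstruction_location
    if concept_id in CATEGORICAL_CONCEPTS:
        return obj.categoricals.get(concept_id, NOT_MENTIONED)
    if concept_id in NUMERIC_CONCEPTS:
        return obj.numerics.get(concept_id)
    raise EvaluationError(f"unknown concept {concept_id!r}")


def _is_positive(concept_id: str, value) -> bool:
    if value is None or value == NOT_EVALUATED:
        return False
    if concept_id == DIAGNOSIS_CONCEPT:
        return binarize_diagnosis(value)
    if concept_id in MULTICLASS_CONCEPTS:
        return value != NOT_MENTIONED
    if concept_id in CATEGORICAL_CONCEPTS:
        return value == PRESENT
    return True  # numeric: any extracted value


def _is_match(concept_id: str, pred, gold, tol: float) -> bool:
    """Do two positive values agree?  Binary concepts always do."""
    if concept_id in MULTICLASS_CONCEPTS:
        return pred == gold
    if concept_id in NUMERIC_CONCEPTS:
        return abs(float(pred) - float(gold)) <= tol
    return True


def confusion_counts(
    predictions: list[ReportResult],
    gold: list[GoldAnnotation],
    concept_id: str,
    numeric_tolerance: float = 0.0,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN for one concept across aligned report sets."""
    pred_by_id = {p.report_id: p for p in predictions}
    gold_by_id = {g.report_id: g for g in gold}
    if len(pred_by_id) != len(predictions):
        raise EvaluationError("duplicate report_ids in predictions")
    if len(gold_by_id) != len(gold):
        raise EvaluationError("duplicate report_ids in gold")
    if set(pred_by_id) != set(gold_by_id):
        missing = sorted(set(gold_by_id) ^ set(pred_by_id))
        raise EvaluationError(f"prediction/gold report_id mismatch: {', '.join(missing)}")

    tp = fp = fn = tn = 0
    for rid, g in gold_by_id.items():
        p = pred_by_id[rid]
        pv, gv = _value_for(p, concept_id), _value_for(g, concept_id)
        ppos, gpos = _is_positive(concept_id, pv), _is_positive(concept_id, gv)
        if ppos and gpos:
            if _is_match(concept_id, pv, gv, numeric_tolerance):
                tp += 1
            else:
                fp += 1  # emitted, but wrong label/value
        elif ppos:
            fp += 1
        elif gpos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def per_label_confusion(
    predictions: list[ReportResult], gold: list[GoldAnnotation], concept_id: str
) -> pd.DataFrame:
    """Supplementary gold-by-predicted label contingency table for a
    multiclass concept."""
    if concept_id not in MULTICLASS_CONCEPTS:
        raise EvaluationError(f"{concept_id} is not multiclass")
    pred_by_id = {p.report_id: p for p in predictions}
    pairs = [
        (str(_value_for(g, concept_id)), str(_value_for(pred_by_id[g.report_id], concept_id)))
        for g in gold
    ]
    df = pd.crosstab(
        pd.Series([a for a, _ in pairs], name="gold"),
        pd.Series([b for _, b in pairs], name="predicted"),
    )
    return df


# ---------------------------------------------------------------------------
# Metrics


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def proportion_ci(
    successes: int, trials: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Two-sided binomial CI for a proportion.

    Clopper–Pearson exact (beta quantiles) by default; ``method="wilson"``
    gives the Wilson score interval.
    """
    k, n = successes, trials
    if not (0 <= k <= n) or n < 1:
        raise EvaluationError(f"invalid (successes, trials) = ({k}, {n})")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return (lo, hi)
    if method == "wilson":
        z = float(stats.norm.ppf(1 - alpha / 2))
        phat = k / n
        denom = 1 + z * z / n
        centre = (phat + z * z / (2 * n)) / denom
        half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
        return (max(0.0, centre - half), min(1.0, centre + half))
    raise EvaluationError(f"unknown CI method {method!r}")


def compute_metrics(
    c: ConfusionCounts, ci_level: float = 0.95, ci_method: str = "clopper-pearson"
) -> MetricSet:
    """The six performance metrics with 95% CIs (none for F1)."""
    if c.total == 0:
        raise EvaluationError("cannot compute metrics on all-zero counts")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    acc = _ratio(c.tp + c.tn, c.total)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)

    cis: dict[str, tuple[float, float] | None] = {}
    for name, k, n in (
        ("sensitivity", c.tp, c.tp + c.fn),
        ("specificity", c.tn, c.tn + c.fp),
        ("ppv", c.tp, c.tp + c.fp),
        ("npv", c.tn, c.tn + c.fn),
        ("accuracy", c.tp + c.tn, c.total),
    ):
        cis[name] = proportion_ci(k, n, ci_level, ci_method) if n > 0 else None
    cis["f1"] = None
    return MetricSet(sens, spec, ppv, npv, acc, f1, cis)


def f1_from(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity."""
    return 2 * (ppv * sensitivity) / (ppv + sensitivity)


# ---------------------------------------------------------------------------
# Whole-table evaluation


def evaluate_all(
    predictions: list[ReportResult],
    gold: list[GoldAnnotation],
    numeric_tolerance: float = 0.0,
    ci_method: str = "clopper-pearson",
) -> pd.DataFrame:
    """One metrics row per phenotype concept (15 rows), with counts and CIs."""
    rows = []
    for cid in CONCEPT_ORDER:
        c = confusion_counts(predictions, gold, cid, numeric_tolerance)
        ms = compute_metrics(c, ci_method=ci_method)
        row: dict[str, object] = {
            "concept": cid, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
        }
        for name in METRIC_NAMES:
            row[name] = getattr(ms, name)
            ci = ms.cis.get(name)
            row[f"{name}_lo"] = ci[0] if ci else None
            row[f"{name}_hi"] = ci[1] if ci else None
        rows.append(row)
    return pd.DataFrame(rows).set_index("concept")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding, 2 decimals half-up (0.985 -> 0.99)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_cell(point, lo, hi) -> str:
    if point is None or (isinstance(point, float) and math.isnan(point)):
        return "undef"
    s = f"{round_half_up(float(point)):.2f}"
    if lo is not None and not (isinstance(lo, float) and math.isnan(lo)):
        s += f" ({round_half_up(float(lo)):.2f}, {round_half_up(float(hi)):.2f})"
    return s


def render_metrics_text(table: pd.DataFrame) -> str:
    """Aligned text rendering: one row per concept, metric (CI) cells."""
    disp = pd.DataFrame(index=table.index)
    for name in METRIC_NAMES:
        disp[name] = [
            _fmt_cell(table.loc[cid, name], table.loc[cid, f"{name}_lo"], table.loc[cid, f"{name}_hi"])
            for cid in table.index
        ]
    return disp.to_string()


def write_metrics(table: pd.DataFrame, out_prefix: str | Path) -> None:
    """Write CSV (full precision), aligned text, and JSON renderings."""
    out_prefix = Path(out_prefix)
    table.to_csv(out_prefix.with_suffix(".csv"))
    out_prefix.with_suffix(".txt").write_text(render_metrics_text(table) + "\n")
    payload = {
        cid: {
            k: (None if pd.isna(v) else (v.item() if hasattr(v, "item") else v))
            for k, v in table.loc[cid].items()
        }
        for cid in table.index
    }
    out_prefix.with_suffix(".json").write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Gold CSV I/O

_GOLD_COLUMNS = [
    "report_id", "diagnosis", "subtype", "obstruction_location",
    *(c.lower() for c in CATEGORICAL_CONCEPTS),
    *(c.lower() for c in NUMERIC_CONCEPTS),
]


def write_gold_csv(gold: list[GoldAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_GOLD_COLUMNS)
        for g in gold:
            row = [g.report_id, g.diagnosis, g.subtype, g.obstruction_location]
            for cid in CATEGORICAL_CONCEPTS:
                v = g.categoricals.get(cid, NOT_MENTIONED)
                row.append("" if v == NOT_MENTIONED else v)
            for cid in NUMERIC_CONCEPTS:
                v = g.numerics.get(cid)
                row.append("" if v in (None, NOT_MENTIONED) else v)
            w.writerow(row)


def read_gold_csv(path: str | Path) -> list[GoldAnnotation]:
    """Read a gold CSV; empty cells mean NOT_MENTIONED (no value)."""
    out: list[GoldAnnotation] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "report_id" not in reader.fieldnames:
            raise EvaluationError(f"{path}: missing report_id column")
        for rec in reader:
            rid = rec["report_id"]
            if rid in seen:
                raise EvaluationError(f"{path}: duplicate report_id {rid!r}")
            seen.add(rid)
            g = GoldAnnotation(
                report_id=rid,
                diagnosis=rec.get("diagnosis", NOT_MENTIONED) or NOT_MENTIONED,
                subtype=rec.get("subtype") or NOT_MENTIONED,
                obstruction_location=rec.get("obstruction_location") or NOT_MENTIONED,
            )
            for cid in CATEGORICAL_CONCEPTS:
                g.categoricals[cid] = rec.get(cid.lower()) or NOT_MENTIONED
            for cid in NUMERIC_CONCEPTS:
                raw = rec.get(cid.lower())
                if raw in (None, ""):
                    g.numerics[cid] = None
                elif raw == NOT_EVALUATED:
                    g.numerics[cid] = NOT_EVALUATED
                else:
                    g.numerics[cid] = float(raw)
            out.append(g)
    return out
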