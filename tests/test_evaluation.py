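"""Confusion counting, performance metrics, and binomial confidence intervals."""

import numpy as np
import pytest

from hcmnlp import (
    ConfusionCounts,
    GoldAnnotation,
    ReportResult,
    binarize_diagnosis,
    compute_metrics,
    confusion_counts,
    evaluate_all,
    f1_from,
    proportion_ci,
    read_gold_csv,
    write_gold_csv,
)
from hcmnlp.evaluation import EvaluationError, per_label_confusion, round_half_up
from hcmnlp.lexicon import CATEGORICAL_CONCEPTS, CONCEPT_ORDER, NUMERIC_CONCEPTS


def make_pair(rid, diag_pred, diag_gold):
    p = ReportResult(report_id=rid, diagnosis=diag_pred)
    g = GoldAnnotation(report_id=rid, diagnosis=diag_gold)
    return p, g


class TestBinarize:
    @pytest.mark.parametrize("status,expected", [
        ("YES", True), ("POSSIBLE", True), ("NO", False), ("NOT_MENTIONED", False),
    ])
    def test_positive_rule(self, status, expected):
        assert binarize_diagnosis(status) is expected

    def test_invalid_status_rejected(self):
        with pytest.raises(EvaluationError):
            binarize_diagnosis("MAYBE")


class TestConfusionCounts:
    def test_perfect_agreement(self):
        pairs = [make_pair(f"r{i}", d, d) for i, d in enumerate(["YES", "YES", "NO", "NO"])]
        c = confusion_counts([p for p, _ in pairs], [g for _, g in pairs], "HCM_DIAGNOSIS")
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 2)

    def test_all_false_positives(self):
        pairs = [make_pair(f"r{i}", "YES", "NO") for i in range(3)]
        c = confusion_counts([p for p, _ in pairs], [g for _, g in pairs], "HCM_DIAGNOSIS")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 3, 0, 0)

    def test_counts_match_per_report_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        statuses = ["YES", "POSSIBLE", "NO", "NOT_MENTIONED"]
        preds, gold = [], []
        for i in range(10):
            preds.append(ReportResult(report_id=f"r{i}", diagnosis=str(rng.choice(statuses))))
            gold.append(GoldAnnotation(report_id=f"r{i}", diagnosis=str(rng.choice(statuses))))
        c = confusion_counts(preds, gold, "HCM_DIAGNOSIS")
        # independent pairwise tally
        tp = fp = fn = tn = 0
        for p, g in zip(preds, gold):
            pp = p.diagnosis in ("YES", "POSSIBLE")
            gp = g.diagnosis in ("YES", "POSSIBLE")
            tp += pp and gp
            fp += pp and not gp
            fn += (not pp) and gp
            tn += (not pp) and (not gp)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 10

    def test_id_mismatch_lists_ids(self):
        p, _ = make_pair("a", "YES", "YES")
        _, g = make_pair("b", "YES", "YES")
        with pytest.raises(EvaluationError, match="a.*b|b.*a"):
            confusion_counts([p], [g], "HCM_DIAGNOSIS")

    def test_numeric_tolerance_controls_tp(self):
        p = ReportResult(report_id="r", diagnosis="YES", numerics={"LV_MASS": 200.0})
        g = GoldAnnotation(report_id="r", diagnosis="YES", numerics={"LV_MASS": 201.0})
        exact = confusion_counts([p], [g], "LV_MASS", numeric_tolerance=0.0)
        loose = confusion_counts([p], [g], "LV_MASS", numeric_tolerance=2.0)
        assert (exact.tp, exact.fp) == (0, 1)
        assert (loose.tp, loose.fp) == (1, 0)

    def test_wrong_multiclass_label_counts_as_false_positive(self):
        p = ReportResult(report_id="r", diagnosis="YES", subtype="SIGMOID")
        g = GoldAnnotation(report_id="r", diagnosis="YES", subtype="APICAL")
        c = confusion_counts([p], [g], "HCM_SUBTYPE")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 0, 0)
        assert c.total == 1


class TestMetrics:
    def test_perfect_counts_give_all_ones(self):
        ms = compute_metrics(ConfusionCounts(1, 0, 0, 1))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1"):
            assert getattr(ms, name) == 1.0

    def test_degenerate_counts_mark_undefined(self):
        ms = compute_metrics(ConfusionCounts(50, 50, 0, 0))
        assert ms.ppv == 0.5 and ms.accuracy == 0.5 and ms.specificity == 0.0
        assert ms.npv is None and ms.cis["npv"] is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_f1_recomputes_published_rows(self):
        assert round_half_up(f1_from(1.00, 0.98)) == 0.99
        assert round_half_up(f1_from(0.78, 1.00)) == 0.88

    def test_metric_identities_on_random_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 40, size=4))
            if tp + fp + fn + tn == 0:
                continue
            ms = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
            P, N = tp + fn, tn + fp
            if ms.sensitivity is not None and ms.specificity is not None:
                blended = (ms.sensitivity * P + ms.specificity * N) / (P + N)
                assert abs(ms.accuracy - blended) < 1e-12
            if ms.f1 is not None:
                assert abs(ms.f1 - f1_from(ms.ppv, ms.sensitivity)) < 1e-12
                assert ms.f1 <= max(ms.ppv, ms.sensitivity) + 1e-12


class TestProportionCI:
    def test_zero_successes_interval(self):
        lo, hi = proportion_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)  # 0.3085

    def test_all_successes_interval_by_symmetry(self):
        lo, hi = proportion_ci(10, 10)
        lo0, hi0 = proportion_ci(0, 10)
        assert hi == 1.0 and lo == pytest.approx(1 - hi0, abs=1e-12)

    def test_reflection_symmetry_at_half(self):
        lo, hi = proportion_ci(5, 10)
        assert lo < 0.5 < hi
        assert lo == pytest.approx(1 - hi, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(EvaluationError):
            proportion_ci(5, 4)
        with pytest.raises(EvaluationError):
            proportion_ci(0, 0)

    def test_wilson_interval_contains_point_estimate(self):
        lo, hi = proportion_ci(40, 50, method="wilson")
        assert lo < 0.8 < hi
        cp_lo, cp_hi = proportion_ci(40, 50)
        assert (hi - lo) <= (cp_hi - cp_lo)  # exact method is conservative


class TestEvaluateAll:
    def _identical_sets(self, n=6):
        preds, gold = [], []
        for i in range(n):
            diag = "YES" if i % 2 == 0 else "NO"
            r = ReportResult(report_id=f"r{i}", diagnosis=diag)
            g = GoldAnnotation(report_id=f"r{i}", diagnosis=diag)
            if diag == "YES":
                r.subtype = g.subtype = "SIGMOID"
                r.obstruction_location = g.obstruction_location = "LVOT"
                for cid in CATEGORICAL_CONCEPTS:
                    r.categoricals[cid] = "PRESENT"
                    g.categoricals[cid] = "PRESENT"
                for cid in NUMERIC_CONCEPTS:
                    r.numerics[cid] = 42.0
                    g.numerics[cid] = 42.0
            else:
                r.subtype = g.subtype = "NOT_EVALUATED"
                r.obstruction_location = g.obstruction_location = "NOT_EVALUATED"
                for cid in CATEGORICAL_CONCEPTS:
                    r.categoricals[cid] = "NOT_EVALUATED"
                    g.categoricals[cid] = "NOT_EVALUATED"
                for cid in NUMERIC_CONCEPTS:
                    r.numerics[cid] = "NOT_EVALUATED"
                    g.numerics[cid] = "NOT_EVALUATED"
            preds.append(r)
            gold.append(g)
        return preds, gold

    def test_fifteen_rows_in_table_order(self):
        preds, gold = self._identical_sets()
        table = evaluate_all(preds, gold)
        assert list(table.index) == list(CONCEPT_ORDER)
        assert len(table) == 15

    def test_identical_sets_score_one_where_defined(self):
        preds, gold = self._identical_sets()
        table = evaluate_all(preds, gold)
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1"):
            vals = table[name].dropna()
            assert (vals == 1.0).all()

    def test_table_metrics_match_recount_from_own_counts(self):
        preds, gold = self._identical_sets()
        # flip one prediction to break perfection
        preds[0].categoricals["SAM"] = "ABSENT_NEGATED"
        table = evaluate_all(preds, gold)
        for cid in table.index:
            c = ConfusionCounts(*(int(table.loc[cid, k]) for k in ("tp", "fp", "fn", "tn")))
            ms = compute_metrics(c)
            for name in ("sensitivity", "ppv", "accuracy"):
                cell = table.loc[cid, name]
                ref = getattr(ms, name)
                if ref is None:
                    assert np.isnan(cell)
                else:
                    assert cell == pytest.approx(ref, abs=1e-12)

    def test_per_label_confusion_totals(self):
        preds, gold = self._identical_sets()
        df = per_label_confusion(preds, gold, "HCM_SUBTYPE")
        assert int(df.to_numpy().sum()) == len(gold)


def test_gold_csv_round_trip(tmp_path):
    g1 = GoldAnnotation(report_id="a", diagnosis="YES", subtype="APICAL",
                        obstruction_location="LVOT")
    for cid in CATEGORICAL_CONCEPTS:
        g1.categoricals[cid] = "PRESENT"
    for cid in NUMERIC_CONCEPTS:
        g1.numerics[cid] = 42.0
    g2 = GoldAnnotation(report_id="b", diagnosis="NO", subtype="NOT_EVALUATED",
                        obstruction_location="NOT_EVALUATED")
    for cid in CATEGORICAL_CONCEPTS:
        g2.categoricals[cid] = "NOT_EVALUATED"
    for cid in NUMERIC_CONCEPTS:
        g2.numerics[cid] = "NOT_EVALUATED"
    path = tmp_path / "gold.csv"
    write_gold_csv([g1, g2], path)
    back = read_gold_csv(path)
    assert back == [g1, g2]
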