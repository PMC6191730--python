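"""Exact statistics: Fisher, predictive values, Pearson, ROC, report."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import auc_pairwise, fisher_p_exact
from refluxscint.stats import (
    ContingencyTable,
    SchemaError,
    benchmark_report,
    fisher_exact_two_tailed,
    pearson_r,
    predictive_values,
    roc_auc,
)


class TestFisher:
    def test_reported_aspiration_table(self):
        """LPR aspirators 58/178 vs GORD 10/72 -> p = 0.0027 (2 s.f.)."""
        p = fisher_exact_two_tailed(ContingencyTable(58, 120, 10, 62))
        assert f"{p:.2g}" == "0.0027"

    def test_balanced_table_gives_one(self):
        assert fisher_exact_two_tailed(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_scipy(self):
        for table in [(58, 120, 10, 62), (3, 9, 8, 2), (1, 0, 0, 1), (12, 5, 7, 11)]:
            mine = fisher_exact_two_tailed(ContingencyTable(*table))
            ref = sps.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_agrees_with_exact_enumeration_small_tables(self):
        """Spot-check against the exact rational oracle (full sweep of all
        tables with total <= 12 runs in the acceptance suite)."""
        for a, b, c, d in [(2, 3, 4, 3), (0, 5, 5, 0), (1, 1, 1, 1), (6, 0, 0, 6)]:
            assert fisher_exact_two_tailed(ContingencyTable(a, b, c, d)) == pytest.approx(
                fisher_p_exact(a, b, c, d), abs=1e-12
            )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 25)] * 4).filter(lambda t: sum(t) > 0))
    def test_invariant_to_transposition_and_row_col_swap(self, table):
        a, b, c, d = table
        p = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
        assert fisher_exact_two_tailed(ContingencyTable(a, c, b, d)) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_two_tailed(ContingencyTable(d, c, b, a)) == pytest.approx(p, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestPredictiveValues:
    def test_perfect_test(self):
        s = predictive_values(ContingencyTable(10, 0, 0, 10))
        assert (s.sensitivity, s.specificity, s.ppv, s.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted_test(self):
        s = predictive_values(ContingencyTable(0, 10, 10, 0))
        assert s.ppv == 0.0 and s.npv == 0.0

    def test_constructed_table(self):
        s = predictive_values(ContingencyTable(49, 1, 3, 60))
        assert s.ppv == pytest.approx(0.98)
        assert s.npv == pytest.approx(60 / 63)

    def test_empty_margin_flagged_not_raised(self):
        s = predictive_values(ContingencyTable(0, 0, 5, 5))
        assert math.isnan(s.ppv)
        assert "ppv" in s.undefined
        assert s.npv == 0.5


class TestPearson:
    def test_identity_and_negation(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.p_value < 0.05

    def test_null_scores_average_half(self):
        rng = np.random.default_rng(0)
        aucs = [
            roc_auc(rng.normal(size=200), rng.random(200) < 0.3).auc for _ in range(200)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(4, 12), seed=st.integers(0, 10_000))
    def test_matches_pairwise_oracle_and_symmetry(self, n, seed):
        """Rank AUC equals brute-force pair counting (ties = 1/2), and
        AUC(s) + AUC(-s) = 1."""
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)
        assert res.auc + roc_auc(-scores, labels).auc == pytest.approx(1.0, abs=1e-12)

    def test_auc_equals_trapezoidal_area(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 3, 300).astype(float)
        labels = rng.random(300) < 0.25
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr), abs=1e-12)
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.normal(size=500) + rng.integers(0, 2, 500)
        labels = rng.random(500) < 0.4
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


def _toy_results(n=40, seed=0):
    rng = np.random.default_rng(seed)
    grades = rng.integers(1, 4, size=(n, 4))
    asp = grades[:, 1] == 3  # aspiration tied to rising supine pharynx
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "symptom_class": ["LPR" if i % 2 else "GORD" for i in range(n)],
            "grade_pharynx_upright": grades[:, 0],
            "grade_pharynx_supine": grades[:, 1],
            "grade_upper_upright": grades[:, 2],
            "grade_upper_supine": grades[:, 3],
            "aspiration_detected": asp,
            "iom_grade": rng.choice(["normal", "mild", "moderate", "severe"], n),
            "proximal_acid_pct": rng.lognormal(1, 1, n),
            "distal_acid_pct": rng.lognormal(2, 1, n),
            "los_pressure": rng.lognormal(1, 1.4, n),
        }
    )


class TestBenchmarkReport:
    def test_missing_columns_listed(self):
        with pytest.raises(SchemaError, match="aspiration_detected"):
            benchmark_report(_toy_results().drop(columns=["aspiration_detected"]))

    def test_partition_and_auditability(self):
        df = _toy_results()
        report = benchmark_report(df)
        ct = report["crosstabs"]
        # each site/posture cross-tab partitions the cohort exactly
        for (site, posture), sub in ct.groupby(["site", "posture"]):
            assert sub.n.sum() == len(df)
        # report PPV/NPV reproducible from the printed counts
        for row in report["predictive_values"].itertuples():
            (a, b), (c, d) = row.table_rising_vs_aspiration
            if a + b:
                assert row.ppv_rising == pytest.approx(a / (a + b))
            if c + d:
                assert row.npv_not_rising == pytest.approx(d / (c + d))
        assert len(report["roc"]) >= 3

    def test_no_grade1_aspirator_gives_unit_npv(self):
        df = _toy_results()
        df.loc[df.grade_pharynx_supine == 1, "aspiration_detected"] = False
        report = benchmark_report(df)
        row = report["predictive_values"].query("site=='pharynx' and posture=='supine'").iloc[0]
        assert row.npv_declining == 1.0
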