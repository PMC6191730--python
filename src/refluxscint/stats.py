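"""Diagnostic benchmarking statistics.

Fisher's exact two-tailed test, predictive values, Pearson correlation
and ROC/AUC, plus assembly of the cohort benchmark report: grade-by-
class-by-aspiration cross-tabulations, the class contingency tests and
per-marker ROC analyses of aspiration prediction.

Two-sided Fisher p-values use the "sum of small p" convention: the sum
of probabilities of all tables with the observed margins whose
hypergeometric probability does not exceed the observed table's (with
the standard 1 + 1e-7 relative guard against floating-point ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class SchemaError(ValueError):
    """Input table is missing required columns."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = group or test result, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("table must have at least one observation")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Exact two-sided p for a 2x2 table with fixed margins."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n > 10**6:
        raise ValueError("table total too large for exact enumeration")
    r1, c1 = a + b, a + c
    dist = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity, specificity, PPV and NPV of a binary test.

    Quantities whose denominator is an empty margin are NaN and listed
    in ``undefined`` rather than silently reported as 0.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: frozenset = field(default_factory=frozenset)


def predictive_values(table: ContingencyTable) -> DiagnosticSummary:
    """Diagnostic summary of a 2x2 test table.

    Row convention: row 1 = test positive, row 2 = test negative;
    column 1 = outcome present (aspiration).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    summary = DiagnosticSummary(
        sensitivity=ratio(a, a + c, "sensitivity"),
        specificity=ratio(d, b + d, "specificity"),
        ppv=ratio(a, a + b, "ppv"),
        npv=ratio(d, c + d, "npv"),
        undefined=frozenset(undefined),
    )
    return summary


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ROCResult:
    """Empirical ROC curve with rank-based AUC and Hanley-McNeil SE."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    p_value: float
    n_positive: int
    n_negative: int


def roc_auc(scores, labels) -> ROCResult:
    """ROC analysis of a continuous or ordinal marker.

    AUC uses the pairwise-concordance (Mann-Whitney) formulation with
    ties counted 1/2, which equals the trapezoidal area under the
    empirical curve.  The standard error is Hanley & McNeil's, and the
    p-value tests AUC = 0.5 two-sided by the normal approximation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = sps.rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # empirical curve over unique thresholds, descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    last_of_group = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    thresholds = sorted_scores[last_of_group]
    tpr = np.r_[0.0, tp[last_of_group] / n1]
    fpr = np.r_[0.0, fp[last_of_group] / n0]
    thresholds = np.r_[math.inf, thresholds]

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(auc),
        auc_se=float(se),
        p_value=float(p),
        n_positive=n1,
        n_negative=n0,
    )


# ---------------------------------------------------------------------------
# cohort benchmark report
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "patient_id",
    "symptom_class",
    "grade_pharynx_upright",
    "grade_pharynx_supine",
    "grade_upper_upright",
    "grade_upper_supine",
    "aspiration_detected",
    "iom_grade",
    "proximal_acid_pct",
    "distal_acid_pct",
    "los_pressure",
)

_IOM_ORDINAL = {"normal": 1, "mild": 2, "moderate": 3, "severe": 4}


def _class_table(df: pd.DataFrame, indicator: pd.Series) -> ContingencyTable:
    """2x2 of a boolean indicator by symptom class (rows LPR, GORD)."""
    lpr = df["symptom_class"] == "LPR"
    return ContingencyTable(
        a=int((indicator & lpr).sum()),
        b=int((~indicator & lpr).sum()),
        c=int((indicator & ~lpr).sum()),
        d=int((~indicator & ~lpr).sum()),
    )


def _grade_test_table(grades: pd.Series, outcome: pd.Series) -> ContingencyTable:
    """Rising curve (grade 3) as the positive test vs the outcome."""
    positive = grades == 3
    return ContingencyTable(
        a=int((positive & outcome).sum()),
        b=int((positive & ~outcome).sum()),
        c=int((~positive & outcome).sum()),
        d=int((~positive & ~outcome).sum()),
    )


def benchmark_report(results: pd.DataFrame) -> dict:
    """Assemble the cohort benchmark report.

    Returns a dict with cross-tabulations (per curve site and posture:
    grade x symptom class with aspiration counts), the Fisher exact
    tests (aspiration by class, severe IOM by class, normal motility by
    class), predictive values of rising/declining curves for aspiration,
    and ROC analyses for each candidate marker.  All counts used are
    included so every derived number is auditable.  No multiple-testing
    correction is applied; each test is read at the 0.05 level.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"results table missing columns: {missing}")
    df = results
    aspirated = df["aspiration_detected"].astype(bool)

    crosstabs = []
    for site in ("pharynx", "upper"):
        for posture in ("upright", "supine"):
            col = f"grade_{site}_{posture}"
            for cls in ("LPR", "GORD"):
                sel = df["symptom_class"] == cls
                for grade in (1, 2, 3):
                    g = sel & (df[col] == grade)
                    crosstabs.append(
                        {
                            "site": site,
                            "posture": posture,
                            "symptom_class": cls,
                            "grade": grade,
                            "n": int(g.sum()),
                            "n_aspirated": int((g & aspirated).sum()),
                        }
                    )
    crosstab_df = pd.DataFrame(crosstabs)

    fisher = {}
    t = _class_table(df, aspirated)
    fisher["aspiration_by_class"] = {
        "table": t.as_array().tolist(),
        "p": fisher_exact_two_tailed(t),
    }
    t = _class_table(df, df["iom_grade"] == "severe")
    fisher["severe_iom_by_class"] = {
        "table": t.as_array().tolist(),
        "p": fisher_exact_two_tailed(t),
    }
    t = _class_table(df, df["iom_grade"] == "normal")
    fisher["normal_motility_by_class"] = {
        "table": t.as_array().tolist(),
        "p": fisher_exact_two_tailed(t),
    }

    predictive = []
    for site in ("pharynx", "upper"):
        for posture in ("upright", "supine"):
            col = f"grade_{site}_{posture}"
            table = _grade_test_table(df[col], aspirated)
            summary = predictive_values(table)
            declining = df[col] == 1
            n_decl = int(declining.sum())
            npv_declining = (
                float((declining & ~aspirated).sum() / n_decl) if n_decl else math.nan
            )
            predictive.append(
                {
                    "site": site,
                    "posture": posture,
                    "table_rising_vs_aspiration": table.as_array().tolist(),
                    "ppv_rising": summary.ppv,
                    "npv_not_rising": summary.npv,
                    "npv_declining": npv_declining,
                    "n_declining": n_decl,
                    "sensitivity": summary.sensitivity,
                    "specificity": summary.specificity,
                }
            )
    predictive_df = pd.DataFrame(predictive)

    markers = {
        "grade_pharynx_supine": df["grade_pharynx_supine"],
        "grade_pharynx_upright": df["grade_pharynx_upright"],
        "grade_upper_supine": df["grade_upper_supine"],
        "grade_upper_upright": df["grade_upper_upright"],
        "iom_grade": df["iom_grade"].map(_IOM_ORDINAL),
        "proximal_acid_pct": df["proximal_acid_pct"],
        "distal_acid_pct": df["distal_acid_pct"],
        "los_pressure": df["los_pressure"],
    }
    roc = {}
    for name, scores in markers.items():
        try:
            res = roc_auc(scores.to_numpy(dtype=float), aspirated.to_numpy())
            roc[name] = {
                "auc": res.auc,
                "auc_se": res.auc_se,
                "p": res.p_value,
                "n_positive": res.n_positive,
                "n_negative": res.n_negative,
            }
        except ValueError:
            roc[name] = {"auc": math.nan, "note": "undefined (single class or constant)"}

    return {
        "n_patients": int(len(df)),
        "crosstabs": crosstab_df,
        "fisher": fisher,
        "predictive_values": predictive_df,
        "roc": roc,
        "footer": "No multiple-testing correction applied; each test read at alpha=0.05.",
    }
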