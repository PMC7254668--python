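"""ROC evaluation and univariate feature-response association testing.

Conventions follow the breast-cancer response-assessment literature: the
classifier scores the probability of pathologic complete response (pCR),
but operating-point metrics (sensitivity, specificity, PPV, NPV) are
reported with **no-pCR as the positive class**, i.e. sensitivity is the
true-positive rate for detecting residual disease.

AUROC confidence intervals and the paired ROC-curve comparison use the
DeLong method (the default of the pROC reference implementation);
binomial rates get exact Clopper-Pearson intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import LABEL_NO_PCR, LABEL_PCR


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Placement values and AUC for one score vector (y: 1=positive)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-negative placements
    return auc, v10, v01


def auroc(scores, y) -> float:
    """Mann-Whitney AUC (tie-corrected) with 1 as the positive class."""
    auc, _, _ = _delong_components(np.asarray(scores, float), np.asarray(y))
    return float(auc)


def auroc_ci(scores, y, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong asymptotic confidence interval.

    Returns ``(auc, lower, upper)`` with the interval clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    auc, v10, v01 = _delong_components(scores, y)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def compare_rocs(scores_a, scores_b, y) -> tuple[float, float]:
    """Paired DeLong test for two correlated ROC curves.

    ``scores_a`` and ``scores_b`` must score the same cases.  Returns
    ``(delta_auc, p_value)`` for the two-sided test; identical score
    vectors give p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != y.shape[0]:
        raise ValueError("paired score vectors must cover the same cases")
    auc_a, v10_a, v01_a = _delong_components(scores_a, y)
    auc_b, v10_b, v01_b = _delong_components(scores_b, y)
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (
        s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]
    ) / v10.shape[1] + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / v01.shape[1]
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# operating-point metrics
# ---------------------------------------------------------------------------

def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson interval for a binomial proportion."""
    if n == 0:
        return 0.0, 1.0
    alpha = 1 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def operating_metrics(
    scores, y_positive, threshold: float
) -> dict[str, tuple[float, float, float]]:
    """Sensitivity, specificity, PPV and NPV at a fixed score threshold.

    ``scores`` are scores for the positive class and a case is called
    positive when ``score >= threshold``.  Each metric is returned as
    ``(point, ci_lower, ci_upper)`` with exact binomial intervals.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_positive).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())

    def rate(k, n):
        point = k / n if n else 0.0
        return (float(point), *_binomial_ci(k, n))

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
    }


def roc_points(scores, y_positive) -> pd.DataFrame:
    """Full ROC curve as (threshold, fpr, tpr) rows."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_positive).astype(bool)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    n1 = y.sum()
    n0 = (~y).sum()
    for t in thresholds:
        pred = scores >= t
        rows.append(
            {
                "threshold": t,
                "fpr": (pred & ~y).sum() / n0,
                "tpr": (pred & y).sum() / n1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate association
# ---------------------------------------------------------------------------

def feature_association(
    table: pd.DataFrame, features: list[str], label_column: str = "label"
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg correction.

    Each feature is compared between the response classes; the returned
    frame has columns ``p`` and ``q`` (BH-adjusted), indexed by feature.
    Constant features get p = 1.
    """
    y = table[label_column]
    a_rows = y == LABEL_PCR
    b_rows = y == LABEL_NO_PCR
    if a_rows.sum() < 2 or b_rows.sum() < 2:
        raise ValueError("need at least 2 observations per class")
    ps = []
    for f in features:
        a = table.loc[a_rows, f].to_numpy(dtype=float)
        b = table.loc[b_rows, f].to_numpy(dtype=float)
        if np.all(a == a[0]) and np.all(b == a[0]):
            ps.append(1.0)
            continue
        ps.append(float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue))
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    return pd.DataFrame({"p": ps, "q": qs}, index=pd.Index(features, name="feature"))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Evaluation summary mirroring the standard response-assessment table."""

    auroc: float
    auroc_ci: tuple[float, float]
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    ppv: tuple[float, float, float]
    npv: tuple[float, float, float]
    threshold: float
    n_cases: int
    n_positive: int          #: positives in the no-pCR orientation
    association: pd.DataFrame | None = None
    comparison_p: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.association is not None:
            d["association"] = self.association.reset_index().to_dict("records")
        return d


def evaluate_scores(
    scores_pcr, labels: pd.Series, threshold: float
) -> EvalReport:
    """Build an :class:`EvalReport` from classifier scores and labels.

    ``scores_pcr`` are the classifier's P(pCR) values; ``threshold`` is on
    the same scale (cases with P(pCR) < threshold are called no-pCR).  The
    AUROC is orientation-invariant; sensitivity/specificity use no-pCR as
    the positive class.
    """
    scores_pcr = np.asarray(scores_pcr, dtype=float)
    y_pcr = (np.asarray(labels) == LABEL_PCR).astype(int)
    auc, lo, hi = auroc_ci(scores_pcr, y_pcr)
    scores_nopcr = 1.0 - scores_pcr
    y_nopcr = 1 - y_pcr
    metrics = operating_metrics(scores_nopcr, y_nopcr, 1.0 - threshold)
    return EvalReport(
        auroc=auc,
        auroc_ci=(lo, hi),
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        ppv=metrics["ppv"],
        npv=metrics["npv"],
        threshold=float(threshold),
        n_cases=len(y_pcr),
        n_positive=int(y_nopcr.sum()),
    )
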