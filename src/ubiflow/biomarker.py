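"""Clinical biomarker statistics for the serum-glutamine cohort.

Two-group comparison (from raw values or from published summary
statistics), a Pearson correlation matrix over clinical variables with
pairwise deletion of missing values, and ROC/AUC for a continuous marker
against a binary diagnosis.  The AUC is the Mann-Whitney U statistic with
half-credit for ties, normalised by n_pos * n_neg — identical to
trapezoidal integration of the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalCohort

__all__ = [
    "SummaryStats",
    "RocResult",
    "ttest_from_summary",
    "ttest_cohort",
    "roc_auc",
    "roc_curve_points",
    "correlation_matrix",
]


@dataclass(frozen=True)
class SummaryStats:
    """Two-group summary: group1 = normal/reference, group2 = case."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    units: str = ""

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    tie_count: int


def ttest_from_summary(
    s: SummaryStats, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    pooled: t = (mean2-mean1)/sqrt(sp^2 (1/n1+1/n2)), df = n1+n2-2 with
    sp^2 the pooled variance.  welch: Welch-Satterthwaite df.  Returns
    (t, df, two-sided p).  Degenerate all-equal input gives p = 1.
    """
    diff = s.mean2 - s.mean1
    if variant == "pooled":
        df = s.n1 + s.n2 - 2
        sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
        se = np.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
    elif variant == "welch":
        a, b = s.sd1**2 / s.n1, s.sd2**2 / s.n2
        se = np.sqrt(a + b)
        if se > 0:
            df = (a + b) ** 2 / (a**2 / (s.n1 - 1) + b**2 / (s.n2 - 1))
        else:
            df = s.n1 + s.n2 - 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        if diff == 0:
            return 0.0, float(df), 1.0  # no variance, no difference
        return float(np.inf) * np.sign(diff), float(df), 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def ttest_cohort(
    cohort: ClinicalCohort, variable: str, variant: str = "pooled"
) -> tuple[float, float, float, SummaryStats]:
    """Two-group t-test on a raw cohort variable; also returns the summary."""
    g1, g2 = cohort.group_order
    x1 = cohort.subjects.loc[cohort.subjects["group"] == g1, variable].dropna()
    x2 = cohort.subjects.loc[cohort.subjects["group"] == g2, variable].dropna()
    s = SummaryStats(
        float(x1.mean()), float(x1.std(ddof=1)), int(len(x1)),
        float(x2.mean()), float(x2.std(ddof=1)), int(len(x2)),
    )
    return (*ttest_from_summary(s, variant), s)


def roc_auc(scores, labels) -> RocResult:
    """AUC via the rank-sum (Mann-Whitney) identity with tie half-credit.

    ``labels`` are binary with 1 = positive (case) class; a higher score
    is read as evidence for the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    n_ties = int(len(scores) - len(np.unique(scores)))
    return RocResult(float(auc), n_pos, n_neg, n_ties)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC coordinates (FPR, TPR, threshold), tie-aware."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    # step only at distinct thresholds
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y == 1)[distinct]
    fp = np.cumsum(y == 0)[distinct]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fp / n_neg],
            "tpr": np.r_[0.0, tp / n_pos],
        }
    )


def correlation_matrix(
    cohort: ClinicalCohort, variables: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix with pairwise deletion.

    A 20-subject cohort cannot afford listwise deletion, so each pair uses
    its complete subjects (>= 3 required, else the cell is missing, as it
    is for constant variables).
    """
    variables = variables or cohort.variables
    data = cohort.subjects[variables].astype(float)
    out = pd.DataFrame(np.nan, index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i:]:
            if a == b:
                x = data[a].dropna().to_numpy()
                if len(x) >= 3 and np.ptp(x) != 0:
                    out.loc[a, a] = 1.0
                continue
            pair = data[[a, b]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair[a].to_numpy(), pair[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            out.loc[a, b] = r
            out.loc[b, a] = r
    return out
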