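"""Two-group differential abundance testing.

The default test is the ordinary pooled-variance Student t on log2
intensities, with the field's common significance rule: p < alpha and
linear fold change above a threshold (default 1.5).  A variance-moderated
mode is provided as an opt-in: per-feature variances are shrunk toward a
pooled prior fitted by the method of moments on log sample variances
(the scaled inverse-chi-square empirical Bayes model), which stabilises
t statistics at n = 4 per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix, SampleDesign

__all__ = [
    "DiffParams",
    "differential_expression",
    "count_differential",
    "moderate_variances",
]


@dataclass(frozen=True)
class DiffParams:
    """alpha: significance level on the (optionally adjusted) p-value.
    fc_threshold: linear fold-change cut, applied symmetrically to both
    directions.  test: student (pooled), welch, or moderated.
    prior_df: fixes the moderated prior degrees of freedom instead of
    estimating them (0 recovers the ordinary Student t exactly)."""

    alpha: float = 0.05
    fc_threshold: float = 1.5
    test: str = "student"
    adjust: str = "none"
    prior_df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1 (linear scale)")
        if self.test not in ("student", "welch", "moderated"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.adjust not in ("none", "BH"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(
    s2: np.ndarray, df: float, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward a fitted prior.

    Method of moments on z = log(s2): under the scaled inverse-chi-square
    model, z - digamma(df/2) + log(df/2) has mean log(s0^2) - digamma(d0/2)
    + log(d0/2) and excess variance trigamma(d0/2) beyond trigamma(df/2);
    inverting the trigamma gives the prior df d0, and the mean gives the
    prior variance s0^2.  Returns (posterior variances, d0, s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0.0:
            return s2.copy(), 0.0, float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
        if not np.isfinite(d0):
            s0_2 = float(np.mean(s2))
            return np.full_like(s2, s0_2), d0, s0_2
        # moment-match s0^2 given fixed d0
        z = np.log(np.maximum(s2, 1e-300))
        e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        z = np.log(np.maximum(s2, 1e-300))
        e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
        n = e.size
        evar = float(np.var(e, ddof=1)) if n > 1 else 0.0
        excess = evar - float(special.polygamma(1, df / 2.0))
        if excess <= 0:
            d0 = np.inf
            s0_2 = float(np.exp(np.mean(e)))
            return np.full_like(s2, s0_2), d0, s0_2
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


def differential_expression(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    params: DiffParams | None = None,
) -> pd.DataFrame:
    """Per-feature two-group test on a log2-normalised, imputed matrix.

    Returns a DataFrame with columns feature_id, log2fc, stat, pvalue,
    adj_pvalue, significant, direction.  log2fc is mean(group2) −
    mean(group1) with groups taken from ``design.group_order``
    (treatment over control).
    """
    params = params or DiffParams()
    if matrix.scale != "log2_normalized":
        raise ValueError("differential_expression expects log2-normalised data")
    if matrix.missing_mask.to_numpy().any():
        raise ValueError("matrix contains missing cells; impute first")
    matrix.check_design(design)
    g1, g2 = design.group_order
    x1 = matrix.values[list(design.samples_in(g1))].to_numpy(dtype=float)
    x2 = matrix.values[list(design.samples_in(g2))].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples")

    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m2 - m1
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    if params.test == "welch":
        se2 = v1 / n1 + v2 / n2
        stat = np.where(se2 > 0, log2fc / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        num = se2**2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        df = np.where(den > 0, num / np.where(den > 0, den, 1.0), n1 + n2 - 2)
        pvalue = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        df0 = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df0
        if params.test == "moderated":
            sp2, d0, _ = moderate_variances(sp2, df0, params.prior_df)
            df = df0 + d0
        else:
            df = float(df0)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        if np.isinf(np.atleast_1d(df)).all():
            pvalue = 2.0 * stats.norm.sf(np.abs(stat))
        else:
            pvalue = 2.0 * stats.t.sf(np.abs(stat), df)

    # exactly-zero contrasts with zero variance: no evidence either way
    pvalue = np.where((log2fc == 0) & (stat == 0), 1.0, pvalue)
    pvalue = np.clip(pvalue, np.nextafter(0, 1), 1.0)

    if params.adjust == "BH":
        adj = multipletests(pvalue, method="fdr_bh")[1]
    else:
        adj = pvalue.copy()

    lfc_cut = np.log2(params.fc_threshold)
    significant = (adj < params.alpha) & (np.abs(log2fc) >= lfc_cut)
    direction = np.where(
        significant, np.where(log2fc > 0, "up", "down"), "none"
    )
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pvalue,
            "adj_pvalue": adj,
            "significant": significant,
            "direction": direction,
        }
    ).reset_index(drop=True)


def count_differential(records: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) among significant features."""
    sig = records[records["significant"]]
    return int((sig["direction"] == "up").sum()), int((sig["direction"] == "down").sum())
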