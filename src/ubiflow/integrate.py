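"""Proteome-ubiquitinome integration: degradative vs non-degradative sites.

The biological question: does a change in a diGly site reflect targeted
degradation of the parent protein, or a signalling event independent of
protein turnover?  The decision logic, applied to every significant
differential site:

1. parent protein not quantified in the proteome -> ``protein_unquantified``
   (kept as its own class for auditability rather than silently counted
   as non-degradative);
2. parent protein itself differential with the SAME-signed trend and the
   site's per-sample profile strongly positively Spearman-correlated with
   the protein's (rho >= rho_min) -> ``removed_confounded``: the apparent
   site change is explained by protein abundance;
3. site trend OPPOSITE in sign to the protein trend -> ``degradative``;
4. otherwise -> ``non_degradative``.

Classes are exhaustive and mutually exclusive, so they partition the
significant-site set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix

__all__ = [
    "ClassifyParams",
    "site_protein_spearman",
    "classify_sites",
    "summarize_classification",
    "CLASSES",
]

CLASSES = ("degradative", "non_degradative", "removed_confounded", "protein_unquantified")


@dataclass(frozen=True)
class ClassifyParams:
    """rho_min: minimum positive Spearman correlation (site vs protein
    profile) for confound removal; the removal additionally requires a
    same-signed differential protein, so stably co-varying but genuinely
    regulated sites are not discarded.
    protein_trend_epsilon: minimum |protein log2fc| to call a protein
    trend (0 = raw sign).
    require_protein_significant: gate the opposite-trend rule on protein
    significance.  On by default: a flat protein's fold change is pure
    noise with a random sign, so an ungated opposite-sign rule would push
    about half of all genuinely protein-independent sites into the
    degradative class."""

    rho_min: float = 0.7
    protein_trend_epsilon: float = 0.0
    require_protein_significant: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_min <= 1.0):
            raise ValueError("rho_min must lie in (0, 1]")
        if self.protein_trend_epsilon < 0:
            raise ValueError("protein_trend_epsilon must be >= 0")


def site_protein_spearman(
    site_profile: np.ndarray, protein_profile: np.ndarray
) -> float:
    """Spearman rho between a site's and its protein's per-sample profiles.

    Pearson correlation of mid-ranks (ties receive the mean rank).
    A constant profile leaves rho undefined; NaN is returned and treated
    as 0 by the confound filter.
    """
    x = np.asarray(site_profile, dtype=float)
    y = np.asarray(protein_profile, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must share >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classify_sites(
    diff_sites: pd.DataFrame,
    diff_proteins: pd.DataFrame,
    annotations: pd.DataFrame,
    site_matrix: AbundanceMatrix,
    protein_matrix: AbundanceMatrix,
    params: ClassifyParams | None = None,
) -> pd.DataFrame:
    """Classify every significant differential site.

    Parameters
    ----------
    diff_sites, diff_proteins:
        Outputs of :func:`ubiflow.diffexpr.differential_expression` for the
        ubiquitinome and proteome layers.
    annotations:
        Site table indexed by site_id with a ``protein_id`` column.
    site_matrix, protein_matrix:
        The preprocessed (log2, imputed) matrices the tests ran on; the
        Spearman correlation is computed on these profiles across all
        shared samples.

    Returns a table with one row per significant site: site_id,
    protein_id, site_log2fc, site_pvalue, protein_log2fc, protein_pvalue,
    rho, class.
    """
    params = params or ClassifyParams()
    sig = diff_sites[diff_sites["significant"]]

    orphans = [
        s
        for s in sig["feature_id"]
        if s not in annotations.index
    ]
    if orphans:
        raise ValueError(f"significant sites without annotation: {orphans}")

    prot = diff_proteins.set_index("feature_id")
    shared = [s for s in site_matrix.sample_ids if s in set(protein_matrix.sample_ids)]
    if len(shared) < 3:
        raise ValueError("site and protein matrices share fewer than 3 samples")

    rows = []
    for rec in sig.itertuples():
        site_id = rec.feature_id
        protein_id = annotations.loc[site_id, "protein_id"]
        row = {
            "site_id": site_id,
            "protein_id": protein_id,
            "site_log2fc": rec.log2fc,
            "site_pvalue": rec.pvalue,
            "protein_log2fc": np.nan,
            "protein_pvalue": np.nan,
            "rho": np.nan,
        }
        if protein_id not in prot.index:
            row["class"] = "protein_unquantified"
            rows.append(row)
            continue
        p = prot.loc[protein_id]
        row["protein_log2fc"] = p["log2fc"]
        row["protein_pvalue"] = p["pvalue"]
        rho = site_protein_spearman(
            site_matrix.values.loc[site_id, shared].to_numpy(dtype=float),
            protein_matrix.values.loc[protein_id, shared].to_numpy(dtype=float),
        )
        row["rho"] = rho
        rho_eff = 0.0 if np.isnan(rho) else rho

        same_sign = np.sign(rec.log2fc) == np.sign(p["log2fc"]) and p["log2fc"] != 0
        protein_trend = abs(p["log2fc"]) > params.protein_trend_epsilon
        if params.require_protein_significant:
            protein_trend = protein_trend and bool(p["significant"])

        if bool(p["significant"]) and same_sign and rho_eff >= params.rho_min:
            row["class"] = "removed_confounded"
        elif protein_trend and np.sign(rec.log2fc) == -np.sign(p["log2fc"]):
            row["class"] = "degradative"
        else:
            row["class"] = "non_degradative"
        rows.append(row)

    cols = [
        "site_id",
        "protein_id",
        "site_log2fc",
        "site_pvalue",
        "protein_log2fc",
        "protein_pvalue",
        "rho",
        "class",
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_classification(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per class: number of sites and number of DISTINCT parent proteins."""
    rows = []
    for cls in CLASSES:
        sub = classifications[classifications["class"] == cls]
        rows.append(
            {
                "class": cls,
                "n_sites": int(len(sub)),
                "n_proteins": int(sub["protein_id"].nunique()),
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_sites", "n_proteins"])
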