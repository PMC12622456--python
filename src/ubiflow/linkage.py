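"""Ubiquitin chain-linkage composition from remnant diGly peptides.

Peptides carrying a diGly remnant on one of ubiquitin's own lysines
(K6/K11/K27/K29/K33/K48/K63) report poly-ubiquitin chain topology: K48 is
the canonical degradation signal, K63 non-degradative signalling.  M1
(linear) chains leave no remnant and are excluded by construction.

Multiple remnant peptides mapping to the same linkage are aggregated by
mean log2 intensity before testing; per-group linkage shares are computed
on linear-scale means.  Because "coverage" can mean share of summed
intensity or share of detected peptides, both are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffexpr import DiffParams, differential_expression
from .io import LINKAGE_POSITIONS, AbundanceMatrix, SampleDesign

__all__ = ["extract_linkage_sites", "linkage_abundance"]


def extract_linkage_sites(annotations: pd.DataFrame) -> pd.DataFrame:
    """Subset of the annotation: ubiquitin-derived sites at chain positions.

    Ubiquitin-flagged sites at non-linkage positions are excluded with a
    warning (they cannot report chain topology).
    """
    ub = annotations[annotations["is_ubiquitin_site"]]
    valid = ub["position"].isin(LINKAGE_POSITIONS)
    if (~valid).any():
        bad = ub.index[~valid].tolist()
        warnings.warn(
            f"ubiquitin-flagged sites at non-linkage positions excluded: {bad}",
            stacklevel=2,
        )
    return ub[valid]


def linkage_abundance(
    matrix: AbundanceMatrix,
    linkage_sites: pd.DataFrame,
    design: SampleDesign,
    diff_params: DiffParams | None = None,
) -> pd.DataFrame:
    """Per-linkage abundance profile, shares and between-group test.

    Expects the preprocessed (log2, imputed) site matrix.  Returns one row
    per detected linkage: linkage, n_peptides, mean_group1, mean_group2
    (linear scale), share_group1, share_group2 (per-sample linear-scale
    intensity shares averaged within group),
    peptide_share_group1/2 (detected-peptide shares), log2fc, pvalue.
    Shares over detected linkages sum to 1 within each group; absent
    linkages are absent from the table, not zero rows.
    """
    diff_params = diff_params or DiffParams()
    if matrix.scale != "log2_normalized":
        raise ValueError("linkage_abundance expects a log2-normalised matrix")
    present = [s for s in linkage_sites.index if s in set(matrix.feature_ids)]
    if not present:
        warnings.warn("no linkage peptides detected; empty profile", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "linkage", "n_peptides", "mean_group1", "mean_group2",
                "share_group1", "share_group2",
                "peptide_share_group1", "peptide_share_group2",
                "log2fc", "pvalue",
            ]
        )
    sites = linkage_sites.loc[present]

    # aggregate peptides -> linkage by mean of log2 profiles
    agg_rows: dict[str, np.ndarray] = {}
    n_peps: dict[str, int] = {}
    for pos in LINKAGE_POSITIONS:
        ids = sites.index[sites["position"] == pos]
        if len(ids) == 0:
            continue
        prof = matrix.values.loc[ids].to_numpy(dtype=float).mean(axis=0)
        agg_rows[f"K{pos}"] = prof
        n_peps[f"K{pos}"] = len(ids)
    agg = pd.DataFrame(agg_rows, index=matrix.sample_ids).T
    agg_mat = AbundanceMatrix(agg, scale="log2_normalized")

    de = differential_expression(agg_mat, design, diff_params).set_index("feature_id")

    g1, g2 = design.group_order
    lin = np.power(2.0, agg)
    m1 = lin[list(design.samples_in(g1))].mean(axis=1)
    m2 = lin[list(design.samples_in(g2))].mean(axis=1)
    # shares per sample (a per-sample scale factor cancels), then averaged
    # within group
    per_sample_share = lin / lin.sum(axis=0)
    s1 = per_sample_share[list(design.samples_in(g1))].mean(axis=1)
    s2 = per_sample_share[list(design.samples_in(g2))].mean(axis=1)
    total_peps = sum(n_peps.values())

    out = pd.DataFrame(
        {
            "linkage": agg.index,
            "n_peptides": [n_peps[k] for k in agg.index],
            "mean_group1": m1.to_numpy(),
            "mean_group2": m2.to_numpy(),
            "share_group1": s1.to_numpy(),
            "share_group2": s2.to_numpy(),
            "peptide_share_group1": [n_peps[k] / total_peps for k in agg.index],
            "peptide_share_group2": [n_peps[k] / total_peps for k in agg.index],
            "log2fc": de.loc[agg.index, "log2fc"].to_numpy(),
            "pvalue": de.loc[agg.index, "pvalue"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out
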