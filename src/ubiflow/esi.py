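"""Mapping differential E3 ligases / DUBs to predicted substrates.

Differential enzymes from the proteome layer are intersected with
differential diGly sites on their library-predicted substrates.  A pair
is retained when the directions are consistent with catalysis: more E3
should mean more substrate ubiquitylation (E3 up & site up, or E3 down &
site down), more DUB should mean less (DUB up & site down, DUB down &
site up).  Retained pairs are ranked by library confidence, descending,
with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import EsiLibrary

__all__ = [
    "candidate_pairs",
    "retain_modifying",
    "rank_retained",
    "aggregate_pairs",
    "RETENTION_RULE",
]

logger = logging.getLogger(__name__)

# (enzyme_class, enzyme_direction, site_direction) -> retained
RETENTION_RULE: dict[tuple[str, str, str], bool] = {
    ("E3", "up", "up"): True,
    ("E3", "down", "down"): True,
    ("E3", "up", "down"): False,
    ("E3", "down", "up"): False,
    ("DUB", "up", "down"): True,
    ("DUB", "down", "up"): True,
    ("DUB", "up", "up"): False,
    ("DUB", "down", "down"): False,
}

PAIR_COLUMNS = [
    "enzyme_id",
    "enzyme_class",
    "substrate_id",
    "site_id",
    "enzyme_direction",
    "site_direction",
    "confidence",
    "retained",
    "rank",
]


def candidate_pairs(
    diff_enzymes: pd.DataFrame,
    diff_sites: pd.DataFrame,
    annotations: pd.DataFrame,
    library: EsiLibrary,
) -> pd.DataFrame:
    """Triple join: library record x differential enzyme x differential site.

    ``diff_enzymes`` is the proteome differential table restricted to
    E3/DUB proteins (class annotation supplied by the caller); only
    significant enzymes and significant sites enter.  One candidate per
    (library record, matching site on that substrate); ``retained`` and
    ``rank`` are left undecided.
    """
    enz = diff_enzymes[diff_enzymes["significant"]].set_index("feature_id")
    sig_sites = diff_sites[diff_sites["significant"]].set_index("feature_id")

    site_ann = annotations.loc[[s for s in sig_sites.index if s in annotations.index]]
    sites_by_protein: dict[str, list[str]] = {}
    for site_id, row in site_ann.iterrows():
        sites_by_protein.setdefault(row["protein_id"], []).append(site_id)

    rows = []
    n_unmatched = 0
    for rec in library.records.itertuples():
        if rec.enzyme_id not in enz.index:
            continue
        site_ids = sites_by_protein.get(rec.substrate_id)
        if not site_ids:
            n_unmatched += 1
            continue
        for site_id in site_ids:
            rows.append(
                {
                    "enzyme_id": rec.enzyme_id,
                    "enzyme_class": rec.enzyme_class,
                    "substrate_id": rec.substrate_id,
                    "site_id": site_id,
                    "enzyme_direction": enz.loc[rec.enzyme_id, "direction"],
                    "site_direction": sig_sites.loc[site_id, "direction"],
                    "confidence": rec.confidence,
                    "retained": False,
                    "rank": pd.NA,
                }
            )
    if n_unmatched:
        logger.info(
            "%d library records with a differential enzyme but no matching "
            "differential site", n_unmatched,
        )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    assert not out.duplicated(["enzyme_id", "enzyme_class", "substrate_id", "site_id"]).any()
    return out


def retain_modifying(pairs: pd.DataFrame) -> pd.DataFrame:
    """Flag pairs whose directions are consistent with catalysis."""
    out = pairs.copy()
    out["retained"] = [
        RETENTION_RULE[(c, e, s)]
        for c, e, s in zip(
            out["enzyme_class"], out["enzyme_direction"], out["site_direction"]
        )
    ]
    return out


def rank_retained(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rank retained pairs 1..n by descending confidence.

    Ties broken by (enzyme_id, substrate_id, site_id) lexicographically, so
    the ranking is invariant under input order.  Non-retained pairs keep a
    missing rank.
    """
    out = pairs.copy()
    kept = out[out["retained"]].sort_values(
        by=["confidence", "enzyme_id", "substrate_id", "site_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    out["rank"] = pd.NA
    out.loc[kept.index, "rank"] = range(1, len(kept) + 1)
    out["rank"] = out["rank"].astype("Int64")
    return out


def aggregate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse site-level retained pairs to (enzyme, substrate) level.

    Several significant sites on one substrate yield several site-level
    candidates for the same library record; the enzyme-substrate report
    keeps the best (lowest) rank per pair, preserving rank order.
    """
    kept = pairs[pairs["retained"]]
    if kept.empty:
        return pd.DataFrame(
            columns=["enzyme_id", "enzyme_class", "substrate_id", "confidence",
                     "n_sites", "best_rank"]
        )
    agg = (
        kept.groupby(["enzyme_id", "enzyme_class", "substrate_id"], sort=False)
        .agg(
            confidence=("confidence", "max"),
            n_sites=("site_id", "nunique"),
            best_rank=("rank", "min"),
        )
        .reset_index()
        .sort_values("best_rank")
        .reset_index(drop=True)
    )
    return agg
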