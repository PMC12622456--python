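import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ubiflow import (
    CLASSES,
    ClassifyParams,
    classify_sites,
    site_protein_spearman,
    summarize_classification,
)
from .conftest import make_matrix


def rank_then_pearson(x, y):
    """Independent Spearman oracle: explicit mid-ranks, then the Pearson
    product-moment formula written out."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_comonotone_is_one(self):
        assert site_protein_spearman([1, 5, 9, 12], [2, 3, 7, 100]) == pytest.approx(1.0)

    def test_antimonotone_is_minus_one(self):
        assert site_protein_spearman([1, 5, 9, 12], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_constant_profile_is_nan(self):
        assert np.isnan(site_protein_spearman([3, 3, 3, 3], [1, 2, 3, 4]))

    @given(seed=st.integers(0, 200))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=8).astype(float)  # ties likely
        y = rng.normal(size=8)
        if np.ptp(x) == 0:
            return
        assert site_protein_spearman(x, y) == pytest.approx(
            rank_then_pearson(x, y), abs=1e-12
        )

    def test_eight_point_profile_with_tie(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0, 7.0, 6.0, 8.0]
        assert site_protein_spearman(x, y) == pytest.approx(
            rank_then_pearson(x, y), abs=1e-12
        )


def build_fixture(design, site_rows, protein_rows, site_de, protein_de):
    """Assemble classify_sites inputs from explicit per-feature rows."""
    ann = pd.DataFrame(
        [
            {"site_id": s, "protein_id": p, "position": 10, "is_ubiquitin_site": False}
            for s, p in [(r["site_id"], r["protein_id"]) for r in site_de]
        ]
    ).set_index("site_id")
    site_mat = make_matrix(site_rows, design, scale="log2_normalized", feature_prefix="S")
    site_mat.values.index = [r["site_id"] for r in site_de]
    prot_mat = make_matrix(protein_rows, design, scale="log2_normalized", feature_prefix="P")
    prot_mat.values.index = [r["feature_id"] for r in protein_de]
    ds = pd.DataFrame(
        [
            {
                "feature_id": r["site_id"],
                "log2fc": r["log2fc"],
                "stat": 0.0,
                "pvalue": r.get("pvalue", 0.01),
                "adj_pvalue": r.get("pvalue", 0.01),
                "significant": r.get("significant", True),
                "direction": "up" if r["log2fc"] > 0 else "down",
            }
            for r in site_de
        ]
    )
    dp = pd.DataFrame(
        [
            {
                "feature_id": r["feature_id"],
                "log2fc": r["log2fc"],
                "stat": 0.0,
                "pvalue": r.get("pvalue", 0.01),
                "adj_pvalue": r.get("pvalue", 0.01),
                "significant": r.get("significant", False),
                "direction": r.get("direction", "none"),
            }
            for r in protein_de
        ]
    )
    return ds, dp, ann, site_mat, prot_mat


class TestClassifyRules:
    def _profiles(self, rng, shift):
        base = rng.normal(20, 0.2, 8)
        out = base.copy()
        out[4:] += shift
        return out

    def test_opposite_trend_is_degradative(self, design_4v4, rng):
        site = self._profiles(rng, 2.0)
        prot = self._profiles(rng, -1.0)
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "P1", "log2fc": 2.0}],
            [{"feature_id": "P1", "log2fc": -1.0, "significant": True, "direction": "down"}],
        )
        cls = classify_sites(ds, dp, ann, sm, pm)
        assert cls.loc[0, "class"] == "degradative"

    def test_flat_protein_site_is_non_degradative(self, design_4v4, rng):
        # the huge-FC site on a stable protein (the inhibitor-of-apoptosis
        # substrate pattern): protein log2fc ~ 0 and not significant
        site = self._profiles(rng, np.log2(407))
        prot = self._profiles(rng, 0.0)
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "P1", "log2fc": np.log2(407)}],
            [{"feature_id": "P1", "log2fc": 0.01, "significant": False}],
        )
        cls = classify_sites(ds, dp, ann, sm, pm)
        assert cls.loc[0, "class"] == "non_degradative"

    def test_same_sign_high_rho_removed_as_confounded(self, design_4v4, rng):
        prot = self._profiles(rng, 1.5)
        site = prot + 0.3  # copies the protein profile exactly: rho = 1
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "P1", "log2fc": 1.5}],
            [{"feature_id": "P1", "log2fc": 1.5, "significant": True, "direction": "up"}],
        )
        cls = classify_sites(ds, dp, ann, sm, pm)
        assert cls.loc[0, "class"] == "removed_confounded"
        assert cls.loc[0, "rho"] == pytest.approx(1.0)

    def test_same_sign_low_rho_survives_as_non_degradative(self, design_4v4, rng):
        prot = self._profiles(rng, 1.5)
        site = self._profiles(rng, 1.5)  # same trend, independent noise
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "P1", "log2fc": 1.5}],
            [{"feature_id": "P1", "log2fc": 1.5, "significant": True, "direction": "up"}],
        )
        cls = classify_sites(ds, dp, ann, sm, pm, ClassifyParams(rho_min=0.999))
        assert cls.loc[0, "class"] == "non_degradative"

    def test_unquantified_parent_gets_own_class(self, design_4v4, rng):
        site = self._profiles(rng, 2.0)
        prot = self._profiles(rng, 0.0)
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "MISSING", "log2fc": 2.0}],
            [{"feature_id": "P1", "log2fc": 0.0}],
        )
        cls = classify_sites(ds, dp, ann, sm, pm)
        assert cls.loc[0, "class"] == "protein_unquantified"
        assert np.isnan(cls.loc[0, "protein_log2fc"])

    def test_non_significant_sites_not_classified(self, design_4v4, rng):
        site = self._profiles(rng, 0.0)
        prot = self._profiles(rng, 0.0)
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "P1", "log2fc": 0.0, "significant": False}],
            [{"feature_id": "P1", "log2fc": 0.0}],
        )
        cls = classify_sites(ds, dp, ann, sm, pm)
        assert len(cls) == 0

    def test_orphan_annotation_rejected(self, design_4v4, rng):
        site = self._profiles(rng, 2.0)
        prot = self._profiles(rng, 0.0)
        ds, dp, ann, sm, pm = build_fixture(
            design_4v4,
            [site],
            [prot],
            [{"site_id": "S1", "protein_id": "P1", "log2fc": 2.0}],
            [{"feature_id": "P1", "log2fc": 0.0}],
        )
        with pytest.raises(ValueError, match="without annotation"):
            classify_sites(ds, dp, ann.drop("S1"), sm, pm)


class TestPartitionAndSymmetry:
    def _random_case(self, design, seed):
        from ubiflow import (
            DiffParams,
            OmicsSimConfig,
            PreprocessParams,
            annotations_frame,
            differential_expression,
            generate_omics,
            preprocess_matrix,
        )

        cfg = OmicsSimConfig(n_proteins=60, seed=seed)
        prot, ubi, anns, truth, design = generate_omics(cfg)
        pp = PreprocessParams(seed=seed)
        p2 = preprocess_matrix(prot, design, pp.max_missing_protein, pp)
        u2 = preprocess_matrix(ubi, design, pp.max_missing_peptide, pp)
        de_p = differential_expression(p2, design)
        de_u = differential_expression(u2, design)
        return de_u, de_p, annotations_frame(anns), u2, p2, design

    @given(seed=st.integers(0, 8))
    def test_classes_partition_significant_sites(self, seed):
        de_u, de_p, ann, u2, p2, design = self._random_case(None, seed)
        cls = classify_sites(de_u, de_p, ann, u2, p2)
        n_sig = int(de_u["significant"].sum())
        assert len(cls) == n_sig
        assert cls["site_id"].is_unique
        assert set(cls["class"]) <= set(CLASSES)
        summary = summarize_classification(cls)
        assert summary["n_sites"].sum() == n_sig

    def test_group_swap_leaves_classes_unchanged(self):
        from ubiflow import differential_expression

        de_u, de_p, ann, u2, p2, design = self._random_case(None, 3)
        cls = classify_sites(de_u, de_p, ann, u2, p2)
        sw = design.swapped()
        cls_sw = classify_sites(
            differential_expression(u2, sw),
            differential_expression(p2, sw),
            ann,
            u2,
            p2,
        )
        merged = cls.merge(cls_sw, on="site_id", suffixes=("", "_sw"))
        assert len(merged) == len(cls)
        assert (merged["class"] == merged["class_sw"]).all()

    def test_summary_counts_sites_and_distinct_proteins(self):
        table = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3"],
                "protein_id": ["pA", "pA", "pB"],
                "class": ["degradative"] * 3,
            }
        )
        summary = summarize_classification(table).set_index("class")
        assert summary.loc["degradative", "n_sites"] == 3
        assert summary.loc["degradative", "n_proteins"] == 2
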