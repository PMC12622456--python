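import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ubiflow import (
    EsiLibrary,
    aggregate_pairs,
    candidate_pairs,
    rank_retained,
    retain_modifying,
)


def diff_table(rows):
    return pd.DataFrame(
        [
            {
                "feature_id": fid,
                "log2fc": 1.0 if d == "up" else -1.0,
                "stat": 0.0,
                "pvalue": 0.01,
                "adj_pvalue": 0.01,
                "significant": sig,
                "direction": d if sig else "none",
            }
            for fid, d, sig in rows
        ]
    )


def ann_table(rows):
    return pd.DataFrame(
        [
            {"site_id": s, "protein_id": p, "position": 5, "is_ubiquitin_site": False}
            for s, p in rows
        ]
    ).set_index("site_id")


def library(rows):
    return EsiLibrary(
        pd.DataFrame(rows, columns=["enzyme_id", "enzyme_class", "substrate_id", "confidence"])
    )


class TestCandidatePairs:
    def test_ligase_substrate_triple_join(self):
        enz = diff_table([("XIAP", "up", True)])
        sites = diff_table([("Diablo_K212", "up", True)])
        ann = ann_table([("Diablo_K212", "Diablo")])
        lib = library([("XIAP", "E3", "Diablo", 0.9)])
        pairs = candidate_pairs(enz, sites, ann, lib)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert (row["enzyme_id"], row["substrate_id"], row["site_id"]) == (
            "XIAP", "Diablo", "Diablo_K212",
        )
        assert row["enzyme_direction"] == "up" and row["site_direction"] == "up"

    def test_enzyme_without_library_record_yields_nothing(self):
        enz = diff_table([("E1", "up", True)])
        sites = diff_table([("S1_K5", "up", True)])
        pairs = candidate_pairs(
            enz, sites, ann_table([("S1_K5", "S1")]), library([("OTHER", "E3", "S1", 0.5)])
        )
        assert pairs.empty

    def test_non_significant_parties_excluded(self):
        enz = diff_table([("E1", "up", False)])
        sites = diff_table([("S1_K5", "up", True)])
        pairs = candidate_pairs(
            enz, sites, ann_table([("S1_K5", "S1")]), library([("E1", "E3", "S1", 0.5)])
        )
        assert pairs.empty

    @given(seed=st.integers(0, 100))
    def test_matches_brute_force_triple_join(self, seed):
        rng = np.random.default_rng(seed)
        enzymes = [f"E{i}" for i in range(5)]
        substrates = [f"P{i}" for i in range(4)]
        enz = diff_table(
            [(e, rng.choice(["up", "down"]), bool(rng.random() < 0.7)) for e in enzymes]
        )
        site_rows, ann_rows = [], []
        for i in range(6):
            p = substrates[int(rng.integers(4))]
            sid = f"{p}_K{i + 1}"
            site_rows.append((sid, rng.choice(["up", "down"]), bool(rng.random() < 0.7)))
            ann_rows.append((sid, p))
        sites = diff_table(site_rows)
        ann = ann_table(ann_rows)
        lib_rows = []
        for _ in range(8):
            key = (
                enzymes[int(rng.integers(5))],
                rng.choice(["E3", "DUB"]),
                substrates[int(rng.integers(4))],
            )
            if any(r[:3] == key for r in lib_rows):
                continue
            lib_rows.append((*key, float(rng.uniform(0, 1))))
        lib = library(lib_rows)
        pairs = candidate_pairs(enz, sites, ann, lib)
        got = {
            (r.enzyme_id, r.enzyme_class, r.substrate_id, r.site_id)
            for r in pairs.itertuples()
        }
        # brute-force: loop every (library row, enzyme, site) combination
        expected = set()
        sig_enz = {r[0] for r in zip(enz["feature_id"], enz["significant"]) if r[1]}
        sig_enz = set(enz.loc[enz["significant"], "feature_id"])
        sig_sites = set(sites.loc[sites["significant"], "feature_id"])
        for le, lc, lsub, _conf in lib_rows:
            for e in sig_enz:
                if e != le:
                    continue
                for s in sig_sites:
                    if ann.loc[s, "protein_id"] == lsub:
                        expected.add((le, lc, lsub, s))
        assert got == expected


class TestRetention:
    @pytest.mark.parametrize(
        "enzyme_class,enzyme_dir,site_dir,kept",
        [
            ("E3", "up", "up", True),
            ("E3", "down", "down", True),
            ("E3", "up", "down", False),
            ("E3", "down", "up", False),
            ("DUB", "up", "down", True),
            ("DUB", "down", "up", True),
            ("DUB", "up", "up", False),
            ("DUB", "down", "down", False),
        ],
    )
    def test_catalysis_consistency_table(self, enzyme_class, enzyme_dir, site_dir, kept):
        pairs = pd.DataFrame(
            [
                {
                    "enzyme_id": "E", "enzyme_class": enzyme_class,
                    "substrate_id": "S", "site_id": "S_K1",
                    "enzyme_direction": enzyme_dir, "site_direction": site_dir,
                    "confidence": 0.5, "retained": False, "rank": pd.NA,
                }
            ]
        )
        assert bool(retain_modifying(pairs).loc[0, "retained"]) is kept

    @given(seed=st.integers(0, 100))
    def test_random_candidates_match_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        pairs = pd.DataFrame(
            {
                "enzyme_id": [f"E{i}" for i in range(n)],
                "enzyme_class": rng.choice(["E3", "DUB"], n),
                "substrate_id": [f"P{i}" for i in range(n)],
                "site_id": [f"P{i}_K1" for i in range(n)],
                "enzyme_direction": rng.choice(["up", "down"], n),
                "site_direction": rng.choice(["up", "down"], n),
                "confidence": rng.uniform(0, 1, n),
                "retained": False,
                "rank": pd.NA,
            }
        )
        out = retain_modifying(pairs)
        for r in out.itertuples():
            # independent re-statement: E3 tracks the site, DUB opposes it
            if r.enzyme_class == "E3":
                expect = r.enzyme_direction == r.site_direction
            else:
                expect = r.enzyme_direction != r.site_direction
            assert r.retained == expect


class TestRanking:
    def _pairs(self, confs, retained=None):
        n = len(confs)
        return pd.DataFrame(
            {
                "enzyme_id": [f"E{i}" for i in range(n)],
                "enzyme_class": ["E3"] * n,
                "substrate_id": [f"P{i}" for i in range(n)],
                "site_id": [f"P{i}_K1" for i in range(n)],
                "enzyme_direction": ["up"] * n,
                "site_direction": ["up"] * n,
                "confidence": confs,
                "retained": [True] * n if retained is None else retained,
                "rank": pd.NA,
            }
        )

    def test_ties_broken_lexicographically(self):
        out = rank_retained(self._pairs([0.7, 0.9, 0.7]))
        by_rank = out.sort_values("rank")
        assert list(by_rank["confidence"]) == [0.9, 0.7, 0.7]
        assert list(by_rank["enzyme_id"]) == ["E1", "E0", "E2"]
        assert list(by_rank["rank"]) == [1, 2, 3]

    def test_single_retained_pair_rank_one(self):
        out = rank_retained(self._pairs([0.4], retained=[True]))
        assert out.loc[0, "rank"] == 1

    def test_non_retained_pairs_unranked(self):
        out = rank_retained(self._pairs([0.9, 0.8], retained=[True, False]))
        assert out.loc[0, "rank"] == 1
        assert pd.isna(out.loc[1, "rank"])

    @given(seed=st.integers(0, 100))
    def test_ranking_invariant_under_input_order(self, seed):
        rng = np.random.default_rng(seed)
        pairs = self._pairs(list(rng.uniform(0, 1, 20)))
        ranked = rank_retained(pairs)
        shuffled = pairs.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        ranked2 = rank_retained(shuffled)
        a = ranked.set_index("enzyme_id")["rank"]
        b = ranked2.set_index("enzyme_id")["rank"]
        assert a.sort_index().equals(b.sort_index())

    def test_ranks_invariant_under_confidence_scaling(self):
        pairs = self._pairs([0.8, 0.2, 0.5])
        r1 = rank_retained(pairs).set_index("enzyme_id")["rank"]
        scaled = pairs.assign(confidence=pairs["confidence"] / 2.0)
        r2 = rank_retained(scaled).set_index("enzyme_id")["rank"]
        assert r1.equals(r2)

    def test_aggregate_keeps_best_rank_per_pair(self):
        pairs = self._pairs([0.9, 0.9, 0.3])
        pairs.loc[1, ["enzyme_id", "substrate_id", "site_id"]] = ["E0", "P0", "P0_K2"]
        out = aggregate_pairs(rank_retained(pairs))
        assert len(out) == 2
        top = out.iloc[0]
        assert (top["enzyme_id"], top["substrate_id"]) == ("E0", "P0")
        assert top["n_sites"] == 2 and top["best_rank"] == 1
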