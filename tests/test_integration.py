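import numpy as np
import pandas as pd
import pytest

from methlink.integration import (
    PUBLISHED_LINK_TABLE,
    collect_dmgs,
    common_dmgs,
    dmg_histogram,
    dmgs_to_frame,
    dose_consistency,
    expectation_regression,
    export_tables,
    link_deg_dmc,
    merge_common_dmcs,
    rank_top_dmgs,
)


def _dmc(site, region, genes, diff=40.0, q=1e-3, sublabel=""):
    return {
        "site": site,
        "region": region,
        "sublabel": sublabel,
        "gene_ids": genes,
        "diff": diff,
        "q": q,
        "p": q / 10,
        "direction": "hyper" if diff > 0 else "hypo",
    }


def _dmcs(rows):
    return pd.DataFrame(
        rows,
        columns=["site", "region", "sublabel", "gene_ids", "diff", "q", "p",
                 "direction"],
    )


class TestCollectDmgs:
    def test_single_exon_dmc_composite_groups(self):
        dmgs = collect_dmgs(_dmcs([_dmc("chr1:10", "EXON", "g1")]), "L2:L1")
        assert len(dmgs) == 1
        assert set(dmgs[0].region_groups) == {"exon", "GB", "P+GB", "RS+GB"}
        assert dmgs[0].n_dmcs == 1

    def test_p250_and_intron_union(self):
        dmgs = collect_dmgs(
            _dmcs([_dmc("chr1:10", "P250", "g1"),
                   _dmc("chr1:50", "INTRON", "g1")]),
            "L2:L1",
        )
        (d,) = dmgs
        assert set(d.region_groups) == {
            "P250", "P", "intron", "GB", "P+GB", "RS+GB"
        }
        assert d.n_dmcs == 2

    def test_igr_contributes_nothing(self):
        assert collect_dmgs(_dmcs([_dmc("chr1:10", "IGR", "")]), "x") == []

    def test_composite_consistency_invariant(self):
        dmgs = collect_dmgs(
            _dmcs([_dmc("chr1:10", "P250", "g1"),
                   _dmc("chr1:20", "FLANK", "g2"),
                   _dmc("chr1:30", "P1K", "g3,g4")]),
            "x",
        )
        for d in dmgs:
            groups = set(d.region_groups)
            if "P250" in groups or "P1K" in groups or "P5K" in groups:
                assert {"P", "P+GB", "RS+GB"} <= groups
            if "flanks" in groups:
                assert "RS+GB" in groups

    def test_multi_gene_credit(self):
        dmgs = collect_dmgs(_dmcs([_dmc("chr1:10", "EXON", "g1,g2")]), "x")
        assert [d.gene_id for d in dmgs] == ["g1", "g2"]

    def test_histogram_buckets(self):
        dmgs = collect_dmgs(
            _dmcs([_dmc(f"chr1:{i}", "EXON", "g1") for i in (1, 3, 5)]
                  + [_dmc("chr1:7", "EXON", "g2")]),
            "x",
        )
        h = dmg_histogram(dmgs).set_index("region_group")
        assert h.loc["exon", "dmgs_3plus"] == 1
        assert h.loc["exon", "dmgs_1"] == 1


class TestMergeCommonDmcs:
    def test_matched_direction_kept(self):
        a = _dmcs([_dmc("chr1:10", "EXON", "g1", diff=40)])
        b = _dmcs([_dmc("chr1:10", "EXON", "g1", diff=30)])
        out = merge_common_dmcs(a, b)
        assert list(out["site"]) == ["chr1:10"]
        assert out["q_min"][0] == pytest.approx(1e-3)

    def test_opposite_direction_dropped(self):
        a = _dmcs([_dmc("chr1:10", "EXON", "g1", diff=40)])
        b = _dmcs([_dmc("chr1:10", "EXON", "g1", diff=-40)])
        assert merge_common_dmcs(a, b).empty

    def test_site_only_in_one_dropped_and_self_merge(self):
        a = _dmcs([_dmc("chr1:10", "EXON", "g1"),
                   _dmc("chr1:20", "IGR", ""),
                   _dmc("chr1:30", "P250", "g2")])
        out = merge_common_dmcs(a, a)
        assert list(out["site"]) == ["chr1:10", "chr1:30"]  # IGR removed

    def test_commutative_up_to_field_swap(self):
        a = _dmcs([_dmc("chr1:10", "EXON", "g1", diff=40, q=1e-3)])
        b = _dmcs([_dmc("chr1:10", "EXON", "g1", diff=30, q=1e-4)])
        ab, ba = merge_common_dmcs(a, b), merge_common_dmcs(b, a)
        assert list(ab["site"]) == list(ba["site"])
        assert ab["diff_a"][0] == ba["diff_b"][0]
        assert ab["q_min"][0] == ba["q_min"][0]

    def test_exon150_sublabel_drives_region_name(self):
        a = _dmcs([_dmc("chr1:10", "EXON", "g1", sublabel="EXON150")])
        out = merge_common_dmcs(a, a)
        assert out["region_name"][0] == "Exon150"


class TestRankTopDmgs:
    def _cdmg(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "region_name", "n_dmcs", "q_min",
                           "n_hypo", "n_hyper"]
        )

    def test_sort_key_chain(self):
        cdmg = self._cdmg(
            [("gD", "P250", 1, 1e-5, 1, 0),
             ("gB", "P250", 2, 1e-4, 2, 0),
             ("gC", "P250", 2, 1e-4, 2, 0),
             ("gA", "P250", 3, 1e-2, 3, 0)]
        )
        top = rank_top_dmgs(cdmg, k=3)
        assert list(top["gene"]) == ["gA", "gB", "gC"]

    def test_fewer_than_k_returns_all(self):
        cdmg = self._cdmg([("g1", "P1K", 1, 1e-3, 1, 0),
                           ("g2", "P1K", 1, 1e-3, 1, 0)])
        assert len(rank_top_dmgs(cdmg, k=3)) == 2

    def test_empty_region_empty_list(self):
        assert rank_top_dmgs(self._cdmg([])).empty


class TestLinkDegDmc:
    def _degs(self, genes):
        return pd.DataFrame(
            {"gene": list(genes), "lfc": [1.0] * len(genes),
             "padj": [0.01] * len(genes)}
        )

    def test_intersection_example(self):
        degs = {("gonads", "L2:L1"): self._degs(["g1", "g2"])}
        dmcs = {("gonads", "L2:L1"): _dmcs(
            [_dmc("chr1:10", "EXON", "g2"), _dmc("chr1:20", "EXON", "g3")]
        )}
        counts, details = link_deg_dmc(degs, dmcs)
        assert counts.iloc[0]["n_link"] == 1
        assert list(details["gene"]) == ["g2"]

    def test_18_rows_for_three_by_three_by_two(self):
        degs, dmcs = {}, {}
        for scope in ("gonads", "liver", "G&L"):
            for c in ("L2:L1", "L3:L1"):
                degs[(scope, c)] = self._degs(["g1"])
                dmcs[(scope, c)] = _dmcs([_dmc("chr1:10", "EXON", "g1")])
        counts, _ = link_deg_dmc(degs, dmcs)
        assert len(counts) == 18

    def test_disjoint_sets_zero_links(self):
        degs = {("gonads", "L2:L1"): self._degs(["g1"])}
        dmcs = {("gonads", "L2:L1"): _dmcs([_dmc("chr1:10", "EXON", "g9")])}
        counts, details = link_deg_dmc(degs, dmcs)
        assert counts.iloc[0]["n_link"] == 0 and details.empty

    def test_link_bounded_by_deg_and_dmg(self):
        rng = np.random.default_rng(0)
        degs, dmcs = {}, {}
        pool = [f"g{i}" for i in range(30)]
        for scope in ("gonads", "liver"):
            for c in ("L2:L1", "L3:L1"):
                degs[(scope, c)] = self._degs(
                    rng.choice(pool, size=rng.integers(1, 20), replace=False)
                )
                dmcs[(scope, c)] = _dmcs(
                    [_dmc(f"chr1:{i}", "EXON", g)
                     for i, g in enumerate(
                         rng.choice(pool, size=rng.integers(1, 20),
                                    replace=False))]
                )
        counts, _ = link_deg_dmc(degs, dmcs)
        assert (counts["n_link"]
                <= counts[["n_deg", "n_dmg"]].min(axis=1)).all()


class TestExpectationRegression:
    def test_perfect_proportionality(self):
        links = pd.DataFrame(
            {"n_link": [1, 2, 3, 4, 5], "n_deg": [10, 20, 30, 40, 50],
             "n_dmg": [7, 13, 5, 9, 21]}
        )
        adj_r2, p, _ = expectation_regression(links)
        assert adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(0)
        links = pd.DataFrame(
            {"n_link": rng.integers(1, 50, 18),
             "n_deg": rng.integers(1, 400, 18),
             "n_dmg": rng.integers(1, 9000, 18)}
        )
        adj_r2, _, _ = expectation_regression(links)
        assert adj_r2 < 0.35

    def test_published_counts_reproduce_083(self):
        adj_r2, p, _ = expectation_regression(PUBLISHED_LINK_TABLE)
        assert round(adj_r2, 2) == 0.83
        assert p == pytest.approx(7.1e-7, abs=0.05e-7)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least 4"):
            expectation_regression(PUBLISHED_LINK_TABLE.head(3))

    def test_zero_variance_predictor(self):
        links = pd.DataFrame(
            {"n_link": [1, 2, 3, 4], "n_deg": [5, 5, 5, 5],
             "n_dmg": [1, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            expectation_regression(links)


class TestDoseConsistency:
    def _frame(self, key, effects, sig=None):
        n = len(effects)
        return pd.DataFrame(
            {key: [f"x{i}" for i in range(n)],
             "lfc" if key == "gene" else "diff": effects,
             "significant": sig if sig is not None else [True] * n}
        )

    def test_identical_vectors(self):
        a = self._frame("gene", [1.0, 2.0, 3.0, -1.0])
        out = dose_consistency(a, a.copy())
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)

    def test_negated_vectors(self):
        a = self._frame("gene", [1.0, 2.0, 3.0, -1.0])
        b = a.copy()
        b["lfc"] = -b["lfc"]
        assert dose_consistency(a, b)["pearson_r"] == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(1)
        n = 500
        shared = rng.normal(size=n)
        rho = 0.8
        x = shared
        y = rho * shared + np.sqrt(1 - rho**2) * rng.normal(size=n)
        a = self._frame("site", x)
        a["diff"] = x
        b = self._frame("site", y)
        b["diff"] = y
        r = dose_consistency(a, b, mode="methylation")["pearson_r"]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_union_rule_requires_one_significant(self):
        a = self._frame("gene", [1.0, 2.0, 3.0, 4.0],
                        sig=[True, False, False, True])
        b = self._frame("gene", [1.0, 2.0, 3.0, 4.0],
                        sig=[False, False, True, False])
        out = dose_consistency(a, b)
        assert out["n_pairs"] == 3

    def test_too_few_pairs(self):
        a = self._frame("gene", [1.0, 2.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            dose_consistency(a, a.copy())


class TestExportTables:
    def _results(self):
        empty_dmcs = _dmcs([])
        degs = pd.DataFrame(
            {"gene": ["g1"], "lfc": [1.5], "padj": [0.05]}
        )
        link_cols = ["deg_dataset", "dmc_dataset", "contrast", "gene", "lfc",
                     "n_dmcs", "dmc_sites", "regions"]
        return {
            "degs_l2": degs,
            "degs_l3": degs,
            "cpgs_l2": _dmcs([_dmc("chr1:10", "EXON", "g1")]),
            "cpgs_l3": empty_dmcs,
            "dmcs_region_l2": pd.DataFrame(columns=["region", "hypo", "hyper"]),
            "dmcs_region_l3": pd.DataFrame(columns=["region", "hypo", "hyper"]),
            "dmgs_l2": dmgs_to_frame([]),
            "dmgs_l3": dmgs_to_frame([]),
            "links_gonads": pd.DataFrame(columns=link_cols),
            "links_liver": pd.DataFrame(columns=link_cols),
            "links_gl": pd.DataFrame(columns=link_cols),
            "common_dmcs": empty_dmcs,
            "common_dmgs": pd.DataFrame(columns=["gene", "region_name"]),
        }

    def test_thirteen_files_written(self, tmp_path):
        paths = export_tables(self._results(), tmp_path / "tables")
        assert len(paths) == 13
        for p in paths:
            assert open(p).readline().strip()  # header present

    def test_missing_result_names_file(self, tmp_path):
        results = self._results()
        del results["common_dmgs"]
        with pytest.raises(ValueError, match="13_common_dmgs.tsv"):
            export_tables(results, tmp_path / "tables")

    def test_rerun_byte_identical(self, tmp_path):
        r = self._results()
        paths1 = export_tables(r, tmp_path / "a")
        paths2 = export_tables(r, tmp_path / "b")
        for p1, p2 in zip(paths1, paths2):
            assert open(p1, "rb").read() == open(p2, "rb").read()
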