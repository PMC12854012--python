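import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from clonebridge import (
    classify_concordance,
    classify_potential_trm,
    classify_trm_clusters,
    concordance_summary,
    concordance_table,
    confirm_trm,
    preranked_gsea,
    rank_sum_de,
    robust_marker_filter,
    shared_vs_nonshared_de,
    trm_marker_signature,
)
from clonebridge.datamodel import ExpressionMatrix, GeneSignature, MetaClusterMap, TrmDecision
from clonebridge.simulate import SimConfig, core_trm_signature, simulate_expression


def _matrix_from_groups(a_vals, b_vals):
    values = np.array([list(a_vals) + list(b_vals)], dtype=float)
    cells = [f"a{i}" for i in range(len(a_vals))] + [f"b{i}" for i in range(len(b_vals))]
    m = ExpressionMatrix(genes=["G1"], cells=cells, values=values)
    return m, cells[: len(a_vals)], cells[len(a_vals):]


def ranksum_enumeration_oracle(a_vals, b_vals):
    """Exact two-sided rank-sum p by brute-force enumeration of assignments."""
    pooled = np.array(list(a_vals) + list(b_vals), dtype=float)
    na, n = len(a_vals), len(pooled)
    ranks = rankdata(pooled)
    mu = na * (n + 1) / 2
    w_obs = ranks[:na].sum()
    hits = total = 0
    for idx in itertools.combinations(range(n), na):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestRankSumDE:
    def test_separated_small_groups_give_exact_p(self):
        """Groups {1,2,3} vs {4,5,6}: only 2 of the 20 assignments are as
        extreme, so the exact two-sided p is 0.1."""
        m, a, b = _matrix_from_groups([1, 2, 3], [4, 5, 6])
        de = rank_sum_de(m, a, b, min_pct=0.0, min_lfc=0.0)
        assert de.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)

    def test_groups_below_three_warn_but_stay_exact(self):
        m, a, b = _matrix_from_groups([1, 2], [4, 5, 6])
        with pytest.warns(UserWarning, match="exact enumeration"):
            de = rank_sum_de(m, a, b, min_pct=0.0, min_lfc=0.0)
        # C(5,2)=10 assignments, only {1,2} is as extreme on both sides -> 2/10
        assert de.loc[0, "p"] == pytest.approx(0.2, abs=1e-12)

    def test_identical_groups_give_zero_lfc_p_one(self):
        m, a, b = _matrix_from_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        de = rank_sum_de(m, a, b, min_pct=0.0, min_lfc=0.0)
        assert de.loc[0, "lfc"] == 0.0
        assert de.loc[0, "p"] == 1.0

    def test_adjusted_p_never_below_raw_p(self, small_matrix):
        de = rank_sum_de(small_matrix, ["c0", "c1", "c2"], ["c3", "c4", "c5"],
                         min_pct=0.0, min_lfc=0.0)
        assert (de["adj_p"] >= de["p"] - 1e-15).all()
        assert de["pct_a"].between(0, 1).all() and de["pct_b"].between(0, 1).all()

    def test_prefilter_limits_tested_genes(self, small_matrix):
        de = rank_sum_de(small_matrix, ["c0", "c1", "c2"], ["c3", "c4", "c5"],
                         min_pct=0.1, min_lfc=0.5)
        assert set(de["gene"]) == {"GENEA"}

    def test_asymptotic_path_matches_scipy(self):
        rng = np.random.default_rng(42)
        values = rng.normal(1, 0.5, size=(20, 40))
        m = ExpressionMatrix(genes=[f"g{i}" for i in range(20)],
                             cells=[f"c{i}" for i in range(40)], values=np.abs(values))
        a, b = m.cells[:18], m.cells[18:]
        de = rank_sum_de(m, a, b, min_pct=0.0, min_lfc=0.0).set_index("gene")
        for i, g in enumerate(m.genes):
            ref = mannwhitneyu(values.__abs__()[i, :18], np.abs(values)[i, 18:],
                               method="asymptotic", use_continuity=True)
            assert de.at[g, "p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_disjointness_enforced(self, small_matrix):
        with pytest.raises(ValueError, match="disjoint"):
            rank_sum_de(small_matrix, ["c0", "c1", "c2"], ["c2", "c3", "c4"])


class TestRobustMarkerFilter:
    def _tables(self, per_patient):
        """per_patient: list of (lfc, adj_p) for gene GX, one per patient."""
        return [
            pd.DataFrame({"gene": ["GX"], "lfc": [l], "p": [p], "adj_p": [p]})
            for l, p in per_patient
        ]

    def test_three_of_five_same_direction_kept(self):
        tables = self._tables([(1, 0.01), (1, 0.01), (1, 0.04), (1, 0.5), (-0.1, 0.9)])
        out = robust_marker_filter(tables, k=3)
        assert list(out["gene"]) == ["GX"] and out.loc[0, "direction"] == "up"

    def test_two_of_five_dropped(self):
        tables = self._tables([(1, 0.01), (1, 0.01), (1, 0.5), (1, 0.5), (1, 0.9)])
        assert robust_marker_filter(tables, k=3).empty

    def test_opposing_directions_dropped(self):
        tables = self._tables([(1, 0.01), (1, 0.01), (1, 0.01), (-1, 0.01), (1, 0.5)])
        assert robust_marker_filter(tables, k=3).empty

    def test_fisher_mode_combines_pvalues(self):
        tables = self._tables([(1, 0.02), (0.8, 0.03), (1.2, 0.04), (0.9, 0.06), (1, 0.07)])
        out = robust_marker_filter(tables, k=3, method="fisher")
        assert list(out["gene"]) == ["GX"] and out.loc[0, "direction"] == "up"


class TestPotentialTrmRule:
    def _de(self, up_sig, down_sig):
        rows = []
        for g in ["ITGAE", "CD69", "CXCR6", "ITGA1", "PDCD1"]:
            rows.append({"gene": g, "lfc": 1.0, "adj_p": 0.001 if g in up_sig else 0.9})
        for g in ["S1PR1", "SELL", "KLF2"]:
            rows.append({"gene": g, "lfc": -1.0, "adj_p": 0.001 if g in down_sig else 0.9})
        return pd.DataFrame(rows)

    def test_two_up_one_down_is_potential(self):
        d = classify_potential_trm(self._de({"ITGAE", "CXCR6"}, {"S1PR1"}))
        assert d.potential and d.marker_hits_up == {"ITGAE", "CXCR6"}

    def test_three_up_no_down_is_not_potential(self):
        d = classify_potential_trm(self._de({"ITGAE", "CXCR6", "ITGA1"}, set()))
        assert not d.potential

    def test_two_total_hits_below_threshold(self):
        d = classify_potential_trm(self._de({"ITGAE"}, {"SELL"}))
        assert not d.potential

    def test_absent_signature_gene_counts_as_non_hit(self):
        de = self._de({"ITGAE", "CXCR6"}, {"S1PR1"})
        de = de[de["gene"] != "CXCR6"]
        assert not classify_potential_trm(de).potential


class TestPrerankedGsea:
    def test_singleton_top_gene_reaches_es_one(self):
        res = preranked_gsea(["a", "b", "c", "d"], [3.0, 2.0, 1.0, 0.5], {"a"},
                             weight=1.0, n_perm=200, rng=np.random.default_rng(0))
        assert res.es == pytest.approx(1.0)

    def test_bottom_gene_set_has_negative_es(self):
        res = preranked_gsea(["a", "b", "c", "d"], [3.0, 2.0, 1.0, 0.5], {"d"},
                             n_perm=200, rng=np.random.default_rng(0))
        assert res.es < 0

    def test_set_equal_to_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            preranked_gsea(["a", "b"], [1.0, 0.5], {"a", "b"})

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            preranked_gsea(["a", "b"], [1.0, 0.5], {"zzz"})

    def test_complement_set_flips_es_sign_at_weight_zero(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        stats = rng.normal(size=30)
        gene_set = set(rng.choice(genes, size=8, replace=False))
        es1 = preranked_gsea(genes, stats, gene_set, weight=0.0, n_perm=10,
                             rng=np.random.default_rng(0)).es
        es2 = preranked_gsea(genes, stats, set(genes) - gene_set, weight=0.0, n_perm=10,
                             rng=np.random.default_rng(0)).es
        assert es1 == pytest.approx(-es2, abs=1e-12)

    def test_p_in_unit_interval_and_positive(self):
        rng = np.random.default_rng(1)
        res = preranked_gsea([f"g{i}" for i in range(50)], rng.normal(size=50),
                             {f"g{i}" for i in range(5)}, n_perm=99,
                             rng=np.random.default_rng(2))
        assert 0 < res.p <= 1


class TestTwoStageClassifier:
    def test_planted_trm_cluster_confirmed(self):
        cfg = SimConfig(seed=21, trm_delta=1.0, n_trm_clusters=1, n_other_clusters=3,
                        cells_per_cluster=150)
        m, clusters, truth = simulate_expression(cfg, np.random.default_rng(21))
        dec = classify_trm_clusters(m, clusters, core_trm_signature(), n_perm=199,
                                    rng=np.random.default_rng(22))
        assert {cl for cl, d in dec.items() if d.confirmed} == truth.trm_clusters

    def test_stage_order_violation_raises(self, small_matrix):
        bad = TrmDecision(cluster_id="x", potential=False)
        with pytest.raises(ValueError, match="stage order"):
            confirm_trm(small_matrix, ["c0"], ["c1"], core_trm_signature(), bad)


class TestConcordance:
    def test_definition_examples(self):
        assert classify_concordance(["Trm"], ["Trm"]) == "same"
        assert classify_concordance(["Trm", "GZMK+"], ["GZMK+"]) == "similar"
        assert classify_concordance(["Trm"], ["Tcm"]) == "different"

    def test_invariant_to_order_and_duplication(self):
        a, b = ["Trm", "GZMK+", "Trm"], ["GZMK+", "GZMK+"]
        assert classify_concordance(a, b) == classify_concordance(a * 3, list(reversed(b)))

    def test_empty_compartment_raises(self):
        with pytest.raises(ValueError):
            classify_concordance([], ["Trm"])

    def test_summary_fractions_sum_to_one(self):
        s = concordance_summary(["same", "similar", "different"])
        assert s == {"same": pytest.approx(1 / 3), "similar": pytest.approx(1 / 3),
                     "different": pytest.approx(1 / 3)}
        assert concordance_summary(["same", "same"]) == {"same": 1.0, "similar": 0.0,
                                                         "different": 0.0}

    @given(st.lists(st.sampled_from(["same", "similar", "different"]), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_summary_always_sums_to_one(self, classes):
        assert sum(concordance_summary(classes).values()) == pytest.approx(1.0, abs=1e-12)

    def test_unmapped_cluster_raises(self, paired_cell_factory):
        from clonebridge import build_chain_profiles, call_clones, find_shared_clones, pool_joint
        from tests.conftest import make_contig, make_meta

        contigs, meta = paired_cell_factory(
            [("c1", "skin", "TGTGCAGCAAAA", "TGTGCCAGCTTT"),
             ("c2", "ST", "TGTGCAGCAAAA", "TGTGCCAGCTTT")]
        )
        meta = [make_meta(m.barcode, compartment=m.compartment, cluster="mystery") for m in meta]
        t = pool_joint(call_clones(build_chain_profiles(contigs), meta))
        shared = find_shared_clones(t)
        mm = MetaClusterMap(lineage="CD8", mapping={"known": "Trm"})
        comps = {m.barcode: "skin" if m.compartment == "skin" else "joint" for m in meta}
        with pytest.raises(KeyError, match="mystery"):
            concordance_table(t, shared, {m.barcode: "mystery" for m in meta}, mm, comps)


class TestSharedVsNonsharedDE:
    def test_planted_cytotoxic_shift_ranks_top(self):
        cfg = SimConfig(seed=31, n_trm_clusters=1, n_other_clusters=2, cells_per_cluster=100,
                        shared_effect_delta=1.5)
        m0, clusters, _ = simulate_expression(cfg, np.random.default_rng(31))
        shared = set(list(m0.cells)[:80])
        m, _, _ = simulate_expression(cfg, np.random.default_rng(31), shared_barcodes=shared)
        nonshared = [c for c in m.cells if c not in shared]
        de = shared_vs_nonshared_de(m, sorted(shared), nonshared)
        top = set(de.head(6)["gene"])
        assert {"GZMB", "GZMH", "GNLY", "PRF1", "NKG7"} <= top

    def test_empty_group_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="empty"):
            shared_vs_nonshared_de(small_matrix, [], ["c0"])
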