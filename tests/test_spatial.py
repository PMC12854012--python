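import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clonebridge import build_contact_graph, composition_edges, contact_enrichment
from clonebridge.simulate import SimConfig, simulate_spatial


def _cells(rows):
    return pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "fov", "cell_type"])


def _triangle(side, fov="F1", types=("A", "A", "A")):
    h = side * math.sqrt(3) / 2
    return _cells(
        [
            ("t1", 0.0, 0.0, fov, types[0]),
            ("t2", side, 0.0, fov, types[1]),
            ("t3", side / 2, h, fov, types[2]),
        ]
    )


class TestContactGraph:
    def test_equilateral_triangle_under_cap_gives_three_edges(self):
        smap = build_contact_graph(_triangle(20.0), cap_um=30.0)
        assert len(smap.edges) == 3

    def test_triangle_over_cap_gives_no_edges(self):
        smap = build_contact_graph(_triangle(50.0), cap_um=30.0)
        assert len(smap.edges) == 0

    def test_no_cross_fov_edges(self):
        cells = _cells([("a", 0.0, 0.0, "F1", "A"), ("b", 1.0, 0.0, "F2", "A")])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smap = build_contact_graph(cells, cap_um=30.0)
        assert len(smap.edges) == 0

    def test_collinear_points_fall_back_to_radius(self):
        cells = _cells([(f"c{i}", 10.0 * i, 0.0, "F1", "A") for i in range(4)])
        with pytest.warns(UserWarning, match="radius"):
            smap = build_contact_graph(cells, cap_um=15.0, radius_um=15.0)
        assert len(smap.edges) == 3  # the path graph

    def test_knn_and_radius_methods(self):
        cells = _triangle(10.0)
        assert len(build_contact_graph(cells, method="radius", radius_um=15.0).edges) == 3
        assert len(build_contact_graph(cells, method="knn", k=1).edges) >= 1


def enrichment_exhaustive_oracle(cells, edges):
    """Brute-force within-fov label permutation null, counted exhaustively."""
    types = sorted(cells["cell_type"].unique())
    code = {t: i for i, t in enumerate(types)}
    labels = cells["cell_type"].map(code).to_numpy()
    fovs = cells["fov"].to_numpy()
    fov_groups = [np.flatnonzero(fovs == f) for f in pd.unique(fovs)]

    def pair_counts(lab):
        out = {}
        for i, j in edges:
            a, b = sorted((lab[i], lab[j]))
            out[(a, b)] = out.get((a, b), 0) + 1
        return out

    obs = pair_counts(labels)
    per_fov = [sorted(set(itertools.permutations(labels[idx]))) for idx in fov_groups]
    total = 0
    ge = {}
    for combo in itertools.product(*per_fov):
        lab = labels.copy()
        for idx, labeling in zip(fov_groups, combo):
            lab[idx] = labeling
        total += 1
        cnt = pair_counts(lab)
        for a in range(len(types)):
            for b in range(a, len(types)):
                if cnt.get((a, b), 0) >= obs.get((a, b), 0):
                    ge[(a, b)] = ge.get((a, b), 0) + 1
    return {
        (types[a], types[b]): (1 + ge.get((a, b), 0)) / (1 + total)
        for a in range(len(types))
        for b in range(a, len(types))
    }


class TestContactEnrichment:
    def test_single_type_map_gives_p_one(self):
        smap = build_contact_graph(_triangle(10.0), cap_um=30.0)
        enr = contact_enrichment(smap, n_perm=100, rng=np.random.default_rng(0))
        assert (enr["p"] == 1.0).all()

    def test_path_graph_matches_hand_enumeration(self):
        """4 cells on a line labeled A,A,B,B: of the 6 distinct labelings,
        exactly 3 (AABB, BAAB, BBAA) have an A-A adjacency >= the observed
        one, so the smoothed upper-tail p is (1+3)/(1+6)."""
        cells = _cells(
            [("c1", 0.0, 0.0, "F1", "A"), ("c2", 10.0, 0.0, "F1", "A"),
             ("c3", 20.0, 0.0, "F1", "B"), ("c4", 30.0, 0.0, "F1", "B")]
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smap = build_contact_graph(cells, cap_um=15.0, radius_um=15.0)
        enr = contact_enrichment(smap, exhaustive=True).set_index(["type_a", "type_b"])
        oracle = enrichment_exhaustive_oracle(cells, smap.edges)
        for pair, p in oracle.items():
            assert enr.at[pair, "p"] == pytest.approx(p, abs=1e-12)
        assert enr.at[("A", "A"), "p"] == pytest.approx((1 + 3) / (1 + 6))

    def test_exhaustive_oracle_equality_on_random_small_maps(self):
        rng = np.random.default_rng(5)
        for trial in range(12):
            n = int(rng.integers(4, 9))
            n_fov = int(rng.integers(1, 3))
            rows = []
            for i in range(n):
                rows.append(
                    (f"c{i}", float(rng.uniform(0, 40)), float(rng.uniform(0, 40)),
                     f"F{int(rng.integers(n_fov)) + 1}", "AB"[int(rng.integers(2))])
                )
            cells = _cells(rows)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                smap = build_contact_graph(cells, method="radius", radius_um=25.0)
            enr = contact_enrichment(smap, exhaustive=True).set_index(["type_a", "type_b"])
            for pair, p in enrichment_exhaustive_oracle(cells, smap.edges).items():
                assert enr.at[pair, "p"] == pytest.approx(p, abs=1e-12), (trial, pair)

    def test_observed_counts_symmetric_and_p_positive(self):
        cfg = SimConfig(seed=9, attraction={("CD8_Trm", "Macrophage"): 0.5})
        cells, _ = simulate_spatial(cfg, np.random.default_rng(9))
        smap = build_contact_graph(cells)
        enr = contact_enrichment(smap, n_perm=199, rng=np.random.default_rng(10))
        assert (enr["p"] > 0).all() and (enr["p"] <= 1).all()
        assert (enr["observed"] >= 0).all()

    def test_planted_attraction_detected(self):
        cfg = SimConfig(seed=13, attraction={("CD8_Trm", "Macrophage"): 0.6})
        cells, _ = simulate_spatial(cfg, np.random.default_rng(13))
        smap = build_contact_graph(cells)
        enr = contact_enrichment(smap, n_perm=999, rng=np.random.default_rng(14))
        row = enr[(enr["type_a"] == "CD8_Trm") & (enr["type_b"] == "Macrophage")]
        assert float(row["p"].iloc[0]) < 0.01

    def test_fixed_seed_is_reproducible(self):
        cfg = SimConfig(seed=9)
        cells, _ = simulate_spatial(cfg, np.random.default_rng(9))
        smap = build_contact_graph(cells)
        a = contact_enrichment(smap, n_perm=199, rng=np.random.default_rng(3))
        b = contact_enrichment(smap, n_perm=199, rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)


class TestCompositionEdges:
    def _star(self, center_type="B", leaf_types=("A", "A", "C", "C")):
        rows = [("center", 0.0, 0.0, "F1", center_type)]
        for i, t in enumerate(leaf_types):
            ang = 2 * math.pi * i / len(leaf_types)
            rows.append((f"leaf{i}", 10 * math.cos(ang), 10 * math.sin(ang), "F1", t))
        return _cells(rows)

    def test_half_of_neighbors_gives_edge(self):
        cells = self._star()
        smap = build_contact_graph(cells, method="radius", radius_um=12.0)
        edges = composition_edges(smap, threshold=0.05)
        ab = edges[(edges["src"] == "A") & (edges["dst"] == "B")]
        assert ab["fraction"].iloc[0] == pytest.approx(0.5)

    def test_zero_fraction_no_edge_and_inclusive_threshold(self):
        cells = self._star(leaf_types=("A", "A", "A", "A"))
        smap = build_contact_graph(cells, method="radius", radius_um=12.0)
        edges = composition_edges(smap, threshold=0.05)
        assert edges[(edges["src"] == "C")].empty  # C absent entirely
        # exactly at threshold: A is 100% of B's neighbors; B is 1/1 of each A's
        exact = composition_edges(smap, threshold=1.0)
        assert not exact[(exact["src"] == "A") & (exact["dst"] == "B")].empty

    def test_isolated_type_has_no_edges(self):
        cells = _cells(
            [("a", 0.0, 0.0, "F1", "A"), ("b", 10.0, 0.0, "F1", "A"),
             ("far", 500.0, 500.0, "F1", "C")]
        )
        smap = build_contact_graph(cells, method="radius", radius_um=15.0)
        edges = composition_edges(smap)
        assert edges[(edges["src"] == "C") | (edges["dst"] == "C")].empty
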