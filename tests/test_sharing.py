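import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonebridge import (
    build_chain_profiles,
    call_clones,
    diversity_table,
    find_shared_clones,
    inverse_pielou,
    occupancy,
    pool_joint,
    sharing_summary,
)

TRA1, TRB1 = "TGTGCAGCAAAA", "TGTGCCAGCTTT"
TRA2, TRB2 = "TGTGCAGCACCC", "TGTGCCAGCGGG"


def _pooled_table(build, cells):
    contigs, meta = build(cells)
    return pool_joint(call_clones(build_chain_profiles(contigs), meta))


class TestFindSharedClones:
    def test_skin_joint_clone_shared_not_triple(self, paired_cell_factory):
        t = _pooled_table(
            paired_cell_factory,
            [("c1", "skin", TRA1, TRB1), ("c2", "ST", TRA1, TRB1), ("c3", "ST", TRA1, TRB1)],
        )
        shared = find_shared_clones(t)
        assert len(shared.clones) == 1
        assert shared.clones[0].sizes == {"skin": 1, "joint": 2}
        assert not shared.clones[0].triple

    def test_blood_presence_marks_triple(self, paired_cell_factory):
        t = _pooled_table(
            paired_cell_factory,
            [("c1", "skin", TRA1, TRB1), ("c2", "SF", TRA1, TRB1), ("c3", "blood", TRA1, TRB1)],
        )
        (clone,) = find_shared_clones(t).clones
        assert clone.triple

    def test_single_compartment_clone_not_shared(self, paired_cell_factory):
        t = _pooled_table(paired_cell_factory, [(f"c{i}", "skin", TRA1, TRB1) for i in range(4)])
        assert find_shared_clones(t).clones == []

    def test_unknown_compartment_raises(self, paired_cell_factory):
        t = _pooled_table(paired_cell_factory, [("c1", "skin", TRA1, TRB1)])
        with pytest.raises(ValueError, match="unknown compartment"):
            find_shared_clones(t, pair=("skin", "liver"))


class TestOccupancy:
    def test_fraction_of_focal_compartment_repertoire(self, paired_cell_factory):
        cells = [("s1", "skin", TRA1, TRB1), ("j1", "ST", TRA1, TRB1)]
        cells += [(f"b{i}", "skin", TRA2, TRB2) for i in range(9)]
        t = _pooled_table(paired_cell_factory, cells)
        shared = find_shared_clones(t)
        occ = occupancy(t, shared, "skin")
        assert occ.per_patient["P1"] == pytest.approx(10.0)

    def test_patient_without_compartment_omitted(self, paired_cell_factory):
        c1, m1 = paired_cell_factory([("s1", "skin", TRA1, TRB1), ("j1", "ST", TRA1, TRB1)], patient="P1")
        c2, m2 = paired_cell_factory([("b1", "blood", TRA2, TRB2)], patient="P2")
        t = pool_joint(call_clones(build_chain_profiles(c1 + c2), m1 + m2))
        occ = occupancy(t, find_shared_clones(t), "skin")
        assert set(occ.per_patient) == {"P1"}
        assert occ.median == occ.per_patient["P1"]

    def test_disjoint_shared_sets_add_occupancies(self, paired_cell_factory):
        cells = [("s1", "skin", TRA1, TRB1), ("j1", "SF", TRA1, TRB1),
                 ("s2", "skin", TRA2, TRB2), ("j2", "ST", TRA2, TRB2)]
        cells += [(f"b{i}", "skin", "TGTGCAGCATTT", "TGTGCCAGCAAA") for i in range(6)]
        t = _pooled_table(paired_cell_factory, cells)
        full = find_shared_clones(t)
        parts = []
        for clone in full.clones:
            sub = find_shared_clones(t)
            sub.clones = [c for c in sub.clones if c.clone_id == clone.clone_id]
            parts.append(occupancy(t, sub, "skin").per_patient["P1"])
        assert sum(parts) == pytest.approx(occupancy(t, full, "skin").per_patient["P1"])


class TestInversePielou:
    def test_boundary_cases(self):
        assert inverse_pielou([5]) == 1.0
        assert inverse_pielou([1, 1, 1, 1]) == 0.0

    def test_hand_computed_example(self):
        # sizes [2,1,1]: H = -(1/2 ln 1/2 + 2 * 1/4 ln 1/4), S = 3
        h = -(0.5 * math.log(0.5) + 0.5 * math.log(0.25))
        assert inverse_pielou([2, 1, 1]) == pytest.approx(1 - h / math.log(3), abs=1e-12)
        assert inverse_pielou([2, 1, 1]) == pytest.approx(0.0536, abs=1e-4)

    def test_rejects_empty_and_fractional(self):
        with pytest.raises(ValueError):
            inverse_pielou([])
        with pytest.raises(ValueError):
            inverse_pielou([0, 2])

    @given(st.lists(st.integers(1, 60), min_size=1, max_size=40), st.integers(2, 7))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_and_scale_invariance(self, sizes, k):
        base = inverse_pielou(sizes)
        assert inverse_pielou(list(reversed(sizes))) == pytest.approx(base, abs=1e-12)
        assert inverse_pielou([k * s for s in sizes]) == pytest.approx(base, abs=1e-12)
        assert 0.0 <= base <= 1.0
        if len(sizes) == 1:
            assert base == 1.0
        elif len(set(sizes)) == 1:
            assert base == 0.0
        else:
            assert 0.0 < base < 1.0

    @given(st.lists(st.integers(1, 40), min_size=2, max_size=25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_growing_the_largest_clone_never_decreases_clonality(self, sizes):
        grown = list(sizes)
        grown[int(np.argmax(grown))] += 1

        def entropy_oracle(ss):
            p = np.asarray(ss, float) / sum(ss)
            return 1 - float(-(p * np.log(p)).sum()) / math.log(len(ss))

        assert inverse_pielou(grown) >= inverse_pielou(sizes) - 1e-12
        assert inverse_pielou(grown) == pytest.approx(entropy_oracle(grown), abs=1e-12)


class TestSharingSummary:
    def test_block_heights_sum_to_100_and_bars_sorted(self, paired_cell_factory):
        cells = [("s1", "skin", TRA1, TRB1), ("j1", "ST", TRA1, TRB1),
                 ("s2", "skin", TRA2, TRB2), ("j2", "ST", TRA2, TRB2), ("j3", "ST", TRA2, TRB2),
                 ("s3", "skin", "TGTGCAGCATTT", "TGTGCCAGCAAA")]
        t = _pooled_table(paired_cell_factory, cells)
        shared = find_shared_clones(t)
        out = sharing_summary(t, [shared])
        per_comp = out["blocks"].groupby("compartment")["height_pct"].sum()
        assert np.allclose(per_comp.to_numpy(), 100.0)
        assert len(out["links"]) == len(shared.clones)
        sizes = out["bars"].groupby("patient")["total_cells"].apply(list)["P1"]
        assert sizes == sorted(sizes, reverse=True)

    def test_diversity_is_per_patient_compartment(self, paired_cell_factory):
        cells = [("s1", "skin", TRA1, TRB1), ("s2", "skin", TRA1, TRB1),
                 ("b1", "blood", TRA2, TRB2)]
        t = _pooled_table(paired_cell_factory, cells)
        df = diversity_table(t)
        skin = df[df["compartment"] == "skin"].iloc[0]
        assert skin["n_clones"] == 1 and skin["inverse_pielou"] == 1.0
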