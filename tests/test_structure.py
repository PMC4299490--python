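import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cccnet.structure import (
    cluster_production,
    cocluster_binding,
    compare_module_overlap,
    jaccard_distance_matrix,
    module_ligand_sets,
    overlap_ttest,
    overlap_vector,
)

S_PRINTED = [9, 13, 10, 12, 12, 17]
T_PRINTED = [75, 75, 69]


def block_matrix(blocks, n_ligands_per_block, noise=0.0, seed=0):
    """cells x ligands binary matrix with one ligand block per cell block."""
    rng = np.random.default_rng(seed)
    cells = [f"c{b}_{i}" for b, size in enumerate(blocks) for i in range(size)]
    ligs = [f"l{b}_{j}" for b in range(len(blocks)) for j in range(n_ligands_per_block)]
    A = pd.DataFrame(0, index=cells, columns=ligs)
    for b, size in enumerate(blocks):
        rows = [c for c in cells if c.startswith(f"c{b}_")]
        cols = [l for l in ligs if l.startswith(f"l{b}_")]
        A.loc[rows, cols] = 1
    if noise:
        flip = rng.random(A.shape) < noise
        A = A.where(~flip, 1 - A)
    return A


class TestProductionClustering:
    def test_identical_ligand_sets_share_a_module_at_any_k(self):
        A = block_matrix([2, 2, 2], 4)
        for k in (2, 3):
            part = cluster_production(A, k_range=(k,))
            assert part.assignment["c0_0"] == part.assignment["c0_1"]

    def test_planted_four_blocks_select_k4_and_match_truth(self):
        A = block_matrix([5, 2, 1, 4], 6)  # mirrors the 4-module cell partition
        part = cluster_production(A, k_range=(2, 3, 4, 5, 6))
        assert part.k == 4
        truth = pd.Series([c.split("_")[0] for c in A.index], index=A.index)
        assert (
            pd.crosstab(truth, part.assignment).gt(0).sum(axis=1) == 1
        ).all()  # each planted block maps to exactly one module

    def test_fully_overlapping_sets_show_no_modularity(self):
        A = pd.DataFrame(1, index=[f"c{i}" for i in range(6)], columns=list("abcd"))
        part = cluster_production(A, k_range=(2, 3))
        # degenerate: silhouettes are near zero or undefined (single cluster)
        sil = part.mean_silhouette_per_k["mean_silhouette"]
        assert not (sil.abs() > 0.1).any()

    def test_empty_ligand_set_pairs_get_distance_zero_with_warning(self, caplog):
        A = pd.DataFrame(
            [[0, 0], [0, 0], [1, 1]], index=["e1", "e2", "f"], columns=["x", "y"]
        )
        with caplog.at_level("WARNING", logger="cccnet.structure"):
            D = jaccard_distance_matrix(A)
        assert D.loc["e1", "e2"] == 0.0
        assert "empty" in caplog.text

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_jaccard_triangle_inequality(self, a, b, c):
        """Jaccard distance is a metric on arbitrary 20-ligand production rows."""
        A = pd.DataFrame(
            [[int(x) for x in f"{v:020b}"] for v in (a, b, c)],
            index=["r0", "r1", "r2"],
            columns=[f"l{i}" for i in range(20)],
        )
        D = jaccard_distance_matrix(A).to_numpy()
        for i, j, k in itertools.permutations(range(3)):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestCocluster:
    def test_exact_two_blocks_recovered(self):
        B = block_matrix([3, 3], 4).T  # ligands x cells
        res = cocluster_binding(B, k=2, seed=0)
        assert res.col_assignment["c0_0"] == res.col_assignment["c0_1"]
        assert res.col_assignment["c0_0"] != res.col_assignment["c1_0"]
        # rows co-cluster with their block's cells
        assert res.row_assignment["l0_0"] == res.col_assignment["c0_0"]

    def test_agrees_with_reference_coclustering_on_noisy_blocks(self):
        from sklearn.cluster import SpectralCoclustering
        from sklearn.metrics import adjusted_rand_score

        B = block_matrix([4, 4, 4], 8, noise=0.05, seed=2).T.astype(float)
        B = B.loc[B.sum(axis=1) > 0, B.columns[(B.sum(axis=0) > 0)]]
        ours = cocluster_binding(B, k=3, seed=0)
        ref = SpectralCoclustering(n_clusters=3, random_state=0).fit(B.to_numpy())
        assert adjusted_rand_score(ref.row_labels_, ours.row_assignment.to_numpy()) > 0.9

    def test_invariant_to_simultaneous_permutation(self):
        rng = np.random.default_rng(4)
        B = block_matrix([3, 3], 5, noise=0.02, seed=4).T
        perm_r = rng.permutation(B.index)
        perm_c = rng.permutation(B.columns)
        a = cocluster_binding(B, k=2, seed=0)
        b = cocluster_binding(B.loc[perm_r, perm_c], k=2, seed=0)
        joint_a = pd.concat([a.row_assignment, a.col_assignment])
        joint_b = pd.concat([b.row_assignment, b.col_assignment])
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(joint_a.sort_index(), joint_b.sort_index()) == 1.0

    def test_all_ones_matrix_reports_non_separability(self):
        B = pd.DataFrame(1.0, index=[f"l{i}" for i in range(6)], columns=list("abcd"))
        res = cocluster_binding(B, k=2, seed=0)
        assert not res.is_separable()

    def test_zero_row_is_named_in_error(self):
        B = pd.DataFrame([[1, 1], [0, 0]], index=["good", "dead"], columns=["a", "b"])
        with pytest.raises(ValueError, match="dead"):
            cocluster_binding(B, k=2)


class TestOverlapComparison:
    def test_printed_vectors_differ_strongly_under_both_variants(self):
        for variant in ("welch", "pooled"):
            res = overlap_ttest(S_PRINTED, T_PRINTED, variant)
            assert res.p < 0.001

    def test_welch_statistic_matches_hand_computation(self):
        # computed from the printed vectors with the Welch formula before wiring
        res = overlap_ttest(S_PRINTED, T_PRINTED, "welch")
        assert res.t == pytest.approx(-26.438171551853706, rel=1e-9)

    def test_identical_vectors_give_p_one_under_pooled_test(self):
        res = overlap_ttest(S_PRINTED, S_PRINTED, "pooled")
        assert res.p == pytest.approx(1.0)

    def test_module_sets_drive_the_comparison(self):
        prod = {1: {"a", "b"}, 2: {"b", "c"}, 3: {"c", "d"}}
        bind = {1: set("abcdef"), 2: set("abcdeg"), 3: set("abcdhi")}
        res = compare_module_overlap(prod, bind)
        assert res.S == [1, 0, 1]
        assert res.T == [5, 4, 4]
        assert res.p < 0.05

    def test_single_module_side_rejected(self):
        with pytest.raises(ValueError, match="2 modules"):
            overlap_vector({1: {"a"}})

    def test_module_ligand_sets_union_rows(self):
        A = pd.DataFrame(
            [[1, 0, 1], [0, 1, 1], [0, 0, 1]],
            index=["x", "y", "z"],
            columns=["l1", "l2", "l3"],
        )
        assignment = pd.Series({"x": 1, "y": 1, "z": 2})
        sets = module_ligand_sets(A, assignment)
        assert sets == {1: {"l1", "l2", "l3"}, 2: {"l3"}}
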