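"""Cosine, UPGMA, CCSV cuts, cophenetic distances, Newick export."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from oracles import naive_cosine_matrix, naive_upgma_cophenetic
from swarmcite import (
    SimilarityMatrix,
    cophenetic,
    cosine_similarity,
    cut_at_ccsv,
    similarity_matrix,
    to_newick,
    upgma,
)
from swarmcite.clustering import write_newick
from swarmcite.errors import DegenerateInputError, UndefinedSimilarityError


def sim_from(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [chr(ord("A") + i) for i in range(len(values))]
    return SimilarityMatrix(labels=list(labels), values=values)


def random_similarity(rng, n):
    x = rng.random((n, n))
    s = (x + x.T) / 2
    np.fill_diagonal(s, 1.0)
    return s


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_similarity([1, 0, 2], [0, 3, 0]) == 0.0

    def test_hand_value(self):
        assert cosine_similarity([1, 2, 0], [2, 1, 1]) == pytest.approx(
            4 / math.sqrt(30), abs=1e-9
        )

    def test_zero_vector_is_an_error(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity([0, 0], [1, 2])


class TestSimilarityMatrix:
    def test_identical_columns_give_one(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [2, 4]}, index=["p1", "p2"])
        sm = similarity_matrix(df, axis="columns")
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_identity_matrix_gives_zero_offdiagonal(self):
        df = pd.DataFrame(np.eye(3, dtype=int), index=list("xyz"), columns=list("abc"))
        sm = similarity_matrix(df, axis="columns")
        off = sm.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 9, size=(5, 4)) + 1
        df = pd.DataFrame(counts, index=[f"r{i}" for i in range(5)],
                          columns=[f"c{j}" for j in range(4)])
        for axis, data in (("rows", counts), ("columns", counts.T)):
            sm = similarity_matrix(df, axis=axis)
            np.testing.assert_allclose(sm.values, naive_cosine_matrix(np.asarray(data, float)),
                                       atol=1e-12)

    def test_zero_profiles_dropped_and_reported(self):
        df = pd.DataFrame({"a": [1, 0], "b": [0, 0], "c": [1, 1]}, index=["p", "q"])
        sm = similarity_matrix(df, axis="columns")
        assert sm.dropped == ["b"] and sm.labels == ["a", "c"]

    def test_fewer_than_two_nonzero_profiles_degenerate(self):
        df = pd.DataFrame({"a": [1], "b": [0]}, index=["p"])
        with pytest.raises(DegenerateInputError):
            similarity_matrix(df, axis="columns")


class TestUPGMA:
    def test_two_items_forced_merge(self):
        tree = upgma(sim_from([[1.0, 0.8], [0.8, 1.0]]))
        assert tree.merges == [(0, 1, pytest.approx(0.2))]

    def test_three_identical_items_merge_at_zero(self):
        tree = upgma(sim_from(np.ones((3, 3))))
        assert all(h == pytest.approx(0.0) for _, _, h in tree.merges)

    def test_matches_naive_oracle_200_seeds(self):
        """Lance-Williams implementation vs from-scratch average-linkage
        recomputation: identical cophenetic matrices on random inputs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            s = random_similarity(rng, n)
            labels = [f"L{i}" for i in range(n)]
            tree = upgma(sim_from(s, labels))
            np.testing.assert_allclose(
                cophenetic(tree), naive_upgma_cophenetic(s, labels), atol=1e-9
            )

    def test_matches_scipy_average_linkage(self):
        """Independent cross-check against scipy's UPGMA on tie-free input."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            s = random_similarity(rng, n)
            tree = upgma(sim_from(s, [f"L{i}" for i in range(n)]))
            d = 1.0 - s
            np.fill_diagonal(d, 0.0)
            Z = sch.linkage(squareform(d, checks=False), method="average")
            np.testing.assert_allclose(
                squareform(cophenetic(tree), checks=False), sch.cophenet(Z), atol=1e-9
            )

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            tree = upgma(sim_from(random_similarity(rng, n), [f"L{i}" for i in range(n)]))
            heights = [h for _, _, h in tree.merges]
            assert all(b >= a - 1e-10 for a, b in zip(heights, heights[1:]))

    def test_deterministic_tie_break(self):
        # three items, all pairwise similarity 0.5: first merge must be (A, B)
        tree = upgma(sim_from(np.full((3, 3), 0.5) + np.eye(3) * 0.5, list("ABC")))
        first = tree.merges[0]
        assert {tree.leaves[first[0]], tree.leaves[first[1]]} == {"A", "B"}


class TestCutAtCCSV:
    def test_threshold_above_everything_gives_singletons(self):
        s = sim_from([[1, 0.3, 0.2], [0.3, 1, 0.4], [0.2, 0.4, 1]])
        clusters = cut_at_ccsv(upgma(s), threshold=0.4)
        assert all(len(c.member_ids) == 1 for c in clusters)

    def test_threshold_below_everything_gives_one_cluster(self):
        s = sim_from([[1, 0.9, 0.8], [0.9, 1, 0.85], [0.8, 0.85, 1]])
        (cluster,) = cut_at_ccsv(upgma(s), threshold=0.5)
        assert cluster.label == "1–3" and len(cluster.member_ids) == 3

    def test_planted_two_blocks_recovered(self):
        """Within-block similarity 0.95, between 0.1: cutting at 0.9 yields
        exactly the two planted blocks (checked against every partition)."""
        n = 6
        s = np.full((n, n), 0.1)
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    s[i, j] = 0.95
        np.fill_diagonal(s, 1.0)
        labels = list("ABCDEF")
        clusters = cut_at_ccsv(upgma(sim_from(s, labels)), threshold=0.9)
        assert {frozenset(c.member_ids) for c in clusters} == {
            frozenset("ABC"),
            frozenset("DEF"),
        }

    def test_cut_is_a_contiguous_partition(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            tree = upgma(sim_from(random_similarity(rng, n), [f"L{i}" for i in range(n)]))
            thr = float(rng.random())
            clusters = cut_at_ccsv(tree, thr)
            covered = set()
            order = [tree.leaves[i] for i in tree.leaf_order]
            for c in clusters:
                assert not (c.member_ids & covered)
                covered |= c.member_ids
                first, last = c.positions
                assert set(order[first - 1 : last]) == c.member_ids
                assert c.ccsv > thr or len(c.member_ids) == 1
            assert covered == set(tree.leaves)


class TestCophenetic:
    def test_two_leaf_tree(self):
        tree = upgma(sim_from([[1, 0.8], [0.8, 1]]))
        assert cophenetic(tree)[0, 1] == pytest.approx(0.2)

    def test_three_leaf_chain_heights(self):
        # A-B merge at 0.1; C joins at mean(0.6, 0.4) = 0.5
        s = np.array([[1.0, 0.9, 0.4], [0.9, 1.0, 0.6], [0.4, 0.6, 1.0]])
        C = cophenetic(upgma(sim_from(s, list("ABC"))))
        assert C[0, 1] == pytest.approx(0.1)
        assert C[0, 2] == pytest.approx(0.5)
        assert C[1, 2] == pytest.approx(0.5)

    def test_ultrametric_inequality(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            C = cophenetic(upgma(sim_from(random_similarity(rng, n), [f"L{i}" for i in range(n)])))
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert C[i, j] <= max(C[i, k], C[j, k]) + 1e-12


class TestNewick:
    def test_two_leaf_string(self):
        tree = upgma(sim_from([[1, 0.8], [0.8, 1]], ["A", "B"]))
        assert to_newick(tree) == "(A:0.1,B:0.1);"

    def test_round_trip_topology(self, tmp_path):
        import dendropy

        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            tree = upgma(sim_from(random_similarity(rng, n), [f"L{i}" for i in range(n)]))
            path = tmp_path / "t.nwk"
            write_newick(tree, path)
            parsed = dendropy.Tree.get(path=str(path), schema="newick")
            assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(tree.leaves)
            # ultrametric depths equal cophenetic/2
            pdm = parsed.phylogenetic_distance_matrix()
            C = cophenetic(tree)
            taxa = {t.label: t for t in parsed.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    d = pdm.patristic_distance(taxa[tree.leaves[i]], taxa[tree.leaves[j]])
                    assert d == pytest.approx(C[i, j], abs=1e-6)

    def test_three_leaf_depths_halve_merge_heights(self, tmp_path):
        s = np.array([[1.0, 0.9, 0.4], [0.9, 1.0, 0.6], [0.4, 0.6, 1.0]])
        tree = upgma(sim_from(s, list("ABC")))
        nwk = to_newick(tree)
        # root height 0.5 -> leaf depth 0.25; A/B merge at 0.1 -> 0.05 branches
        assert "A:0.05" in nwk and "B:0.05" in nwk and "C:0.25" in nwk
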