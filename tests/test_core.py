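import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comparanet import (
    Connectome,
    RegionTable,
    average_subjects,
    density,
    merge_regions,
    read_connectome,
    read_region_table,
    split_hemispheres,
    subject_consistency,
    symmetrize_binarize,
    threshold_to_edge_count,
    write_connectome,
)
from comparanet.synthetic import (
    default_region_table,
    generate_subjects,
    random_weighted_connectome,
)

from conftest import connectome_from_edges


# ---------------------------------------------------------------------------
# domain-type invariants
# ---------------------------------------------------------------------------


class TestConnectomeInvariants:
    def test_rejects_nonzero_diagonal(self):
        w = np.ones((2, 2))
        with pytest.raises(ValueError, match="diagonal"):
            Connectome(("A", "B"), w)

    def test_rejects_negative_weights(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            Connectome(("A", "B"), w)

    def test_rejects_asymmetric_undirected(self):
        w = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            Connectome(("A", "B"), w, directed=False)

    def test_rejects_nonbinary_when_unweighted(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="0 or 1"):
            Connectome(("A", "B"), w, weighted=False)

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            Connectome(("A", "A"), np.zeros((2, 2)))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="matrix"):
            Connectome(("A", "B", "C"), np.zeros((2, 2)))


class TestRegionTable:
    def test_hemisphere_codes_validated(self):
        with pytest.raises(ValueError, match="hemisphere"):
            RegionTable(("A",), ("X",), ("frontal",))

    def test_roundtrip(self, tmp_path):
        rt = default_region_table(6)
        rt.to_tsv(tmp_path / "rt.tsv")
        back = read_region_table(tmp_path / "rt.tsv")
        assert back == rt

    def test_hemisphere_labels(self):
        rt = default_region_table(6)
        assert len(rt.hemisphere_labels("L")) == 3
        assert set(rt.hemisphere_labels("L")) | set(rt.hemisphere_labels("R")) == set(rt.labels)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


class TestIO:
    def test_dense_roundtrip_toy(self, toy_pair, tmp_path):
        net1, _ = toy_pair
        write_connectome(net1, tmp_path / "net1.tsv", "dense")
        back = read_connectome(tmp_path / "net1.tsv", "dense")
        assert back.labels == net1.labels
        assert np.array_equal(back.weights, net1.weights)
        assert back.n_edges == 4

    def test_dense_roundtrip_weighted_subjects(self, tmp_path):
        base = random_weighted_connectome(10, 20, seed=3)
        subjects = generate_subjects(base, 5, noise_sd=0.05, seed=7)
        for i, s in enumerate(subjects):
            write_connectome(s, tmp_path / f"s{i}.tsv", "dense")
            back = read_connectome(tmp_path / f"s{i}.tsv", "dense")
            assert np.array_equal(back.weights, s.weights)

    def test_edgelist_roundtrip(self, toy_pair, tmp_path):
        net1, _ = toy_pair
        write_connectome(net1, tmp_path / "net1.el.tsv", "edgelist")
        back = read_connectome(tmp_path / "net1.el.tsv", "edgelist")
        assert back.edge_set() == net1.edge_set()

    def test_empty_edge_roundtrip(self, tmp_path):
        c = Connectome(("A", "B", "C"), np.zeros((3, 3)))
        write_connectome(c, tmp_path / "empty.tsv", "dense")
        back = read_connectome(tmp_path / "empty.tsv", "dense")
        assert np.array_equal(back.weights, c.weights)

    def test_edgelist_symmetric_duplicate_collapses(self, tmp_path):
        (tmp_path / "e.tsv").write_text("A\tB\t1.0\nB\tA\t1.0\n")
        c = read_connectome(tmp_path / "e.tsv", "edgelist")
        assert c.n_edges == 1
        assert not c.directed

    def test_edgelist_conflicting_duplicate_rejected(self, tmp_path):
        (tmp_path / "e.tsv").write_text("A\tB\t1.0\nB\tA\t2.0\n")
        with pytest.raises(ValueError, match="conflicting"):
            read_connectome(tmp_path / "e.tsv", "edgelist")

    def test_edgelist_self_pair_rejected(self, tmp_path):
        (tmp_path / "e.tsv").write_text("A\tA\t1.0\n")
        with pytest.raises(ValueError, match="self-pair"):
            read_connectome(tmp_path / "e.tsv", "edgelist")

    def test_edgelist_negative_weight_rejected(self, tmp_path):
        (tmp_path / "e.tsv").write_text("A\tB\t-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            read_connectome(tmp_path / "e.tsv", "edgelist")

    def test_dense_nonsquare_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("\tA\tB\tC\nA\t0\t1\t0\nB\t1\t0\t0\n")
        with pytest.raises(ValueError):
            read_connectome(tmp_path / "bad.tsv", "dense")

    def test_label_absent_from_region_table_rejected(self, tmp_path, toy_pair):
        net1, _ = toy_pair
        write_connectome(net1, tmp_path / "net1.tsv", "dense")
        rt = RegionTable(("A", "B"), ("L", "L"), ("frontal", "frontal"))
        with pytest.raises(ValueError, match="absent"):
            read_connectome(tmp_path / "net1.tsv", "dense", region_table=rt)

    def test_region_table_order_wins(self, tmp_path, toy_pair):
        net1, _ = toy_pair
        write_connectome(net1, tmp_path / "net1.tsv", "dense")
        rt = RegionTable(("D", "C", "B", "A"), ("L",) * 4, ("frontal",) * 4)
        c = read_connectome(tmp_path / "net1.tsv", "dense", region_table=rt)
        assert c.labels == ("D", "C", "B", "A")
        assert c.edge_set() == net1.edge_set()


# ---------------------------------------------------------------------------
# symmetrize / binarize
# ---------------------------------------------------------------------------


class TestSymmetrizeBinarize:
    def test_directed_edge_becomes_undirected(self):
        w = np.zeros((2, 2))
        w[0, 1] = 3.5
        c = Connectome(("A", "B"), w, directed=True, weighted=True)
        out = symmetrize_binarize(c)
        assert out.weights[0, 1] == 1.0 and out.weights[1, 0] == 1.0
        assert not out.directed and not out.weighted

    def test_idempotent_on_binary_undirected(self, toy_pair):
        net1, _ = toy_pair
        out = symmetrize_binarize(net1)
        assert np.array_equal(out.weights, net1.weights)

    def test_any_nonzero_counts(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.2
        c = Connectome(("A", "B"), w, directed=True, weighted=True)
        assert symmetrize_binarize(c).weights[1, 0] == 1.0

    def test_commutes_with_label_permutation(self, rng):
        w = rng.uniform(0, 1, size=(6, 6))
        np.fill_diagonal(w, 0)
        labels = tuple("ABCDEF")
        c = Connectome(labels, w, directed=True, weighted=True)
        perm = rng.permutation(6)
        w_p = w[np.ix_(perm, perm)]
        c_p = Connectome(tuple(labels[i] for i in perm), w_p,
                         directed=True, weighted=True)
        out = symmetrize_binarize(c).weights[np.ix_(perm, perm)]
        out_p = symmetrize_binarize(c_p).weights
        assert np.array_equal(out, out_p)


# ---------------------------------------------------------------------------
# averaging, thresholding, density
# ---------------------------------------------------------------------------


class TestAverageSubjects:
    def test_identity(self):
        c = random_weighted_connectome(5, 6, seed=1)
        out = average_subjects([c, c])
        assert np.allclose(out.weights, c.weights)

    def test_simple_mean(self):
        a = connectome_from_edges("AB", [("A", "B")], weights=[0.0 + 1.0])
        b = Connectome(("A", "B"), np.zeros((2, 2)), weighted=True)
        out = average_subjects([a, b])
        assert out.weights[0, 1] == 0.5

    def test_matches_elementwise_oracle(self):
        base = random_weighted_connectome(8, 15, seed=2)
        subjects = generate_subjects(base, 5, noise_sd=0.1, seed=9)
        out = average_subjects(subjects)
        expected = sum(s.weights for s in subjects) / 5  # independent arithmetic
        assert np.allclose(out.weights, expected, atol=1e-15)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_subjects([])

    def test_label_mismatch_rejected(self):
        a = Connectome(("A", "B"), np.zeros((2, 2)), weighted=True)
        b = Connectome(("A", "C"), np.zeros((2, 2)), weighted=True)
        with pytest.raises(ValueError, match="label"):
            average_subjects([a, b])


class TestThreshold:
    def test_distinct_weights(self):
        c = connectome_from_edges(
            "ABCD", [("A", "B"), ("B", "C"), ("C", "D")], weights=[3, 2, 1])
        out = threshold_to_edge_count(c, 2)
        assert out.edge_set() == {("A", "B"), ("B", "C")}
        assert not out.weighted

    def test_boundary_keeps_full_support(self):
        c = random_weighted_connectome(6, 9, seed=4)
        out = threshold_to_edge_count(c, 9)
        assert out.edge_set() == c.edge_set()

    def test_tie_break_is_lexicographic_and_deterministic(self):
        # weight-2 pair kept; among the tied weight-1 pairs (B,C) < (B,D) < (C,D)
        edges = [("A", "B"), ("B", "C"), ("B", "D"), ("C", "D")]
        c = connectome_from_edges("ABCD", edges, weights=[2, 1, 1, 1])
        expected = {("A", "B"), ("B", "C")}  # enumerated by the declared rule
        for _ in range(5):
            out = threshold_to_edge_count(c, 2)
            assert out.edge_set() == expected

    def test_target_exceeding_support_rejected(self):
        c = connectome_from_edges("AB", [("A", "B")], weights=[1.0])
        with pytest.raises(ValueError, match="exceeds"):
            threshold_to_edge_count(c, 2)

    @given(st.integers(min_value=0, max_value=15), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_edge_count_exact_even_with_ties(self, target, seed):
        rng = np.random.default_rng(seed)
        n = 6
        w = rng.integers(0, 3, size=(n, n)).astype(float)  # many ties
        w = np.triu(w, 1)
        w = w + w.T
        c = Connectome(tuple("ABCDEF"), w, weighted=True)
        available = c.n_edges
        if target > available:
            return
        out = threshold_to_edge_count(c, target)
        assert out.n_edges == target
        assert density(out) == target / (n * (n - 1) / 2)


class TestDensity:
    def test_brain_scale_value(self, brain_sized):
        assert round(density(brain_sized), 3) == 0.559

    def test_complete_graph(self):
        w = 1.0 - np.eye(4)
        assert density(Connectome(tuple("ABCD"), w)) == 1.0

    def test_empty_graph(self):
        assert density(Connectome(tuple("ABCD"), np.zeros((4, 4)))) == 0.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            density(Connectome(("A",), np.zeros((1, 1))))


# ---------------------------------------------------------------------------
# hemisphere split and subject consistency
# ---------------------------------------------------------------------------


class TestSplitHemispheres:
    def test_half_and_half(self, brain_sized):
        rt = default_region_table(82)
        left, right = split_hemispheres(brain_sized, rt)
        assert left.n_regions == 41 and right.n_regions == 41

    def test_only_interhemispheric_edges(self):
        rt = default_region_table(4)  # first two L, last two R
        labels = rt.labels
        c = connectome_from_edges(labels, [(labels[0], labels[2]),
                                           (labels[1], labels[3])])
        left, right = split_hemispheres(c, rt)
        assert left.n_edges == 0 and right.n_edges == 0

    def test_edge_counts_match_pair_enumeration(self, rng):
        rt = default_region_table(10)
        from comparanet.synthetic import random_connectome
        c = random_connectome(10, 25, seed=11, labels=rt.labels)
        left, right = split_hemispheres(c, rt)
        hemi_of = dict(zip(rt.labels, rt.hemispheres))
        # oracle: count label pairs by brute-force enumeration
        for hemi, sub in (("L", left), ("R", right)):
            expected = sum(
                1 for (u, v) in c.edge_set()
                if hemi_of[u] == hemi and hemi_of[v] == hemi
            )
            assert sub.n_edges == expected

    def test_missing_label_rejected(self):
        rt = default_region_table(4)
        c = connectome_from_edges(("X", "Y"), [("X", "Y")])
        with pytest.raises(ValueError, match="missing"):
            split_hemispheres(c, rt)


class TestSubjectConsistency:
    def test_identical_subjects(self):
        c = random_weighted_connectome(8, 16, seed=5)
        fraction, corrs = subject_consistency([c, c, c], target_L=10, m=3)
        assert fraction == 1.0
        assert all(r == pytest.approx(1.0) for r in corrs)

    def test_disjoint_supports(self):
        a = connectome_from_edges("ABCD", [("A", "B")], weights=[2.0])
        b = connectome_from_edges("ABCD", [("C", "D")], weights=[2.0])
        fraction, _ = subject_consistency([a, b], target_L=1, m=2)
        assert fraction == 0.0

    def test_matches_set_count_oracle(self):
        base = random_weighted_connectome(12, 40, seed=6)
        subjects = generate_subjects(base, 5, noise_sd=0.2, seed=8)
        target_L, m = 25, 4
        fraction, corrs = subject_consistency(subjects, target_L, m)
        # oracle: explicit set intersection counting
        avg = average_subjects(subjects)
        avg_edges = threshold_to_edge_count(avg, target_L).edge_set()
        subj_edges = [threshold_to_edge_count(s, target_L).edge_set()
                      for s in subjects]
        expected = sum(
            1 for e in avg_edges if sum(e in s for s in subj_edges) >= m
        ) / len(avg_edges)
        assert fraction == expected
        assert len(corrs) == 10  # C(5,2)

    def test_m_exceeding_subjects_rejected(self):
        c = random_weighted_connectome(5, 6, seed=1)
        with pytest.raises(ValueError):
            subject_consistency([c, c], target_L=3, m=3)


class TestMergeRegions:
    def test_merge_preserves_any_connection(self):
        c = connectome_from_edges("ABCD", [("A", "C"), ("B", "D")])
        merged = merge_regions(c, {"A": "AB", "B": "AB", "C": "CD", "D": "CD"})
        assert merged.labels == ("AB", "CD")
        assert merged.n_edges == 1
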