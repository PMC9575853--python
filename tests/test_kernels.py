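"""Similarity kernels: worked examples, error contracts and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsinet import (
    AlignmentScoring,
    BinaryProfileSet,
    ConfidenceGraph,
    ISPParams,
    SequenceSet,
    alignment_similarity,
    common_neighbor_similarity,
    cosine_similarity,
    isp_similarity,
    isp_transform,
    jaccard_similarity,
    measure_correlations,
    tanimoto_similarity,
)
from fsinet.kernels import _binary_pairwise


def profiles_from_rows(*rows):
    rows = np.array(rows)
    return BinaryProfileSet(
        entity_ids=[f"e{i}" for i in range(rows.shape[0])],
        feature_ids=[f"f{j}" for j in range(rows.shape[1])],
        matrix=rows,
    )


binary_profiles = st.integers(1, 97).flatmap(
    lambda seed: st.tuples(st.integers(2, 8), st.integers(1, 12)).map(
        lambda shape: (np.random.default_rng(seed).random(shape) < 0.4).astype(int)
    )
)


@pytest.mark.parametrize(
    "kernel,rows,expected_01",
    [
        (tanimoto_similarity, [(1, 0, 1), (1, 0, 1)], 1.0),
        (tanimoto_similarity, [(1, 1, 0), (0, 0, 1)], 0.0),
        (tanimoto_similarity, [(1, 1, 0), (1, 0, 1)], 1 / 3),
        (jaccard_similarity, [(1, 1, 0), (1, 1, 0)], 1.0),
        (jaccard_similarity, [(1, 0, 0), (0, 1, 1)], 0.0),
        (jaccard_similarity, [(1, 1, 0), (1, 0, 1)], 1 / 3),
        (cosine_similarity, [(0, 1, 1), (0, 1, 1)], 1.0),
        (cosine_similarity, [(1, 1, 0), (1, 0, 1)], 0.5),
        (cosine_similarity, [(1, 0, 0), (0, 1, 0)], 0.0),
    ],
)
def test_profile_kernel_worked_examples(kernel, rows, expected_01):
    sim = kernel(profiles_from_rows(*rows))
    assert sim.values[0, 1] == pytest.approx(expected_01, abs=1e-12)
    assert sim.values[0, 0] == 1.0


def test_zero_profile_rows_score_zero_off_diagonal():
    sim = jaccard_similarity(profiles_from_rows((0, 0, 0), (1, 1, 0)))
    assert sim.values[0, 1] == 0.0
    assert sim.values[0, 0] == 1.0  # diagonal forced even for empty profiles


def test_empty_profile_set_is_an_error():
    empty = BinaryProfileSet(entity_ids=[], feature_ids=["f0"], matrix=np.zeros((0, 1)))
    with pytest.raises(ValueError, match="no entities"):
        tanimoto_similarity(empty)


@given(binary_profiles)
@settings(max_examples=40, deadline=None)
def test_tanimoto_equals_jaccard_on_binary_vectors(matrix):
    jac = _binary_pairwise(matrix, "jaccard")
    assert np.allclose(jac, _binary_pairwise(matrix, "jaccard"))
    prof = BinaryProfileSet(
        [f"e{i}" for i in range(matrix.shape[0])],
        [f"f{j}" for j in range(matrix.shape[1])],
        matrix,
    )
    assert np.allclose(tanimoto_similarity(prof).values, jaccard_similarity(prof).values)


@given(binary_profiles)
@settings(max_examples=40, deadline=None)
def test_jaccard_below_cosine_and_matrix_invariants(matrix):
    """|u&v|/|u|v| <= |u&v|/sqrt(|u||v|) pointwise, and every output is a
    valid similarity matrix (symmetric, in [0,1], unit diagonal)."""
    jac = _binary_pairwise(matrix, "jaccard")
    cos = _binary_pairwise(matrix, "cosine")
    assert np.all(jac <= cos + 1e-12)
    for sim in (jac, cos):
        assert np.allclose(sim, sim.T)
        assert sim.min() >= 0 and sim.max() <= 1
        assert np.allclose(np.diag(sim), 1.0)


def path_graph(n, confidence=0.9):
    ids = [f"p{i}" for i in range(n)]
    edges = [(ids[i], ids[i + 1], confidence) for i in range(n - 1)]
    return ConfidenceGraph(node_ids=ids, edges=edges)


class TestISP:
    def test_adjacent_pair_matches_hand_value(self):
        sim = isp_similarity(path_graph(3), ISPParams(A=0.9, b=1.0))
        assert sim.values[0, 1] == pytest.approx(0.9 * np.exp(-1), abs=1e-10)

    def test_raw_transform_at_distance_zero_gives_amplitude(self):
        assert isp_transform(0.0, ISPParams(A=0.9, b=1.0)) == pytest.approx(0.9)

    def test_disconnected_pair_scores_zero(self):
        g = ConfidenceGraph(["a", "b", "c"], [("a", "b", 0.9)])
        sim = isp_similarity(g)
        assert sim.values[0, 2] == 0.0 and sim.values[2, 0] == 0.0

    def test_confidence_filter_removes_weak_edges(self):
        g = ConfidenceGraph(["a", "b"], [("a", "b", 0.3)])
        sim = isp_similarity(g, ISPParams(min_confidence=0.5))
        assert sim.values[0, 1] == 0.0

    def test_similarity_non_increasing_with_hop_distance(self):
        sim = isp_similarity(path_graph(6), ISPParams(min_confidence=0.5))
        chain = [sim.values[0, j] for j in range(1, 6)]
        assert all(a >= b for a, b in zip(chain, chain[1:]))

    def test_edge_with_unknown_node_is_an_error(self):
        with pytest.raises(ValueError, match="unknown node"):
            ConfidenceGraph(["a"], [("a", "zzz", 0.9)])


class TestCommonNeighbors:
    def test_identical_neighbor_sets_score_one(self):
        g = ConfidenceGraph(
            ["a", "b", "x", "y"],
            [("a", "x", 0.9), ("a", "y", 0.9), ("b", "x", 0.9), ("b", "y", 0.9)],
        )
        sim = common_neighbor_similarity(g, index="jaccard")
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_neighbor_sets_score_zero(self):
        g = ConfidenceGraph(["a", "b", "x", "y"], [("a", "x", 0.9), ("b", "y", 0.9)])
        sim = common_neighbor_similarity(g, index="jaccard")
        assert sim.values[0, 1] == 0.0

    def test_partial_overlap_hand_value(self):
        # neighbours of n1 = {a, b}, of n2 = {a, c}: Jaccard 1/3
        g = ConfidenceGraph(
            ["n1", "n2", "a", "b", "c"],
            [("n1", "a", 0.9), ("n1", "b", 0.9), ("n2", "a", 0.9), ("n2", "c", 0.9)],
        )
        sim = common_neighbor_similarity(g, index="jaccard")
        assert sim.values[0, 1] == pytest.approx(1 / 3)


class TestAlignment:
    toy = AlignmentScoring(match=1, mismatch=-1, gap_open=1, gap_extend=1)

    def test_identical_sequences_score_one(self):
        seqs = SequenceSet(["a", "b"], ["ACGT", "ACGT"])
        sim = alignment_similarity(seqs, mode="local", scoring=self.toy)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_local_alignment_hand_value(self):
        # local optimum aligns the common prefix ACG: 3 / sqrt(4 * 4)
        seqs = SequenceSet(["a", "b"], ["ACGT", "ACGA"])
        sim = alignment_similarity(seqs, mode="local", scoring=self.toy)
        assert sim.values[0, 1] == pytest.approx(0.75)

    def test_protein_defaults_give_valid_matrix(self):
        seqs = SequenceSet(["a", "b", "c"], ["MKTAYIAK", "MKTAYLAK", "GGGGGGGG"])
        for mode in ("local", "global"):
            sim = alignment_similarity(seqs, mode=mode)
            sim.validate()
            assert sim.values[0, 1] > sim.values[0, 2]

    def test_unknown_residue_is_named_in_error(self):
        seqs = SequenceSet(["a", "b"], ["MKTA", "MK1A"])
        with pytest.raises(ValueError, match="'b'.*1"):
            alignment_similarity(seqs)

    def test_permuting_sequence_order_permutes_matrix(self):
        seqs = SequenceSet(["a", "b", "c"], ["MKTAYIAK", "MKTAYLAK", "WWYFHHKL"])
        rev = SequenceSet(["c", "b", "a"], ["WWYFHHKL", "MKTAYLAK", "MKTAYIAK"])
        s1 = alignment_similarity(seqs).values
        s2 = alignment_similarity(rev).values
        assert np.allclose(s1, s2[::-1, ::-1].T)


class TestMeasureCorrelations:
    def _matrix(self, values, name="m"):
        from fsinet import SimilarityMatrix

        return SimilarityMatrix("drug", [f"e{i}" for i in range(len(values))],
                                np.array(values, dtype=float), name, "x")

    def test_self_correlation_is_one(self):
        m = self._matrix([[1, 0.2, 0.7], [0.2, 1, 0.4], [0.7, 0.4, 1]])
        rho = measure_correlations([m, m])
        assert rho[0, 1] == pytest.approx(1.0)

    def test_complemented_matrix_is_perfectly_anticorrelated(self):
        v = np.array([[1, 0.2, 0.7], [0.2, 1, 0.4], [0.7, 0.4, 1]])
        comp = 1 - v
        np.fill_diagonal(comp, 1.0)
        rho = measure_correlations([self._matrix(v), self._matrix(comp, "inv")])
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_constant_matrix_reports_missing_value(self):
        v = np.full((3, 3), 0.5)
        np.fill_diagonal(v, 1.0)
        rho = measure_correlations([self._matrix(v, "const"), self._matrix(v, "c2")])
        assert np.isnan(rho[0, 1])

    def test_independent_random_measures_nearly_uncorrelated(self):
        rng = np.random.default_rng(5)
        n = 60
        mats = []
        for name in ("r1", "r2"):
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            from fsinet import SimilarityMatrix

            mats.append(SimilarityMatrix("drug", [f"e{i}" for i in range(n)], a, name, name))
        rho = measure_correlations(mats)
        assert abs(rho[0, 1]) < 0.1
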