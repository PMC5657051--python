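import numpy as np
import pytest

from lpfuse.data_io import InteractionTable
from lpfuse.hetesim import (
    InteractionMatrix,
    hetesim_lpp,
    hetesim_recursive,
    reachable_probability,
    row_normalize,
)
from lpfuse.similarity import SimilarityMatrix

from .conftest import random_similarity


def make_lp(values, lncrnas=None, proteins=None):
    values = np.asarray(values, dtype=float)
    lncrnas = lncrnas or tuple(f"L{i}" for i in range(values.shape[0]))
    proteins = proteins or tuple(f"P{i}" for i in range(values.shape[1]))
    return InteractionMatrix(lncrnas, proteins, values)


def relations_for(lp: InteractionMatrix, pp: SimilarityMatrix):
    """Dict-of-dicts view of the two relations, diagonal of pp excluded."""
    rel_lp = {
        l: {p: lp.values[i, j] for j, p in enumerate(lp.protein_index) if lp.values[i, j] > 0}
        for i, l in enumerate(lp.lncrna_index)
    }
    rel_pp = {
        p: {q: pp.values[i, j] for j, q in enumerate(pp.index) if i != j and pp.values[i, j] > 0}
        for i, p in enumerate(pp.index)
    }
    return [rel_lp, rel_pp]


class TestRowNormalize:
    def test_positive_row_divided_by_sum(self):
        out = row_normalize(np.array([[1.0, 1.0, 0.0]]))
        assert np.allclose(out.values, [[0.5, 0.5, 0.0]])

    def test_zero_row_left_zero_and_flagged(self):
        out = row_normalize(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert np.array_equal(out.values[0], [0.0, 0.0])
        assert out.zero_rows == (0,)

    def test_idempotent_on_stochastic_matrix(self):
        stochastic = np.array([[0.3, 0.7], [1.0, 0.0]])
        assert np.allclose(row_normalize(stochastic).values, stochastic)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            row_normalize(np.array([[-1.0, 2.0]]))


class TestReachableProbability:
    def test_single_matrix_is_identity_of_product(self):
        tm = row_normalize(np.array([[1.0, 1.0], [0.0, 1.0]]))
        assert np.array_equal(reachable_probability([tm]), tm.values)

    def test_product_of_stochastic_matrices_is_stochastic(self):
        a = row_normalize(np.array([[1.0, 3.0], [2.0, 2.0]]))
        b = row_normalize(np.array([[1.0, 0.0], [1.0, 1.0]]))
        pm = reachable_probability([a, b])
        assert np.allclose(pm.sum(axis=1), 1.0)

    def test_hand_multiplied_fixture(self):
        a = row_normalize(np.array([[1.0, 1.0], [2.0, 0.0], [0.0, 4.0]]))
        b = row_normalize(np.array([[3.0, 1.0], [0.0, 2.0]]))
        pm = reachable_probability([a, b])
        expected = np.array([[0.375, 0.625], [0.75, 0.25], [0.0, 1.0]])
        assert np.allclose(pm, expected)

    def test_dimension_mismatch_rejected(self):
        a = row_normalize(np.ones((2, 3)))
        b = row_normalize(np.ones((2, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            reachable_probability([a, b])


class TestHetesimLpp:
    def test_colinear_reach_distributions_score_one(self):
        # L0 interacts only with P1; P0's only similarity neighbour is P1.
        lp = make_lp([[0, 1, 0]])
        pp_values = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        pp = SimilarityMatrix(lp.protein_index, pp_values)
        scores = hetesim_lpp(lp, pp).values
        assert scores[0, 0] == pytest.approx(1.0)

    def test_lncrna_without_interactions_scores_zero(self):
        lp = make_lp([[0, 0, 0], [1, 1, 0]])
        pp = random_similarity(3, np.random.default_rng(0), index=lp.protein_index)
        assert (hetesim_lpp(lp, pp).values[0] == 0.0).all()

    def test_index_mismatch_rejected(self):
        lp = make_lp([[1, 1]], proteins=("Q0", "Q1"))
        pp = random_similarity(2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="indices differ"):
            hetesim_lpp(lp, pp)

    def test_matches_recursive_reference_on_fixture(self):
        rng = np.random.default_rng(5)
        lp = make_lp((rng.random((3, 4)) < 0.5).astype(float))
        pp = random_similarity(4, rng, index=lp.protein_index)
        scores = hetesim_lpp(lp, pp)
        relations = relations_for(lp, pp)
        for i, l in enumerate(lp.lncrna_index):
            for j, p in enumerate(lp.protein_index):
                assert scores.values[i, j] == pytest.approx(
                    hetesim_recursive(l, p, relations), abs=1e-9
                )

    def test_invariant_under_joint_protein_permutation(self):
        rng = np.random.default_rng(11)
        lp = make_lp((rng.random((4, 5)) < 0.4).astype(float))
        pp = random_similarity(5, rng, index=lp.protein_index)
        perm = np.array([2, 0, 4, 1, 3])
        lp_perm = InteractionMatrix(
            lp.lncrna_index, tuple(lp.protein_index[i] for i in perm), lp.values[:, perm]
        )
        pp_perm = SimilarityMatrix(
            tuple(pp.index[i] for i in perm), pp.values[np.ix_(perm, perm)]
        )
        assert np.allclose(
            hetesim_lpp(lp, pp).values[:, perm], hetesim_lpp(lp_perm, pp_perm).values
        )

    def test_invariant_to_positive_scaling_of_similarity(self):
        rng = np.random.default_rng(3)
        lp = make_lp((rng.random((3, 4)) < 0.5).astype(float))
        pp = random_similarity(4, rng, index=lp.protein_index)
        scaled = SimilarityMatrix(pp.index, pp.values.copy())
        scaled.values *= 0.25  # bypasses [0,1]-validation deliberately
        assert np.allclose(
            hetesim_lpp(lp, pp).values, hetesim_lpp(lp, scaled).values, atol=1e-12
        )

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(17)
        lp = make_lp((rng.random((6, 8)) < 0.3).astype(float))
        pp = random_similarity(8, rng, index=lp.protein_index)
        scores = hetesim_lpp(lp, pp).values
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_sqrt_denominator_variant_never_exceeds_cosine(self):
        # reach distributions have Euclidean norm <= 1, so the sqrt-of-product
        # denominator is the larger of the two and its scores the smaller
        rng = np.random.default_rng(29)
        lp = make_lp((rng.random((3, 4)) < 0.5).astype(float))
        pp = random_similarity(4, rng, index=lp.protein_index)
        cosine = hetesim_lpp(lp, pp).values
        alt = hetesim_lpp(lp, pp, denominator="sqrt").values
        assert (alt <= cosine + 1e-12).all()


class TestRecursiveReference:
    def test_length_one_path_returns_interaction_indicator(self):
        rel = [{"L1": {"P1": 1.0}, "L2": {}}]
        assert hetesim_recursive("L1", "P1", rel) == 1.0
        assert hetesim_recursive("L2", "P1", rel) == 0.0

    def test_empty_path_is_object_identity(self):
        assert hetesim_recursive("a", "a", []) == 1.0
        assert hetesim_recursive("a", "b", []) == 0.0

    def test_uniform_weights_reduce_to_neighbour_pair_average(self):
        # L reaches {P1,P2}; target P3's neighbours are {P2,P4}: one common
        # middle out of 2x2 neighbour pairs -> unnormalized score 1/4.
        rel_lp = {"L": {"P1": 1.0, "P2": 1.0}}
        rel_pp = {
            "P1": {"P2": 1.0},
            "P2": {"P1": 1.0, "P3": 1.0},
            "P3": {"P2": 1.0, "P4": 1.0},
            "P4": {"P3": 1.0},
        }
        raw = hetesim_recursive("L", "P3", [rel_lp, rel_pp], normalized=False)
        assert raw == pytest.approx(1 / 4)

    def test_unknown_object_rejected(self):
        rel = [{"L1": {"P1": 1.0}}, {"P1": {"P2": 1.0}, "P2": {"P1": 1.0}}]
        with pytest.raises(KeyError, match="unknown"):
            hetesim_recursive("L9", "P1", rel)
        with pytest.raises(KeyError, match="unknown"):
            hetesim_recursive("L1", "P9", rel)


def test_score_table_serialization_sorted_by_score(tmp_path):
    lp = make_lp([[1, 0], [0, 1]])
    pp = SimilarityMatrix(lp.protein_index, np.array([[1.0, 0.5], [0.5, 1.0]]))
    table = hetesim_lpp(lp, pp)
    out = tmp_path / "scores.tsv"
    table.to_tsv(out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "lncrna_id\tprotein_id\tscore"
    scores = [float(line.split("\t")[2]) for line in lines[1:]]
    assert scores == sorted(scores, reverse=True)
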