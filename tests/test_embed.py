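"""SPPMI computation, spectral factorization, and dimension selection."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from keser import (
    CooccurrenceMatrix,
    EmbeddingSet,
    RelationPair,
    RelationPairSet,
    SPPMIMatrix,
    Vocabulary,
    compute_sppmi,
    factorize,
    select_dim_metric,
    select_dim_variance,
)


def two_code_matrix(count=2):
    vocab = Vocabulary(("PheCode:A", "PheCode:B"))
    C = sp.csr_matrix(np.array([[0, count], [count, 0]]))
    return CooccurrenceMatrix(vocab, C)


def random_sppmi(p, seed, density=0.2):
    rng = np.random.default_rng(seed)
    M = sp.random(p, p, density=density, random_state=seed, data_rvs=rng.random)
    A = abs(M + M.T)
    vocab = Vocabulary(tuple(f"PheCode:{i:03d}" for i in range(p)))
    return SPPMIMatrix(vocab, sp.csr_matrix(A))


class TestSPPMI:
    def test_hand_example(self):
        S = compute_sppmi(two_code_matrix(), k=1.0)
        assert S.S[0, 1] == pytest.approx(np.log(2), abs=1e-12)
        assert S.S[0, 0] == 0.0

    def test_shift_two_floors_to_zero(self):
        assert compute_sppmi(two_code_matrix(), k=2.0).S.nnz == 0

    def test_independence_cell_is_zero(self):
        # C(w,c)|D| == C(w,.)C(c,.) for every cell of a rank-one count table
        vocab = Vocabulary(("A", "B"))
        C = CooccurrenceMatrix(vocab, sp.csr_matrix(np.array([[1, 1], [1, 1]])))
        assert compute_sppmi(C, k=1.0).S.nnz == 0

    def test_zero_row_sum_warns_not_errors(self):
        vocab = Vocabulary(("A", "B", "C"))
        M = np.zeros((3, 3), dtype=int)
        M[0, 1] = M[1, 0] = 2
        S = compute_sppmi(CooccurrenceMatrix(vocab, sp.csr_matrix(M)))
        assert S.S.toarray()[2].sum() == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 100), st.sampled_from([1.0, 2.0, 5.0, 10.0]))
    def test_entrywise_monotone_nonincreasing_in_k(self, seed, k):
        S1 = compute_sppmi(_random_counts(seed), k=1.0).S.toarray()
        Sk = compute_sppmi(_random_counts(seed), k=k).S.toarray()
        assert np.all(Sk <= S1 + 1e-12)
        assert np.all(Sk >= 0)


def _random_counts(seed, p=6):
    rng = np.random.default_rng(seed)
    M = rng.integers(0, 5, size=(p, p))
    M = M + M.T
    np.fill_diagonal(M, 0)
    vocab = Vocabulary(tuple(f"C{i}" for i in range(p)))
    return CooccurrenceMatrix(vocab, sp.csr_matrix(M))


class TestFactorize:
    def test_full_rank_reconstruction(self):
        S = random_sppmi(30, seed=1)
        emb = factorize(S, 30)
        assert np.linalg.norm(emb.reconstruct() - S.S.toarray()) <= 1e-8

    def test_truncation_equals_direct_factorization(self):
        S = random_sppmi(25, seed=2)
        full = factorize(S, 20)
        for d in (1, 5, 13):
            direct = factorize(S, d)
            assert np.array_equal(full.truncate(d).V, direct.V)
            assert np.array_equal(full.truncate(d).singular_values, direct.singular_values)

    def test_rank_one_closed_form(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal(10)
        u /= np.linalg.norm(u)
        sigma = 4.2
        vocab = Vocabulary(tuple(f"C{i}" for i in range(10)))
        S = SPPMIMatrix(vocab, sp.csr_matrix(sigma * np.outer(u, u)))
        emb = factorize(S, 1)
        v = emb.V[:, 0]
        expect = np.sqrt(sigma) * u
        assert min(np.linalg.norm(v - expect), np.linalg.norm(v + expect)) <= 1e-8
        # sign convention: largest-magnitude entry positive
        assert v[np.abs(v).argmax()] > 0

    def test_deterministic_bit_identical(self):
        S = random_sppmi(15, seed=4)
        assert np.array_equal(factorize(S, 10).V, factorize(S, 10).V)

    def test_d_out_of_range(self):
        S = random_sppmi(5, seed=5)
        with pytest.raises(ValueError):
            factorize(S, 6)

    def test_matches_independent_truncated_svd(self):
        """Cross-check singular values against scikit-learn's solver."""
        from sklearn.decomposition import TruncatedSVD

        S = random_sppmi(40, seed=6)
        emb = factorize(S, 5)
        ref = TruncatedSVD(n_components=5, algorithm="arpack", random_state=0).fit(
            sp.csr_matrix(S.S)
        )
        assert np.allclose(emb.singular_values, ref.singular_values_, atol=1e-8)

    def test_cosines_reflect_top_eigenspace_sign_pattern(self):
        # two blocks of mutually reinforcing codes: within-block cosines
        # positive, cross-block near zero at d=2
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 3.0
        A[2, 3] = A[3, 2] = 2.0
        vocab = Vocabulary(("a", "b", "c", "d"))
        emb = factorize(SPPMIMatrix(vocab, sp.csr_matrix(A)), 2)
        U = emb.rows_normalized()
        assert abs(U[0] @ U[2]) < 1e-8


class TestDimSelection:
    def test_variance_hand_example(self):
        # squared shares of (2,1,1): 4/6, 5/6, 6/6 -> need all three for 95%
        assert select_dim_variance([2, 1, 1], 0.95) == 3
        assert select_dim_variance([2, 1, 1], 0.6) == 1

    def test_fraction_one_is_full_rank(self):
        assert select_dim_variance([5, 3, 1e-3], 1.0) == 3

    def test_single_value(self):
        assert select_dim_variance([7.0], 0.5) == 1

    def test_unsquared_convention_flag(self):
        # unsquared shares of (2,1,1): 1/2, 3/4, 1 -> 0.7 needs d=2
        assert select_dim_variance([2, 1, 1], 0.7, squared=False) == 2
        assert select_dim_variance([2, 1, 1], 0.7, squared=True) == 2

    def test_empty_spectrum(self):
        with pytest.raises(ValueError):
            select_dim_variance([], 0.95)

    def test_metric_grid_of_one(self, toy_embeddings):
        pairs = RelationPairSet([RelationPair("PheCode:000", "PheCode:001")])
        assert select_dim_metric(toy_embeddings, pairs, "auc", [4], seed=0) == 4

    def test_planted_optimum_recovered(self):
        """Known pairs collinear only in the leading subspace: the metric
        grid search should land at (or next to) the planted dimension."""
        rng = np.random.default_rng(11)
        p, d_star, d = 20, 3, 10
        base = rng.standard_normal((p // 2, d_star)) * 3.0
        lead = np.repeat(base, 2, axis=0)  # pairs (2i, 2i+1) share leading coords
        tail = rng.standard_normal((p, d - d_star))
        V = np.hstack([lead, tail])
        vocab = Vocabulary(tuple(f"PheCode:{i:03d}" for i in range(p)))
        emb = EmbeddingSet(vocab, V)
        pairs = RelationPairSet(
            RelationPair(vocab.codes[2 * i], vocab.codes[2 * i + 1]) for i in range(p // 2)
        )
        got = select_dim_metric(emb, pairs, "auc", grid=[1, 2, 3, 4, 5, 8, 10], seed=1)
        assert got in (2, 3, 4)

    def test_unknown_metric(self, toy_embeddings):
        pairs = RelationPairSet([RelationPair("PheCode:000", "PheCode:001")])
        with pytest.raises(ValueError):
            select_dim_metric(toy_embeddings, pairs, "magic", [2])


def test_embedding_roundtrip(tmp_path):
    S = random_sppmi(12, seed=9)
    emb = factorize(S, 6)
    emb.save(tmp_path / "emb")
    again = EmbeddingSet.load(tmp_path / "emb")
    assert again.vocab.codes == emb.vocab.codes
    assert np.allclose(again.V, emb.V)
    assert np.allclose(again.singular_values, emb.singular_values)
    assert np.allclose(again.reconstruct(), emb.reconstruct())
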