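"""Compressed donor-repeat algebra: every operation must equal its dense
oracle (expand the matrix, then do ordinary linear algebra)."""

import numpy as np
import pytest

from conftest import random_grm, random_repeats
from sceqtl.air import (
    CompressedMatrix,
    GRMFactorization,
    RepeatVector,
    expand_dense,
    grm_eigendecompose,
    grm_from_genotypes,
    matmul_compressed,
    snp_gene_covariance,
    track_allocations,
    whiten,
    whiten_compressed,
)


class TestExpandDense:
    def test_replication(self):
        cm = CompressedMatrix([[1.0, 2.0]], RepeatVector([2, 3]))
        np.testing.assert_array_equal(expand_dense(cm), [[1, 1, 2, 2, 2]])

    def test_identity_when_counts_one(self):
        cm = CompressedMatrix([[1.0], [0.0]], RepeatVector([1]))
        np.testing.assert_array_equal(expand_dense(cm), [[1.0], [0.0]])

    def test_blocks_constant(self, rng):
        rv = RepeatVector([1, 2, 1, 3, 1])
        cm = CompressedMatrix(rng.normal(size=(3, 5)), rv)
        D = expand_dense(cm)
        assert D.shape == (3, 8)
        for d, sl in enumerate(rv.block_slices()):
            assert np.all(D[:, sl] == cm.values[:, [d]])

    def test_refuses_large_expansion(self):
        cm = CompressedMatrix(np.ones((1, 2)), RepeatVector([9000, 9000]))
        with pytest.raises(ValueError, match="refusing"):
            expand_dense(cm)
        assert expand_dense(cm, force=True).shape == (1, 18000)


class TestMatmul:
    def test_ones_vector(self):
        cm = CompressedMatrix([[1.0, 2.0]], RepeatVector([2, 3]))
        out = matmul_compressed(cm, np.ones((5, 1)))
        np.testing.assert_allclose(out, [[8.0]])

    def test_counts_on_diagonal(self):
        cm = CompressedMatrix(np.eye(2), RepeatVector([2, 3]))
        np.testing.assert_allclose(
            matmul_compressed(cm, mode="weighted-gram"), np.diag([2.0, 3.0])
        )

    def test_matches_dense(self, rng):
        rv = RepeatVector(rng.integers(1, 5, 6))
        cm = CompressedMatrix(rng.normal(size=(4, 6)), rv)
        D = expand_dense(cm)
        other = rng.normal(size=(rv.n_cell, 3))
        np.testing.assert_allclose(matmul_compressed(cm, other), D @ other, rtol=1e-10)
        np.testing.assert_allclose(
            matmul_compressed(cm, mode="weighted-gram"), D @ D.T, rtol=1e-10
        )

    def test_shape_mismatch(self, rng):
        cm = CompressedMatrix(np.ones((1, 2)), RepeatVector([2, 3]))
        with pytest.raises(ValueError):
            matmul_compressed(cm, np.ones((4, 1)))


class TestGrm:
    def test_two_donor_standardization(self):
        K = grm_from_genotypes(np.array([[0.0, 2.0]]), RepeatVector([1, 1]))
        np.testing.assert_allclose(K, [[1, -1], [-1, 1]])

    def test_matches_dense_gram(self, rng):
        rv = RepeatVector([1, 2, 3, 1])
        G = rng.integers(0, 3, (10, 4)).astype(float)
        G[G.std(axis=1) == 0] += rng.integers(0, 2, 4)
        G = G[G.std(axis=1) > 0]
        K = grm_from_genotypes(G, rv)
        Z = (G - G.mean(1, keepdims=True)) / G.std(1, keepdims=True)
        GE = np.repeat(Z, rv.counts, axis=1)
        K_cell = np.repeat(np.repeat(K, rv.counts, 0), rv.counts, 1)
        np.testing.assert_allclose(K_cell, GE.T @ GE / G.shape[0], atol=1e-10)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            grm_from_genotypes(np.array([[1.0, 1.0, 1.0]]), RepeatVector([1, 1, 1]))

    def test_eigenvalues_nonnegative(self, rng):
        for _ in range(20):
            rv = random_repeats(rng, n_donor=int(rng.integers(3, 10)))
            K, _ = random_grm(rng, rv)
            assert np.linalg.eigvalsh(K).min() > -1e-8


class TestEigendecompose:
    def test_identity_grm(self):
        fact = grm_eigendecompose(np.eye(2), RepeatVector([1, 1]))
        np.testing.assert_allclose(fact.eigenvalues, [1, 1])

    def test_single_donor_all_ones(self):
        fact = grm_eigendecompose(np.array([[1.0]]), RepeatVector([3]))
        np.testing.assert_allclose(fact.eigenvalues, [3.0])
        u = np.repeat(fact.donor_eigvecs[:, 0] / np.sqrt(3), 3)
        np.testing.assert_allclose(np.abs(u), np.full(3, 1 / np.sqrt(3)))

    def test_matches_dense_spectrum(self, rng):
        rv = RepeatVector([2, 1, 4, 1, 2])
        K, fact = random_grm(rng, rv)
        K_cell = np.repeat(np.repeat(K, rv.counts, 0), rv.counts, 1)
        dense_vals = np.sort(np.linalg.eigvalsh(K_cell))[::-1]
        np.testing.assert_allclose(fact.eigenvalues, dense_vals[: fact.rank], atol=1e-8)
        U = np.repeat(fact.donor_eigvecs / np.sqrt(rv.counts)[:, None], rv.counts, axis=0)
        np.testing.assert_allclose((U * fact.eigenvalues) @ U.T, K_cell, atol=1e-8)
        np.testing.assert_allclose(U.T @ U, np.eye(fact.rank), atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            grm_eigendecompose(np.array([[1.0, 0.5], [0.0, 1.0]]), RepeatVector([1, 1]))

    def test_never_materializes_cell_matrix(self, rng):
        rv = RepeatVector(rng.integers(50, 100, 10))
        K, _ = random_grm(rng, rv)
        with track_allocations() as t:
            grm_eigendecompose(K, rv)
        assert t.max_dim <= rv.n_donor


class TestWhiten:
    def test_lambda_zero_is_identity(self, rng):
        rv = RepeatVector([2, 3])
        _, fact = random_grm(rng, rv)
        Y = rng.normal(size=(2, rv.n_cell))
        np.testing.assert_array_equal(whiten(fact, 0.0, Y), Y)

    def test_single_block_scaling(self):
        fact = grm_eigendecompose(np.array([[1.0]]), RepeatVector([3]))
        y = np.ones(3)
        lam = 0.7
        out = whiten(fact, lam, y)
        np.testing.assert_allclose(out, (1 + 3 * lam) ** -0.5 * y)

    def test_inverse_roundtrip(self, rng):
        rv = random_repeats(rng, n_donor=6)
        _, fact = random_grm(rng, rv)
        Y = rng.normal(size=(3, rv.n_cell))
        W = whiten(fact, 2.5, Y)
        np.testing.assert_allclose(whiten(fact, 2.5, W, inverse=True), Y, atol=1e-10)

    def test_negative_lambda_rejected(self, rng):
        rv = RepeatVector([2, 2])
        _, fact = random_grm(rng, rv)
        with pytest.raises(ValueError):
            whiten(fact, -1.0, np.ones(4))

    def test_decorrelates_mvn_draws(self, rng):
        """Whitened draws from MVN(0, I + lam K) have near-identity covariance."""
        rv = RepeatVector([10, 10, 10, 10])
        K, fact = random_grm(rng, rv)
        lam = 2.0
        K_cell = np.repeat(np.repeat(K, rv.counts, 0), rv.counts, 1)
        A = np.linalg.cholesky(np.eye(rv.n_cell) + lam * K_cell)
        draws = (A @ rng.normal(size=(rv.n_cell, 5000))).T
        wd = whiten(fact, lam, draws)
        emp = wd.T @ wd / 5000
        se = 3.0 / np.sqrt(5000)
        assert np.abs(emp - np.eye(rv.n_cell)).max() < 3 * se + 0.05

    def test_compressed_consistent_with_cell_level(self, rng):
        rv = random_repeats(rng, n_donor=5)
        _, fact = random_grm(rng, rv)
        V = rng.normal(size=(3, rv.n_donor))
        wc = whiten_compressed(fact, 1.3, V)
        wd = whiten(fact, 1.3, np.repeat(V, rv.counts, axis=1))
        np.testing.assert_allclose(np.repeat(wc, rv.counts, axis=1), wd, atol=1e-10)


class TestSnpGeneCovariance:
    def test_two_point(self):
        rv = RepeatVector([1, 1])
        cov = snp_gene_covariance([[0.0, 2.0]], [[0.0, 2.0]], rv)
        np.testing.assert_allclose(cov, [[1.0]])

    def test_constant_gene_zero(self, rng):
        rv = RepeatVector([2, 3])
        G = rng.integers(0, 3, (4, 2)).astype(float)
        Y = np.full((2, rv.n_cell), 3.14)
        np.testing.assert_allclose(snp_gene_covariance(G, Y, rv), 0.0, atol=1e-12)

    def test_matches_dense(self, rng):
        rv = RepeatVector([2, 3, 1, 2])
        G = rng.integers(0, 3, (6, 4)).astype(float)
        Y = rng.normal(size=(5, rv.n_cell))
        GE = np.repeat(G, rv.counts, axis=1)
        dense = np.array(
            [
                [np.mean((GE[j] - GE[j].mean()) * (Y[i] - Y[i].mean())) for i in range(5)]
                for j in range(6)
            ]
        )
        np.testing.assert_allclose(snp_gene_covariance(G, Y, rv), dense, atol=1e-10)


def test_randomized_dense_equivalence(rng):
    """All compressed ops agree with the dense oracle on 100 random instances."""
    for _ in range(100):
        rv = random_repeats(rng)
        n_rows = int(rng.integers(1, 5))
        cm = CompressedMatrix(rng.normal(size=(n_rows, rv.n_donor)), rv)
        D = expand_dense(cm, force=True)
        other = rng.normal(size=(rv.n_cell, 2))
        np.testing.assert_allclose(matmul_compressed(cm, other), D @ other, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(
            matmul_compressed(cm, mode="weighted-gram"), D @ D.T, rtol=1e-8, atol=1e-8
        )
        K, fact = random_grm(rng, rv, n_snp=15)
        K_cell = np.repeat(np.repeat(K, rv.counts, 0), rv.counts, 1)
        U = np.repeat(fact.donor_eigvecs / np.sqrt(rv.counts)[:, None], rv.counts, axis=0)
        np.testing.assert_allclose((U * fact.eigenvalues) @ U.T, K_cell, atol=1e-8)
        lam = float(rng.uniform(0.1, 3.0))
        y = rng.normal(size=rv.n_cell)
        # dense whitening oracle: eigendecompose the cell-level covariance
        vals, vecs = np.linalg.eigh(np.eye(rv.n_cell) + lam * K_cell)
        Wd = vecs @ np.diag(vals**-0.5) @ vecs.T
        np.testing.assert_allclose(whiten(fact, lam, y), Wd @ y, atol=1e-7)
        Ymat = rng.normal(size=(2, rv.n_cell))
        GE = np.repeat(rng.integers(0, 3, (3, rv.n_donor)).astype(float), rv.counts, axis=1)
        dense_cov = np.array(
            [
                [np.mean((g - g.mean()) * (yy - yy.mean())) for yy in Ymat]
                for g in GE
            ]
        )
        Gd = GE[:, np.r_[0, np.cumsum(rv.counts)[:-1]]]
        np.testing.assert_allclose(
            snp_gene_covariance(Gd, Ymat, rv), dense_cov, atol=1e-10
        )


def test_identity_factorization_is_noop(rng):
    rv = RepeatVector([2, 3])
    fact = GRMFactorization.identity(rv)
    Y = rng.normal(size=(2, 5))
    np.testing.assert_array_equal(whiten(fact, 5.0, Y), Y)
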