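"""Donor-compressed matrix algebra for population-scale single-cell data.

In population-scale scRNA-seq every cell of a donor carries the same germline
genotype, so cell-level matrices built from genotypes consist of donor-level
columns replicated once per cell.  This module stores only the donor-level
values together with the per-donor cell counts and performs the linear algebra
the eQTL linear mixed model needs -- Gram products, GRM estimation and
eigendecomposition, whitening by the GRM, and SNP-gene covariances -- directly
on the compressed representation, with results numerically identical to the
dense computation on the expanded matrix.

Cells are always assumed to be in donor-block order: all cells of donor 0
first, then donor 1, etc.  :mod:`sceqtl.data` enforces this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RepeatVector",
    "CompressedMatrix",
    "GRMFactorization",
    "expand_dense",
    "matmul_compressed",
    "grm_from_genotypes",
    "grm_eigendecompose",
    "whiten",
    "whiten_compressed",
    "snp_gene_covariance",
    "track_allocations",
    "max_tracked_dim",
]

# ---------------------------------------------------------------------------
# allocation instrumentation: ops report the largest dimension of arrays they
# allocate so tests can assert no cell-by-cell matrix is ever materialized.

_ALLOC_TRACKER: list[int] | None = None


class track_allocations:
    """Context manager recording the largest array dimension allocated by ops."""

    def __enter__(self):
        global _ALLOC_TRACKER
        self._prev = _ALLOC_TRACKER
        _ALLOC_TRACKER = []
        self.dims = _ALLOC_TRACKER
        return self

    def __exit__(self, *exc):
        global _ALLOC_TRACKER
        _ALLOC_TRACKER = self._prev
        return False

    @property
    def max_dim(self) -> int:
        return max(self.dims, default=0)


def _note_alloc(*shape: int) -> None:
    if _ALLOC_TRACKER is not None:
        _ALLOC_TRACKER.extend(int(s) for s in shape)


def max_tracked_dim(tracker: track_allocations) -> int:
    return tracker.max_dim


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatVector:
    """Number of cells per donor, in the shared fixed donor order."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(c < 1):
            raise ValueError("every donor must have at least one cell")
        object.__setattr__(self, "counts", c)

    @property
    def n_donor(self) -> int:
        return int(self.counts.size)

    @property
    def n_cell(self) -> int:
        return int(self.counts.sum())

    def cell_donor_index(self) -> np.ndarray:
        """Donor index of each cell (length n_cell, donor-block order)."""
        return np.repeat(np.arange(self.n_donor), self.counts)

    def block_slices(self) -> list[slice]:
        ends = np.cumsum(self.counts)
        starts = ends - self.counts
        return [slice(int(a), int(b)) for a, b in zip(starts, ends)]

    def donor_sum(self, y: np.ndarray) -> np.ndarray:
        """Sum the trailing (cell) axis of ``y`` within donor blocks.

        Accepts (..., n_cell) and returns (..., n_donor).  O(size of y).
        """
        y = np.asarray(y)
        if y.shape[-1] != self.n_cell:
            raise ValueError("trailing axis must have n_cell entries")
        ends = np.cumsum(self.counts)[:-1]
        return np.add.reduceat(y, np.r_[0, ends], axis=-1)

    def expand(self, v: np.ndarray) -> np.ndarray:
        """Replicate the trailing (donor) axis of ``v`` to cell level."""
        v = np.asarray(v)
        if v.shape[-1] != self.n_donor:
            raise ValueError("trailing axis must have n_donor entries")
        return np.repeat(v, self.counts, axis=-1)


@dataclass(frozen=True)
class CompressedMatrix:
    """A rows x n_cell matrix stored as donor-level values plus repeats.

    Column ``d`` of ``values`` stands for ``repeats.counts[d]`` identical
    cell-level columns in donor-block order.
    """

    values: np.ndarray
    repeats: RepeatVector

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != self.repeats.n_donor:
            raise ValueError(
                f"values has {v.shape[1]} columns, repeats has "
                f"{self.repeats.n_donor} donors"
            )
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.values.shape[0], self.repeats.n_cell)


# expand_dense exists only as the testing oracle; it refuses to build large
# cell-level matrices unless forced.
_EXPAND_LIMIT = 10_000


def expand_dense(cm: CompressedMatrix, force: bool = False) -> np.ndarray:
    """Materialize the cell-level matrix (testing oracle only)."""
    if cm.repeats.n_cell > _EXPAND_LIMIT and not force:
        raise ValueError(
            f"refusing to expand to {cm.repeats.n_cell} cells "
            f"(> {_EXPAND_LIMIT}); pass force=True if you really mean it"
        )
    return np.repeat(cm.values, cm.repeats.counts, axis=1)


def matmul_compressed(
    cm: CompressedMatrix,
    other: "np.ndarray | CompressedMatrix | None" = None,
    mode: str = "right-multiply",
) -> np.ndarray:
    """Multiply a compressed matrix without expanding it.

    mode="right-multiply": ``X @ other`` where ``other`` is a cell-level
    (n_cell x m) dense array; computed via donor sums of ``other``.

    mode="weighted-gram": ``X @ X.T`` (or ``X @ Y.T`` when ``other`` is a
    second CompressedMatrix on the same repeats), computed as
    ``V diag(counts) W.T`` at donor level -- O(rows^2 * n_donor), no
    n_cell-sized intermediate.
    """
    rv = cm.repeats
    if mode == "right-multiply":
        other = np.asarray(other, dtype=float)
        if other.shape[0] != rv.n_cell:
            raise ValueError("cell-level shape mismatch")
        summed = rv.donor_sum(other.T).T  # (n_donor, m)
        out = cm.values @ summed
        _note_alloc(*out.shape)
        return out
    if mode == "weighted-gram":
        if other is None:
            w = cm
        elif isinstance(other, CompressedMatrix):
            if not np.array_equal(other.repeats.counts, rv.counts):
                raise ValueError("operands must share repeats")
            w = other
        else:
            raise TypeError("weighted-gram needs a CompressedMatrix operand")
        out = (cm.values * rv.counts) @ w.values.T
        _note_alloc(*out.shape)
        return out
    raise ValueError(f"unknown mode {mode!r}")


def grm_from_genotypes(G: np.ndarray, repeats: RepeatVector) -> np.ndarray:
    """Donor-level genetic relationship matrix from donor genotype dosages.

    Each SNP row is standardized to mean 0 / variance 1 across donors, then
    K_d = Ghat.T Ghat / n_SNP.  The implied cell-level GRM is the donor-block
    expansion of K_d.  Monomorphic SNPs are an error: QC must remove them.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[1] != repeats.n_donor:
        raise ValueError("G must have one column per donor")
    mu = G.mean(axis=1, keepdims=True)
    sd = G.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd[:, 0] == 0)
        raise ValueError(
            f"monomorphic SNP must be removed by QC (zero variance rows: {bad[:5]})"
        )
    Z = (G - mu) / sd
    K = (Z.T @ Z) / G.shape[0]
    _note_alloc(*K.shape)
    return K


@dataclass(frozen=True)
class GRMFactorization:
    """Eigendecomposition of the implicit cell-level GRM, at donor resolution.

    The cell-level eigenvector u_r is constant within each donor block with
    per-cell value ``donor_eigvecs[d, r] / sqrt(counts[d])``; eigenvalues are
    shared with the cell-level matrix (all remaining cell-level eigenvalues
    are zero).
    """

    eigenvalues: np.ndarray
    donor_eigvecs: np.ndarray
    repeats: RepeatVector

    @property
    def rank(self) -> int:
        return int(self.eigenvalues.size)

    @classmethod
    def identity(cls, repeats: RepeatVector) -> "GRMFactorization":
        """Factorization standing for K = 0 (whitening is a no-op)."""
        return cls(
            eigenvalues=np.zeros(0),
            donor_eigvecs=np.zeros((repeats.n_donor, 0)),
            repeats=repeats,
        )

    def project(self, Y: np.ndarray) -> np.ndarray:
        """Eigenbasis coordinates u_r . y for each row of cell-level Y."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        s = self.repeats.donor_sum(Y)  # (vars, n_donor)
        return (s / np.sqrt(self.repeats.counts)) @ self.donor_eigvecs

    def project_compressed(self, V: np.ndarray) -> np.ndarray:
        """Eigenbasis coordinates for donor-constant rows (donor values V)."""
        V = np.atleast_2d(np.asarray(V, dtype=float))
        return (V * np.sqrt(self.repeats.counts)) @ self.donor_eigvecs


def grm_eigendecompose(K_d: np.ndarray, repeats: RepeatVector) -> GRMFactorization:
    """Eigendecompose the implicit cell-level GRM in O(n_donor^3).

    With C = diag(counts), the nonzero spectrum of the cell-level GRM equals
    that of M = C^{1/2} K_d C^{1/2}; the eigenvector for (mu_r, v_r) of M is
    donor-block constant with per-cell value v_r[d] / sqrt(counts[d]).
    Eigenvalues within -1e-8 of zero are clipped to 0; more negative ones are
    an error (the GRM must be PSD).
    """
    K_d = np.asarray(K_d, dtype=float)
    n = repeats.n_donor
    if K_d.shape != (n, n):
        raise ValueError("K_d must be n_donor x n_donor")
    if not np.allclose(K_d, K_d.T, atol=1e-8):
        raise ValueError("K_d must be symmetric")
    sq = np.sqrt(repeats.counts.astype(float))
    M = K_d * sq[:, None] * sq[None, :]
    _note_alloc(*M.shape)
    mu, V = np.linalg.eigh(M)
    scale = max(1.0, float(np.abs(mu).max(initial=0.0)))
    if mu.min(initial=0.0) < -1e-8 * scale:
        raise ValueError(f"GRM has negative eigenvalue {mu.min():.3e} beyond tolerance")
    mu = np.clip(mu, 0.0, None)
    order = np.argsort(mu)[::-1]
    return GRMFactorization(eigenvalues=mu[order], donor_eigvecs=V[:, order], repeats=repeats)


def _whiten_weights(fact: GRMFactorization, lam: float, half: bool = True) -> np.ndarray:
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    denom = 1.0 + lam * fact.eigenvalues
    return 1.0 - denom ** (-0.5 if half else -1.0)


def whiten(fact: GRMFactorization, lam: float, Y: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Decorrelate rows of cell-level Y under covariance sigma^2 (I + lam K).

    Each row y becomes y - sum_r u_r (1 - (1 + lam s_r)^{-1/2}) (u_r . y), so
    that y ~ MVN(0, sigma^2 (I + lam K)) maps to MVN(0, sigma^2 I).  With
    ``inverse=True`` the exact inverse (scale components by (1+lam s_r)^{1/2})
    is applied instead.  Cost O(vars (n_donor^2 + n_cell)).
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    single = np.asarray(Y).ndim == 1
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if fact.rank == 0 or lam == 0:
        return Y[0] if single else Y.copy()
    coords = fact.project(Y)  # (vars, rank)
    denom = 1.0 + lam * fact.eigenvalues
    w = 1.0 - (denom ** 0.5 if inverse else denom ** -0.5)
    adj = (coords * w) @ fact.donor_eigvecs.T  # (vars, n_donor)
    out = Y - fact.repeats.expand(adj / np.sqrt(fact.repeats.counts))
    _note_alloc(*out.shape)
    return out[0] if single else out


def whiten_compressed(fact: GRMFactorization, lam: float, V: np.ndarray) -> np.ndarray:
    """Whiten donor-constant rows; returns donor-level values (stays compressed).

    Whitening preserves donor-block structure because every eigenvector is
    donor-block constant, so a compressed row stays compressed.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if lam == 0 or fact.rank == 0:
        return V.copy()
    coords = fact.project_compressed(V)
    w = _whiten_weights(fact, lam)
    adj = (coords * w) @ fact.donor_eigvecs.T
    out = V - adj / np.sqrt(fact.repeats.counts)
    _note_alloc(*out.shape)
    return out


def snp_gene_covariance(G: np.ndarray, Y: np.ndarray, repeats: RepeatVector) -> np.ndarray:
    """Cell-level covariance between expanded genotypes and expression.

    Entry (j, i) is the population covariance (divide by n_cell) between SNP
    j's expanded genotype and gene i's expression across cells.  Computed via
    per-gene donor sums then donor-level dot products:
    O(n_gene (n_SNP n_donor + n_cell)).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if G.shape[1] != repeats.n_donor or Y.shape[1] != repeats.n_cell:
        raise ValueError("shape mismatch")
    n = repeats.n_cell
    ysum_d = repeats.donor_sum(Y)  # (n_gene, n_donor)
    ytot = ysum_d.sum(axis=1)  # (n_gene,)
    gmean = (G @ repeats.counts) / n  # cell-level mean of each SNP
    cov = (G @ ysum_d.T) / n - np.outer(gmean, ytot / n)
    _note_alloc(*cov.shape)
    return cov
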