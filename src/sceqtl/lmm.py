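"""Linear-mixed-model single-cell eQTL mapping.

Model per gene and SNP: y = alpha C + beta x + eps with
eps ~ MVN(0, sigma^2 (I + lambda K)), where K is the cell-level GRM implied
by donor genotypes and lambda is the ratio of donor-structured to i.i.d.
cell-level variance.  Mapping proceeds in the standard two steps: (1) lambda
is estimated per gene by maximum likelihood under the null (beta = 0); genes
whose donor-level share of unexplained variance exceeds 75% (lambda > 3) are
excluded as likely batch-effect artifacts; (2) with lambda fixed, y, x and the
covariates are whitened by the GRM eigenbasis, covariates are projected out,
and the squared correlation (conditional R^2) between the residuals gives the
likelihood-ratio test, whose null distribution is Beta(1/2, dof2/2), well
approximated by chi^2_1 on dof2 * R^2.

Everything runs at donor-level cost: genotypes stay compressed and whitening
preserves their donor-block structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from sceqtl.air import (
    GRMFactorization,
    RepeatVector,
    whiten,
    whiten_compressed,
)
from sceqtl.data import Dataset
from sceqtl.qc import NormalizedExpression

__all__ = [
    "GrmOption",
    "donor_variance_share",
    "LambdaProfile",
    "estimate_lambda_null",
    "pvalue_from_r2",
    "build_covariates",
    "map_sceqtl",
    "genotype_pcs",
    "negative_control_trans",
    "cis_window_mask",
    "CIS_WINDOW",
    "LAMBDA_EXCLUDE",
]

CIS_WINDOW = 1_000_000  # |pos - TSS| <= 1 Mb, inclusive at the boundary
LAMBDA_EXCLUDE = 3.0  # donor-level variance share > 75%


@dataclass(frozen=True)
class GrmOption:
    """GRM choice for mapping: identity (plain OLS) or genotype-estimated,
    optionally with top genotype principal components as covariates."""

    kind: str = "genotype"
    n_pc_covariates: int = 0

    def __post_init__(self):
        if self.kind not in ("identity", "genotype"):
            raise ValueError("kind must be 'identity' or 'genotype'")


def donor_variance_share(lam: float) -> float:
    """Fraction of unexplained variance attributable to donor-level variation.

    Under eps ~ MVN(0, sigma^2 (I + lambda K)) with unit-diagonal donor blocks
    the donor component contributes lambda/(1 + lambda) of the total; the
    exclusion threshold lambda = 3 corresponds to a 75% share.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return lam / (1.0 + lam)


# ---------------------------------------------------------------------------
# lambda estimation


class LambdaProfile:
    """Profiled null log-likelihood of lambda for one response.

    Caches eigenbasis projections of y and the covariates so each lambda
    evaluation costs O(rank * n_cov^2), independent of n_cell.
    """

    def __init__(self, fact: GRMFactorization, y: np.ndarray, C: np.ndarray):
        y = np.asarray(y, dtype=float).ravel()
        C = np.atleast_2d(np.asarray(C, dtype=float))
        self.n = y.size
        self.s = fact.eigenvalues
        self.a = fact.project(y[None, :])[0]  # (rank,)
        self.A = fact.project(C)  # (k, rank)
        self.yy = float(y @ y)
        self.Cy = C @ y
        self.CC = C @ C.T

    def rss(self, lam: float) -> float:
        w = 1.0 - 1.0 / (1.0 + lam * self.s)
        yy = self.yy - (self.a**2 * w).sum()
        Cy = self.Cy - self.A @ (self.a * w)
        CC = self.CC - (self.A * w) @ self.A.T
        sol = np.linalg.lstsq(CC, Cy, rcond=None)[0]
        return float(yy - Cy @ sol)

    def loglik(self, lam: float) -> float:
        rss = self.rss(lam)
        if not np.isfinite(rss) or rss <= 0:
            raise FloatingPointError("non-finite likelihood")
        logdet = np.log1p(lam * self.s).sum()
        n = self.n
        return -0.5 * (n * np.log(2 * np.pi * rss / n) + logdet + n)


_GOLDEN = (np.sqrt(5) - 1) / 2


def _golden_max(f, lo: float, hi: float, tol: float) -> float:
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2


def estimate_lambda_null(
    y: np.ndarray,
    C: np.ndarray,
    fact: GRMFactorization,
    grid_size: int = 100,
    bounds: tuple = (1e-4, 1e4),
    tol: float = 1e-4,
) -> tuple[float, bool]:
    """ML estimate of lambda under the null model (beta = 0).

    Maximizes the Gaussian log-likelihood with sigma^2 profiled analytically
    over a logarithmic grid on ``bounds`` plus lambda = 0, then refines with
    golden-section search (tolerance ``tol`` in log-lambda).  Returns
    (lambda_hat, excluded_flag) where the flag marks lambda_hat > 3.
    """
    if fact.rank == 0:
        return 0.0, False
    prof = LambdaProfile(fact, y, C)
    grid = np.log(np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), grid_size))
    ll = np.array([prof.loglik(np.exp(g)) for g in grid])
    ll0 = prof.loglik(0.0)
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    log_lam = _golden_max(lambda g: prof.loglik(np.exp(g)), lo, hi, tol)
    lam = float(np.exp(log_lam))
    if ll0 >= prof.loglik(lam):
        lam = 0.0
    return lam, lam > LAMBDA_EXCLUDE


# ---------------------------------------------------------------------------
# p values


def pvalue_from_r2(r2, dof2, method: str = "chi2"):
    """P value of the conditional R^2 under the null.

    ``beta``: exact finite-sample survival of Beta(1/2, dof2/2) at r2.
    ``chi2`` (default): survival of chi^2_1 at dof2 * r2, the large-sample
    approximation.  Monotone decreasing in r2 for either method.
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("r2 must lie in [0, 1]")
    if method == "beta":
        return scipy.stats.beta.sf(r2, 0.5, np.asarray(dof2) / 2.0)
    if method == "chi2":
        return scipy.stats.chi2.sf(np.asarray(dof2) * r2, 1)
    raise ValueError("method must be 'beta' or 'chi2'")


# ---------------------------------------------------------------------------
# covariates


def genotype_pcs(G: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal components of the standardized donor genotype matrix.

    Donors are observations.  Returns a (k, n_donor) array of PC scores, each
    standardized to mean 0, variance 1 (mutually orthogonal by construction).
    Expand to cells via repeats when used as covariates.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n_donor = G.shape[1]
    if k >= n_donor:
        raise ValueError("k must be smaller than the number of donors")
    if k == 0:
        return np.zeros((0, n_donor))
    mu = G.mean(axis=1, keepdims=True)
    sd = G.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    Z = (G[keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)  # donors x snps
    pcs = U[:, :k].T  # orthonormal, mean-zero columns
    return pcs * np.sqrt(n_donor)


def build_covariates(
    ds: Dataset, norm: NormalizedExpression, grm_opt: GrmOption | None = None
) -> np.ndarray:
    """Stack intercept, technical covariates, user covariates, and (optionally)
    genotype PCs expanded to cells.  Rows are deduplicated conservatively:
    the intercept row of ds.covariates is dropped (already added here)."""
    rows = [np.ones((1, ds.n_cell)), norm.tech_covariates]
    user = ds.covariates[1:] if ds.covariates.shape[0] > 0 else np.zeros((0, ds.n_cell))
    rows.append(user)
    if grm_opt is not None and grm_opt.n_pc_covariates > 0:
        pcs = genotype_pcs(ds.genotypes, grm_opt.n_pc_covariates)
        rows.append(ds.repeats.expand(pcs))
    return np.vstack(rows)


def cis_window_mask(snp_meta: pd.DataFrame, gene_row) -> np.ndarray:
    """Boolean mask of SNPs within the 1 Mb cis window of one gene."""
    same = (snp_meta["chrom"] == gene_row["chrom"]).to_numpy()
    dist = np.abs(snp_meta["pos"].to_numpy() - gene_row["tss"])
    return same & (dist <= CIS_WINDOW)


# ---------------------------------------------------------------------------
# association scan


def grm_factorization(ds: Dataset, grm_opt: GrmOption) -> GRMFactorization:
    """Build the GRM eigendecomposition the scan will whiten with."""
    from sceqtl.air import grm_eigendecompose, grm_from_genotypes

    rv = ds.repeats
    if grm_opt.kind == "identity":
        return GRMFactorization.identity(rv)
    K_d = grm_from_genotypes(ds.genotypes.astype(float), rv)
    return grm_eigendecompose(K_d, rv)


def map_sceqtl(
    ds: Dataset,
    norm: NormalizedExpression,
    fact: GRMFactorization,
    grm_opt: GrmOption = GrmOption(),
    trans_keep_p: float | None = 1e-4,
    method: str = "chi2",
    lambda_hats: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every (SNP, gene) pair; emit all cis records and trans records
    with p < trans_keep_p (None keeps everything).

    Returns a table with columns snp, gene, cis_or_trans, beta, r2, p,
    lambda_hat, dof2.  beta is the effect per alt-allele dosage on the
    normalized (variance-standardized) expression scale.
    """
    if ds.gene_meta["id"].duplicated().any() or ds.snp_meta["id"].duplicated().any():
        raise ValueError("duplicate gene or SNP ids")
    rv = ds.repeats
    C = build_covariates(ds, norm, grm_opt)
    k = C.shape[0]
    dof2 = ds.n_cell - k - 1
    Y = norm.logexpr
    G = ds.genotypes.astype(float)

    if lambda_hats is None:
        lam_flags = [estimate_lambda_null(Y[i], C, fact) for i in range(ds.n_gene)]
        lambda_hats = np.array([lf[0] for lf in lam_flags])
        excluded = np.array([lf[1] for lf in lam_flags])
    else:
        lambda_hats = np.asarray(lambda_hats, dtype=float)
        excluded = lambda_hats > LAMBDA_EXCLUDE
    if excluded.all():
        raise ValueError("no genes survive the lambda exclusion")

    snp_ids = ds.snp_meta["id"].to_numpy()
    frames = []
    for i in np.flatnonzero(~excluded):
        lam = lambda_hats[i]
        beta, r2 = _scan_one_gene(Y[i], C, G, fact, rv, lam)
        p = pvalue_from_r2(np.clip(r2, 0.0, 1.0), dof2, method)
        cis = cis_window_mask(ds.snp_meta, ds.gene_meta.iloc[i])
        keep = cis.copy()
        if trans_keep_p is None:
            keep[:] = True
        else:
            keep |= (~cis) & (p < trans_keep_p)
        frames.append(
            pd.DataFrame(
                {
                    "snp": snp_ids[keep],
                    "gene": ds.gene_meta["id"].iloc[i],
                    "cis_or_trans": np.where(cis[keep], "cis", "trans"),
                    "beta": beta[keep],
                    "r2": r2[keep],
                    "p": p[keep],
                    "lambda_hat": lam,
                    "dof2": dof2,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["snp", "gene", "cis_or_trans", "beta", "r2", "p", "lambda_hat", "dof2"]
    )
    return out.sort_values(["gene", "snp"], kind="stable").reset_index(drop=True)


def _scan_one_gene(y, C, G, fact: GRMFactorization, rv: RepeatVector, lam: float):
    """Whiten, residualize on covariates, and test all SNPs against one gene.

    Genotypes stay at donor level throughout (whitening preserves the
    donor-block structure); per-gene cost is
    O(n_cell * n_cov^2 + n_SNP * n_donor * n_cov).
    """
    yw = whiten(fact, lam, y)
    Cw = whiten(fact, lam, C)
    Q, _ = np.linalg.qr(Cw.T)  # (n_cell, k)
    yr = yw - Q @ (Q.T @ yw)
    ynorm2 = float(yr @ yr)
    ysum_d = rv.donor_sum(yr)  # (n_donor,)
    Xw = whiten_compressed(fact, lam, G)  # (n_snp, n_donor)
    SQ = rv.donor_sum(Q.T)  # (k, n_donor)
    coef = Xw @ SQ.T  # (n_snp, k)
    xnorm2 = (Xw**2 * rv.counts).sum(axis=1) - (coef**2).sum(axis=1)
    xy = Xw @ ysum_d
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xnorm2 > 1e-12, xy / xnorm2, 0.0)
        r2 = np.where(
            (xnorm2 > 1e-12) & (ynorm2 > 0), xy**2 / np.maximum(xnorm2 * ynorm2, 1e-300), 0.0
        )
    return beta, r2


# ---------------------------------------------------------------------------
# diagnostics


def negative_control_trans(
    ds: Dataset,
    norm: NormalizedExpression,
    fact: GRMFactorization,
    cis_records: pd.DataFrame,
    grm_opt: GrmOption = GrmOption(),
    method: str = "chi2",
) -> pd.DataFrame:
    """QQ table of trans P values for negative-control SNPs.

    SNPs whose every cis association has raw P > 0.5 are mapped against genes
    on other chromosomes only; observed sorted P values are paired with
    uniform expected quantiles (i - 0.5) / m, both also as -log10 columns.
    """
    cis = cis_records[cis_records["cis_or_trans"] == "cis"]
    worst = cis.groupby("snp")["p"].min()
    controls = set(worst[worst > 0.5].index)
    # SNPs with no cis record at all are not negative controls (never tested)
    if not controls:
        raise ValueError("no SNP qualifies as a negative control (all cis P > 0.5)")
    snp_mask = ds.snp_meta["id"].isin(controls).to_numpy()
    sub = ds.subset(snps=snp_mask)
    full = map_sceqtl(sub, norm, fact, grm_opt, trans_keep_p=None, method=method)
    # other chromosomes only
    chrom_of_gene = dict(zip(ds.gene_meta["id"], ds.gene_meta["chrom"]))
    chrom_of_snp = dict(zip(sub.snp_meta["id"], sub.snp_meta["chrom"]))
    diff = np.array(
        [chrom_of_snp[s] != chrom_of_gene[g] for s, g in zip(full["snp"], full["gene"])]
    )
    pvals = np.sort(full.loc[diff, "p"].to_numpy())
    m = pvals.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {
            "expected": expected,
            "observed": pvals,
            "expected_nlog10": -np.log10(expected),
            "observed_nlog10": -np.log10(np.maximum(pvals, 1e-300)),
        }
    )
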