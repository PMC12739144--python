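"""Cell-state-specific eQTL mapping.

Extends the LMM with every linear and quadratic interaction between genotype
x, a binary cell-state indicator s, and the other covariates C:

    y = a0 + a1 (C,s,x) + a2 (C,s) kron (C,s) + a3 C kron x + a4 x_dom
        + beta s kron x + eps

where ``kron`` is the modified row-wise Kronecker product (element-wise
products of row pairs; self-products keep unique pairs only) and x_dom is the
dominant-allele indicator standing in for x kron x, which spans the same
space for biallelic dosages.  The tested term s kron x is always last;
everything else is a covariate.  Testing follows the same two-step recipe as
the marginal scan: lambda is re-estimated per (gene, SNP) under the extended
null (all terms except s kron x), then the tested term's conditional R^2
gives the P value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sceqtl.air import GRMFactorization, whiten
from sceqtl.data import Dataset
from sceqtl.lmm import (
    LambdaProfile,
    _golden_max,
    cis_window_mask,
    pvalue_from_r2,
    LAMBDA_EXCLUDE,
)
from sceqtl.qc import NormalizedExpression

logger = logging.getLogger(__name__)

__all__ = [
    "modified_kron",
    "dominant_encode",
    "InteractionDesign",
    "build_interaction_design",
    "map_interaction",
]


def modified_kron(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Modified row-wise Kronecker product.

    Distinct operands give n_A * n_B rows ordered (A1*B1, A1*B2, ...,
    A2*B1, ...); the self-product (B is None or A) keeps only unique row
    pairs: (A1*A1, ..., A1*An, A2*A2, ..., A2*An, ..., An*An).  Vectors are
    treated as 1-row matrices.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    selfprod = B is None or B is A
    B = A if selfprod else np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("operands must have the same number of columns")
    if selfprod:
        rows = [A[i] * A[j] for i in range(A.shape[0]) for j in range(i, A.shape[0])]
    else:
        rows = [a * b for a in A for b in B]
    return np.array(rows).reshape(-1, A.shape[1])


def dominant_encode(x: np.ndarray) -> np.ndarray:
    """Dominant-allele indicator: 1 where the dosage is nonzero."""
    x = np.asarray(x)
    if not np.isin(x, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    return (x != 0).astype(float)


class InteractionDesign:
    """Assembled design matrix with the tested term last.

    ``design`` rows follow the fixed order intercept, (C, s, x),
    (C,s) kron (C,s), C kron x, x_dom, s kron x; degenerate covariate rows
    (constant, or duplicates of an earlier row up to scaling) are dropped
    with a log entry -- never the tested term.
    """

    def __init__(self, design: np.ndarray, labels: list, dropped: list):
        self.design = design
        self.labels = labels
        self.dropped = dropped

    @property
    def null_design(self) -> np.ndarray:
        return self.design[:-1]

    @property
    def tested(self) -> np.ndarray:
        return self.design[-1]


def _dedup(rows: list, labels: list) -> tuple[np.ndarray, list, list]:
    """Drop constant rows (other than the leading intercept) and rows equal to
    an earlier-kept row up to scaling; first kept wins."""
    kept, kept_labels, dropped = [], [], []
    for row, lab in zip(rows, labels):
        row = np.asarray(row, dtype=float)
        norm = np.linalg.norm(row)
        dup = False
        if lab != "intercept":
            if np.ptp(row) == 0:
                dup = True
            else:
                for prev in kept:
                    pn = np.linalg.norm(prev)
                    if pn > 0 and norm > 0 and abs(abs(prev @ row) / (pn * norm) - 1) < 1e-12:
                        dup = True
                        break
        if dup:
            dropped.append(lab)
        else:
            kept.append(row)
            kept_labels.append(lab)
    return np.array(kept), kept_labels, dropped


def build_interaction_design(C: np.ndarray, s: np.ndarray, x: np.ndarray) -> InteractionDesign:
    """Assemble the full interaction design for one SNP.

    ``C`` excludes the intercept (added as the first row here), ``s`` is the
    binary cell-state indicator, ``x`` the dosage vector.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    s = np.asarray(s, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if not np.isin(s, (0, 1)).all():
        raise ValueError("cell state must be binary")
    n = s.size
    if C.shape[0] and C.shape[1] != n:
        raise ValueError("covariate shape mismatch")
    Cs = np.vstack([C, s[None, :]])
    rows = [np.ones(n)]
    labels = ["intercept"]
    for j in range(C.shape[0]):
        rows.append(C[j])
        labels.append(f"C{j}")
    rows.append(s)
    labels.append("s")
    rows.append(x)
    labels.append("x")
    quad = modified_kron(Cs)
    nq = Cs.shape[0]
    pairs = [(i, j) for i in range(nq) for j in range(i, nq)]
    qlabels = [
        f"{'s' if i == nq - 1 else 'C%d' % i}*{'s' if j == nq - 1 else 'C%d' % j}"
        for i, j in pairs
    ]
    rows.extend(quad)
    labels.extend(qlabels)
    if C.shape[0]:
        cx = modified_kron(C, x[None, :])
        rows.extend(cx)
        labels.extend([f"C{j}*x" for j in range(C.shape[0])])
    rows.append(dominant_encode(x))
    labels.append("x_dom")

    kept, kept_labels, dropped = _dedup(rows, labels)
    if dropped:
        logger.info("dropped degenerate design rows: %s", dropped)
    design = np.vstack([kept, (s * x)[None, :]])
    kept_labels.append("s*x")
    return InteractionDesign(design, kept_labels, dropped)


def map_interaction(
    ds: Dataset,
    norm: NormalizedExpression,
    fact: GRMFactorization,
    state_pair: tuple,
    user_covariates: np.ndarray | None = None,
    method: str = "chi2",
    grid_size: int = 40,
    snp_gene_pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test genotype-by-cell-state interactions for every (SNP, gene) pair.

    ``ds`` must already be restricted to cells of the two states in
    ``state_pair``; ``s`` is the indicator of the second state, so swapping
    the pair negates the interaction effect and leaves P unchanged.  lambda is
    estimated per (gene, SNP) under the extended null; pairs with
    lambda > 3 are excluded.  ``snp_gene_pairs`` (columns snp, gene) restricts
    the scan; default is all pairs.
    """
    state_a, state_b = state_pair
    states = ds.cell_meta["state"].to_numpy()
    in_pair = np.isin(states, (state_a, state_b))
    if not in_pair.all():
        raise ValueError("dataset contains cells outside the state pair")
    s = (states == state_b).astype(float)
    if s.sum() == 0 or s.sum() == s.size:
        raise ValueError("a state has zero cells")

    C = norm.tech_covariates
    if user_covariates is not None and len(user_covariates):
        C = np.vstack([C, user_covariates])
    rv = ds.repeats
    G = ds.genotypes.astype(float)
    Y = norm.logexpr
    gene_ids = ds.gene_meta["id"].to_numpy()
    snp_ids = ds.snp_meta["id"].to_numpy()
    snp_index = {sid: j for j, sid in enumerate(snp_ids)}

    if snp_gene_pairs is None:
        wanted = {gid: list(range(len(snp_ids))) for gid in gene_ids}
    else:
        wanted = {
            gid: [snp_index[sid] for sid in grp["snp"]]
            for gid, grp in snp_gene_pairs.groupby("gene")
        }

    records = []
    grid = np.log(np.logspace(-4, 4, grid_size))
    for i, gid in enumerate(gene_ids):
        if gid not in wanted:
            continue
        y = Y[i]
        for j in wanted[gid]:
            x = rv.expand(G[j])
            dz = build_interaction_design(C, s, x)
            lam = _fit_lambda(fact, y, dz.null_design, grid)
            if lam > LAMBDA_EXCLUDE:
                continue
            beta, r2, dof2 = _test_last_term(fact, lam, y, dz)
            p = float(pvalue_from_r2(np.clip(r2, 0.0, 1.0), dof2, method))
            cis = bool(cis_window_mask(ds.snp_meta.iloc[[j]], ds.gene_meta.iloc[i])[0])
            records.append(
                {
                    "snp": snp_ids[j],
                    "gene": gid,
                    "cis_or_trans": "cis" if cis else "trans",
                    "beta": beta,
                    "r2": r2,
                    "p": p,
                    "lambda_hat": lam,
                    "dof2": dof2,
                    "term": f"{state_b}:x",
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["snp", "gene", "cis_or_trans", "beta", "r2", "p", "lambda_hat", "dof2", "term"],
    )


def _fit_lambda(fact: GRMFactorization, y, C_null, grid) -> float:
    if fact.rank == 0:
        return 0.0
    prof = LambdaProfile(fact, y, C_null)
    ll = np.array([prof.loglik(np.exp(g)) for g in grid])
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    log_lam = _golden_max(lambda g: prof.loglik(np.exp(g)), lo, hi, 1e-3)
    lam = float(np.exp(log_lam))
    if prof.loglik(0.0) >= prof.loglik(lam):
        lam = 0.0
    return lam


def _test_last_term(fact: GRMFactorization, lam: float, y, dz: InteractionDesign):
    yw = whiten(fact, lam, y)
    Dw = whiten(fact, lam, dz.design)
    Cw, tw = Dw[:-1], Dw[-1]
    Q, _ = np.linalg.qr(Cw.T)
    yr = yw - Q @ (Q.T @ yw)
    tr = tw - Q @ (Q.T @ tw)
    tnorm2 = float(tr @ tr)
    ynorm2 = float(yr @ yr)
    dof2 = y.size - Cw.shape[0] - 1
    if tnorm2 < 1e-12 or ynorm2 <= 0:
        return 0.0, 0.0, dof2
    xy = float(tr @ yr)
    return xy / tnorm2, xy**2 / (tnorm2 * ynorm2), dof2
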