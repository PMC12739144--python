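"""Quality control and expression normalization.

QC iterates removal rules to a fixpoint: low-coverage cells, sparsely
expressed genes, and donors with too few cells are removed repeatedly until
nothing changes, since removing one entity can push another below its floor.
Cell subsets that survive QC are then gated on minimum dataset dimensions
before any mapping.

Normalization is a deliberately simple, pluggable scheme: log2 CPM expression,
library-size technical covariates, and per-gene variance standardization of
the OLS residual after those covariates.  It preserves the two properties the
mapper relies on -- log-scale expression and library-size covariates -- and a
more elaborate normalizer can be substituted via the ``normalizer`` argument
of the pipeline entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sceqtl.data import Dataset

__all__ = [
    "QCReport",
    "qc_iterate",
    "subset_gate",
    "NormalizedExpression",
    "normalize_expression",
    "pseudobulk_lcpm",
]

# removal floors (strict inequalities: an entity AT the floor survives)
MIN_GENES_PER_CELL = 100
MIN_READS_PER_CELL = 500
MIN_DONOR_FRACTION_PER_GENE = 0.10
MIN_CELLS_PER_GENE = 100
MIN_CELL_FRACTION_PER_GENE = 0.02
MAX_REMOVED_DONOR_CELLS = 5  # donors with <= 5 cells are removed

GATE_FLOORS = {"cells": 500, "donors": 40, "snps": 10_000, "genes": 500}


@dataclass
class QCReport:
    iterations: list = field(default_factory=list)

    def add(self, counts: dict) -> None:
        self.iterations.append(counts)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations).fillna(0).astype(int)


def _one_pass(ds: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Evaluate all rules on the current dataset; returns keep-masks."""
    X = ds.counts
    expressed = X > 0  # boolean sparse
    genes_per_cell = np.asarray(expressed.sum(axis=0)).ravel()
    reads_per_cell = np.asarray(X.sum(axis=0)).ravel()
    cell_ok = (genes_per_cell >= MIN_GENES_PER_CELL) & (reads_per_cell >= MIN_READS_PER_CELL)

    didx = ds.cell_donor_index()
    n_donor = ds.n_donor
    # gene expressed in a donor: >= 1 read in any cell of that donor
    cells_per_gene = np.asarray(expressed.sum(axis=1)).ravel()
    ind = sp.csr_matrix(
        (np.ones(ds.n_cell), (didx, np.arange(ds.n_cell))), shape=(n_donor, ds.n_cell)
    )
    donors_per_gene = np.asarray(((expressed @ ind.T) > 0).sum(axis=1)).ravel()
    gene_ok = (
        (donors_per_gene >= MIN_DONOR_FRACTION_PER_GENE * n_donor)
        & (cells_per_gene >= MIN_CELLS_PER_GENE)
        & (cells_per_gene >= MIN_CELL_FRACTION_PER_GENE * ds.n_cell)
    )

    cells_per_donor = np.bincount(didx, minlength=n_donor)
    donor_ok = cells_per_donor > MAX_REMOVED_DONOR_CELLS

    removed = {
        "cells_low_coverage": int((~cell_ok).sum()),
        "genes_low_expression": int((~gene_ok).sum()),
        "donors_few_cells": int((~donor_ok).sum()),
    }
    return cell_ok, gene_ok, donor_ok, removed


def qc_iterate(ds: Dataset, max_iter: int = 100) -> tuple[Dataset, QCReport]:
    """Apply removal rules repeatedly until a fixpoint is reached.

    Rules per iteration (evaluated on the current surviving data): cells with
    <100 expressed genes or <500 reads; genes expressed in <10% of donors,
    <100 cells, or <2% of cells; donors with <=5 cells (and their cells).
    """
    report = QCReport()
    for _ in range(max_iter):
        cell_ok, gene_ok, donor_ok, removed = _one_pass(ds)
        report.add(removed)
        if cell_ok.all() and gene_ok.all() and donor_ok.all():
            break
        # donor removal also removes that donor's cells; donors left with no
        # cell are dropped by the cell subset itself
        bad_donors = {ds.donor_ids[i] for i in np.flatnonzero(~donor_ok)}
        cell_ok &= ~ds.cell_meta["donor"].isin(bad_donors).to_numpy()
        if not cell_ok.any() or not gene_ok.any():
            raise ValueError("dataset empty after QC")
        ds = ds.subset(genes=gene_ok, cells=cell_ok)
        if ds.n_gene == 0 or ds.n_cell == 0 or ds.n_donor == 0:
            raise ValueError("dataset empty after QC")
    return ds, report


def subset_gate(ds: Dataset) -> tuple[bool, list]:
    """Minimum-dimension gate for one QCed cell subset.

    Fails when fewer than 500 cells, 40 donors, 10,000 SNPs, or 500 genes
    remain ('less than' is strict: exactly at every floor passes).
    """
    dims = {"cells": ds.n_cell, "donors": ds.n_donor, "snps": ds.n_snp, "genes": ds.n_gene}
    reasons = [k for k, floor in GATE_FLOORS.items() if dims[k] < floor]
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizedExpression:
    """Log-scale expression with technical covariates.

    ``logexpr`` rows are variance-standardized: after OLS on the technical
    covariates the residual variance is 1, and ``scale`` holds the per-gene
    divisor so effects can be converted between the raw-log2 and standardized
    scales.  ``tech_covariates`` rows are standardized to mean 0, variance 1.
    """

    logexpr: np.ndarray
    tech_covariates: np.ndarray
    scale: np.ndarray
    tech_names: list


def normalize_expression(counts) -> NormalizedExpression:
    """Default normalization: log2 CPM, library-size covariates, per-gene
    variance standardization.

    logexpr[i, c] = log2(1e6 * counts[i, c] / libsize[c] + 1), then each gene
    row is divided by the standard deviation of its OLS residual on
    {1, log libsize, log #expressed genes}; constant covariates are dropped
    with a warning.
    """
    X = sp.csr_matrix(counts)
    lib = np.asarray(X.sum(axis=0)).ravel().astype(float)
    if np.any(lib == 0):
        raise ValueError("zero-library-size cell (QC should have removed it)")
    ngene_expr = np.asarray((X > 0).sum(axis=0)).ravel().astype(float)

    logexpr = np.log2(1e6 * X.toarray() / lib + 1.0)

    tech, names = [], []
    for vec, name in ((np.log(lib), "log_libsize"), (np.log(ngene_expr), "log_ngenes")):
        sd = vec.std()
        if sd < 1e-12 * max(1.0, abs(vec.mean())):
            import warnings

            warnings.warn(f"technical covariate {name} is constant; dropped")
            continue
        tech.append((vec - vec.mean()) / sd)
        names.append(name)
    T = np.array(tech) if tech else np.zeros((0, X.shape[1]))

    # residual variance after OLS on [1, tech]
    D = np.vstack([np.ones(X.shape[1]), T])
    beta, *_ = np.linalg.lstsq(D.T, logexpr.T, rcond=None)
    resid = logexpr - beta.T @ D
    scale = resid.std(axis=1)
    scale = np.where(scale == 0, 1.0, scale)
    return NormalizedExpression(
        logexpr=logexpr / scale[:, None], tech_covariates=T, scale=scale, tech_names=names
    )


def pseudobulk_lcpm(counts) -> np.ndarray:
    """Pseudo-bulk log(CPM + 1) per gene (natural log), used by calibration."""
    X = sp.csr_matrix(counts)
    per_gene = np.asarray(X.sum(axis=1)).ravel().astype(float)
    total = per_gene.sum()
    if total == 0:
        raise ValueError("all-zero count matrix")
    return np.log(1e6 * per_gene / total + 1.0)
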