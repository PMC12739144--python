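"""Dataset container and readers/writers for the pipeline's file formats.

A :class:`Dataset` bundles donor genotypes, SNP/gene annotation, the sparse
gene-by-cell count matrix, per-cell metadata (donor, cell state), and
cell-level covariates.  Cells are kept in donor-block order (all cells of a
donor contiguous, donors in genotype-column order); readers re-sort incoming
cells and record the permutation.  Counts are Matrix Market, everything else
is TSV; genotypes may alternatively come from a minimal biallelic VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from sceqtl.air import RepeatVector

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "read_dataset", "read_genotype_vcf", "write_results"]


@dataclass
class Dataset:
    """In-memory single-cell eQTL dataset in donor-block cell order.

    genotypes : (n_SNP, n_donor) int array of alt-allele dosages in {0,1,2}
    snp_meta : per-SNP ``id, chrom, pos, ref, alt`` (pos 1-based bp)
    counts : (n_gene, n_cell) sparse nonnegative integer matrix
    gene_meta : per-gene ``id, chrom, tss`` (tss 1-based bp)
    cell_meta : per-cell ``donor, state``
    covariates : (n_cov, n_cell) real matrix whose first row is the intercept
    donor_ids : donor labels in genotype-column order
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    counts: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame
    covariates: np.ndarray
    donor_ids: list

    def __post_init__(self):
        self.validate()

    # -- derived ------------------------------------------------------------

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_donor(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_gene(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cell(self) -> int:
        return self.counts.shape[1]

    @property
    def repeats(self) -> RepeatVector:
        donor_of_cell = self.cell_meta["donor"].to_numpy()
        order = {d: i for i, d in enumerate(self.donor_ids)}
        idx = np.array([order[d] for d in donor_of_cell])
        counts = np.bincount(idx, minlength=self.n_donor)
        if np.any(counts == 0):
            raise ValueError("every donor must have at least one cell")
        return RepeatVector(counts)

    def cell_donor_index(self) -> np.ndarray:
        order = {d: i for i, d in enumerate(self.donor_ids)}
        return np.array([order[d] for d in self.cell_meta["donor"]])

    # -- checks -------------------------------------------------------------

    def validate(self) -> None:
        g = np.asarray(self.genotypes)
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        self.genotypes = g.astype(np.int8)
        if len(self.snp_meta) != self.n_snp:
            raise ValueError("snp_meta length mismatch")
        if len(self.gene_meta) != self.n_gene:
            raise ValueError("gene_meta length mismatch")
        if len(self.cell_meta) != self.n_cell:
            raise ValueError("cell_meta length mismatch")
        if self.covariates.shape[1] != self.n_cell:
            raise ValueError("covariates must have one column per cell")
        known = set(self.donor_ids)
        unknown = set(self.cell_meta["donor"]) - known
        if unknown:
            raise ValueError(f"unknown donor in cell_meta: {sorted(unknown)[:5]}")
        idx = self.cell_donor_index()
        if np.any(np.diff(idx) < 0):
            raise ValueError("cells are not in donor-block order; use sort_cells()")
        self.counts = sp.csr_matrix(self.counts)

    # -- manipulation -------------------------------------------------------

    def sort_cells(self) -> tuple["Dataset", np.ndarray]:
        """Return a copy with cells in donor-block order plus the permutation.

        The permutation is stable within donors, and ``out.cell_meta`` row j
        equals ``self.cell_meta`` row ``perm[j]``.
        """
        order = {d: i for i, d in enumerate(self.donor_ids)}
        idx = np.array([order[d] for d in self.cell_meta["donor"]])
        perm = np.argsort(idx, kind="stable")
        ds = Dataset(
            genotypes=self.genotypes,
            snp_meta=self.snp_meta,
            counts=sp.csr_matrix(self.counts[:, perm]),
            gene_meta=self.gene_meta,
            cell_meta=self.cell_meta.iloc[perm].reset_index(drop=True),
            covariates=self.covariates[:, perm],
            donor_ids=self.donor_ids,
        )
        return ds, perm

    def subset(self, genes=None, cells=None, snps=None, donors=None) -> "Dataset":
        """Subset by boolean masks or index arrays.

        ``donors`` restricts genotype columns and drops their cells;
        ``cells`` additionally drops donors left without any cell.
        """
        ds = self

        def _idx(sel, n):
            sel = np.asarray(sel)
            return np.flatnonzero(sel) if sel.dtype == bool else sel

        if donors is not None:
            keep = _idx(donors, ds.n_donor)
            donor_ids = [ds.donor_ids[i] for i in keep]
            cellmask = ds.cell_meta["donor"].isin(set(donor_ids)).to_numpy()
            cidx = np.flatnonzero(cellmask)
            ds = Dataset(
                genotypes=ds.genotypes[:, keep],
                snp_meta=ds.snp_meta,
                counts=ds.counts[:, cidx],
                gene_meta=ds.gene_meta,
                cell_meta=ds.cell_meta.iloc[cidx].reset_index(drop=True),
                covariates=ds.covariates[:, cidx],
                donor_ids=donor_ids,
            )
        if cells is not None:
            cidx = _idx(cells, ds.n_cell)
            cell_meta = ds.cell_meta.iloc[cidx].reset_index(drop=True)
            surviving = set(cell_meta["donor"])
            keep_d = [i for i, d in enumerate(ds.donor_ids) if d in surviving]
            ds = Dataset(
                genotypes=ds.genotypes[:, keep_d],
                snp_meta=ds.snp_meta,
                counts=ds.counts[:, cidx],
                gene_meta=ds.gene_meta,
                cell_meta=cell_meta,
                covariates=ds.covariates[:, cidx],
                donor_ids=[ds.donor_ids[i] for i in keep_d],
            )
        if genes is not None:
            ds = replace_fields(ds, genes=_idx(genes, ds.n_gene))
        if snps is not None:
            ds = replace_fields(ds, snps=_idx(snps, ds.n_snp))
        return ds

    def restrict_state(self, state) -> "Dataset":
        mask = (self.cell_meta["state"] == state).to_numpy()
        return self.subset(cells=mask)


def replace_fields(ds: Dataset, genes=None, snps=None) -> Dataset:
    out = dict(
        genotypes=ds.genotypes,
        snp_meta=ds.snp_meta,
        counts=ds.counts,
        gene_meta=ds.gene_meta,
        cell_meta=ds.cell_meta,
        covariates=ds.covariates,
        donor_ids=ds.donor_ids,
    )
    if genes is not None:
        out["counts"] = ds.counts[genes]
        out["gene_meta"] = ds.gene_meta.iloc[genes].reset_index(drop=True)
    if snps is not None:
        out["genotypes"] = ds.genotypes[snps]
        out["snp_meta"] = ds.snp_meta.iloc[snps].reset_index(drop=True)
    return Dataset(**out)


# ---------------------------------------------------------------------------
# readers


def read_genotype_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list]:
    """Read a minimal VCF into a dosage matrix (requires cyvcf2).

    Biallelic records only: multi-allelic records are skipped with a logged
    warning; any missing genotype is a hard error (QC must pre-remove SNPs
    that could not be confidently genotyped).
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%d", rec.CHROM, rec.POS)
            continue
        dosage = np.asarray(rec.gt_types)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        if np.any(dosage == 2):
            raise ValueError(
                f"missing genotype at {rec.CHROM}:{rec.POS}; remove unconfident SNPs in QC"
            )
        dosage = np.where(dosage == 3, 2, dosage)
        rows.append(dosage)
        meta.append((rec.ID or f"{rec.CHROM}_{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    G = np.array(rows, dtype=np.int8)
    snp_meta = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return G, snp_meta, donors


def read_dataset(paths: dict) -> tuple[Dataset, np.ndarray]:
    """Assemble a Dataset from files; returns it plus the cell permutation.

    ``paths`` keys: counts (MTX), genes (row labels TSV), cells (cell metadata
    TSV with columns cell,donor,state), snp_meta (TSV), genotypes (TSV matrix
    with donor columns) or vcf, gene_meta (TSV: id,chrom,tss), optional
    covariates (TSV, cells as columns).
    """
    counts = sp.csr_matrix(scipy.io.mmread(paths["counts"]))
    gene_ids = pd.read_csv(paths["genes"], sep="\t")["id"].tolist()
    cell_meta = pd.read_csv(paths["cells"], sep="\t")
    if "vcf" in paths:
        G, snp_meta, donors = read_genotype_vcf(paths["vcf"])
    else:
        gt = pd.read_csv(paths["genotypes"], sep="\t", index_col=0)
        donors = list(gt.columns)
        G = gt.to_numpy()
        snp_meta = pd.read_csv(paths["snp_meta"], sep="\t")
        if list(snp_meta["id"]) != list(gt.index):
            raise ValueError("snp_meta ids do not match genotype matrix rows")
    if not np.isin(G, (0, 1, 2)).all():
        raise ValueError("non-{0,1,2} genotype entry (missing data must be removed by QC)")
    gene_meta = pd.read_csv(paths["gene_meta"], sep="\t")
    if list(gene_meta["id"]) != gene_ids:
        gene_meta = gene_meta.set_index("id").loc[gene_ids].reset_index()
    if "covariates" in paths:
        cov = pd.read_csv(paths["covariates"], sep="\t", index_col=0).to_numpy()
    else:
        cov = np.zeros((0, counts.shape[1]))
    cov = np.vstack([np.ones((1, counts.shape[1])), cov])
    ds = Dataset.__new__(Dataset)  # bypass block-order check before sorting
    ds.genotypes = np.asarray(G, dtype=np.int8)
    ds.snp_meta = snp_meta
    ds.counts = counts
    ds.gene_meta = gene_meta
    ds.cell_meta = cell_meta
    ds.covariates = cov
    ds.donor_ids = donors
    unknown = set(cell_meta["donor"]) - set(donors)
    if unknown:
        raise ValueError(f"unknown donor in cell_meta: {sorted(unknown)[:5]}")
    ds, perm = Dataset.sort_cells(ds)
    return ds, perm


# ---------------------------------------------------------------------------
# writers

_SCHEMAS = {
    "association": ["snp", "gene", "cis_or_trans", "beta", "r2", "p", "q", "lambda_hat"],
    "interaction": ["snp", "gene", "cis_or_trans", "beta", "r2", "p", "q", "lambda_hat", "term"],
    "edge": [
        "regulator",
        "target",
        "cell_state",
        "n_instruments",
        "strength_median",
        "rel_variability",
        "conflict_flag",
    ],
}


def write_results(records: pd.DataFrame, kind: str, path) -> None:
    """Write a result table as TSV: fixed schema, 6 significant digits,
    deterministic row order (sorted by the leading key columns)."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown kind {kind!r}")
    cols = _SCHEMAS[kind]
    missing = [c for c in cols if c not in records.columns]
    if missing and len(records):
        raise ValueError(f"records missing columns {missing}")
    df = records.reindex(columns=cols)
    keys = cols[:3] if kind != "edge" else cols[:3]
    if len(df):
        df = df.sort_values(keys, kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
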