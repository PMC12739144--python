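"""Population-scale scRNA-seq eQTL simulators with ground truth.

The generative model is a latent log-expression per gene and cell,

    y_i = alpha_i + sum_j beta_ji x_j + eps0 + eps1,

with i.i.d. cell-level noise eps0 ~ N(0, sigma0^2) and donor-block noise
eps1 ~ MVN(0, sigma1^2 K) (K block-diagonal all-ones), pushed through a
per-cell softmax across genes and binomial read sampling at empirically
resampled per-cell totals.  ``synthetic_base`` builds a fully synthetic base
dataset with no eQTL effects; the simulators resample a base to target
dimensions, permute genotypes across donors to kill LD and population
structure, pick cis-eQTLs at random within 1 Mb windows, fit their effect
sizes to the base expression (so effect magnitudes track what the data can
support), scale them, and regenerate counts with known truth.

True effect sizes are stored on the latent natural-log scale;
``SimTruth.on_analysis_scale`` converts them to the variance-standardized
normalized-expression scale of a given normalization, which is the scale the
mapper estimates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sceqtl.data import Dataset
from sceqtl.lmm import CIS_WINDOW
from sceqtl.qc import NormalizedExpression, normalize_expression

logger = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "synthetic_base",
    "resample_and_permute",
    "simulate_eqtl_dataset",
    "simulate_celltype_dataset",
    "simulate_calibration_null",
    "plant_regulation_dataset",
]

LN2 = np.log(2.0)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``cis_effects`` / ``celltype_effects`` columns: snp, gene, beta -- beta on
    the latent natural-log expression scale.  Pairs not listed have true
    effect zero.  ``gains`` holds the per-gene measurement gain: the expected
    response of log-CPM to a unit latent shift under the count model, which
    exceeds 1 for sparsely measured genes because the log(CPM + 1) transform
    jumps discretely between zero and one read.
    """

    cis_effects: pd.DataFrame
    celltype_effects: pd.DataFrame
    sigma0: float
    sigma1: float
    scale: float
    gene_ids: list = field(default_factory=list)
    gains: dict = field(default_factory=dict)
    gains_state: dict = field(default_factory=dict)

    def on_analysis_scale(self, norm: NormalizedExpression, which: str = "cis") -> pd.DataFrame:
        """Convert latent-scale effects to the normalized-expression scale.

        The true effect on the analysis scale is the expected change of
        normalized expression per dosage under the generative model: the
        latent effect times the gene's measurement gain, divided by
        ln 2 * standardization factor (normalization is a per-gene linear
        map of log2 CPM).
        """
        eff = self.cis_effects if which == "cis" else self.celltype_effects
        gains = self.gains if which == "cis" else (self.gains_state or self.gains)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        out = eff.copy()
        conv = np.array(
            [gains.get(g, 1.0) / (LN2 * norm.scale[idx[g]]) for g in eff["gene"]]
        )
        out["beta"] = eff["beta"] * conv
        return out


# ---------------------------------------------------------------------------
# helpers


def _softmax(latent: np.ndarray) -> np.ndarray:
    P = np.exp(latent - latent.max(axis=0, keepdims=True))
    P /= P.sum(axis=0, keepdims=True)
    return P


def _sample_counts(P, totals, rng, multinomial=False) -> sp.csr_matrix:
    if multinomial:
        counts = rng.multinomial(totals, P.T).T
    else:
        counts = rng.binomial(totals[None, :], P)
    return sp.csr_matrix(counts)


def _counts_from_latent(latent, totals, rng, multinomial=False) -> sp.csr_matrix:
    """Softmax across genes per cell, then per-gene binomial read sampling
    (or an exact-total multinomial variant with identical marginals)."""
    return _sample_counts(_softmax(latent), totals, rng, multinomial)


def _gain_interpolator(totals: np.ndarray, m_max: float = 5000.0):
    """Expected log-CPM response to a unit latent shift, on a (m, T) grid.

    For reads c ~ Poisson(m) at library size T the derivative of
    E[ln(1e6 c / T + 1)] with respect to the latent log mean equals
    E[(c - m) ln(1e6 c / T + 1)]; tabulated over expected counts m and
    totals T, then interpolated bilinearly in log space.
    """
    from scipy.interpolate import RegularGridInterpolator
    from scipy.stats import poisson

    m_grid = np.concatenate([[1e-6], np.logspace(-4, np.log10(m_max), 80)])
    t_lo = max(float(totals.min()), 1.0)
    t_hi = max(float(totals.max()), t_lo * 1.001)
    T_grid = np.logspace(np.log10(t_lo), np.log10(t_hi), 40)
    out = np.zeros((m_grid.size, T_grid.size))
    for a, m in enumerate(m_grid):
        hi = int(m + 12 * np.sqrt(m) + 25)
        cc = np.arange(hi + 1)
        pmf = poisson.pmf(cc, m)
        for b, T in enumerate(T_grid):
            y = np.log(1e6 * cc / T + 1)
            out[a, b] = pmf @ ((cc - m) * y)
    return RegularGridInterpolator(
        (np.log(m_grid + 1e-12), np.log(T_grid)), out, bounds_error=False, fill_value=None
    )


def _measurement_gains(P, totals, genes, s=None) -> tuple[dict, dict]:
    """Per-gene measurement gain (and state-restricted gain) for truth genes."""
    interp = _gain_interpolator(totals.astype(float))
    logT = np.log(totals.astype(float))
    gains, gains_state = {}, {}
    for i, gid in genes:
        m = totals * P[i]
        # (1 - p): raising one gene's latent level also raises the softmax
        # denominator by its own share
        g = interp(np.c_[np.log(m + 1e-12), logT]) * (1.0 - P[i])
        gains[gid] = float(g.mean())
        if s is not None:
            gains_state[gid] = float(g[s > 0.5].mean())
    return gains, gains_state


def _donor_noise(rng, sigma1, counts_per_donor, n_gene) -> np.ndarray:
    draws = rng.normal(0.0, sigma1, size=(n_gene, counts_per_donor.size))
    return np.repeat(draws, counts_per_donor, axis=1)


def _even_split(n_cell: int, n_donor: int) -> np.ndarray:
    base = n_cell // n_donor
    extra = n_cell % n_donor
    return np.array([base + (1 if d < extra else 0) for d in range(n_donor)])


# ---------------------------------------------------------------------------
# base generator


def synthetic_base(
    n_donor: int,
    n_cell: int,
    n_gene: int,
    n_snp: int,
    seed: int,
    maf_range: tuple = (0.05, 0.5),
    n_chrom: int = 2,
    chrom_len: float = 1e8,
    sigma0: float = 0.5,
    sigma1: float = 2.0,
    intercept_sd: float = 1.5,
    mean_reads: float = 3000.0,
    reads_logsd: float = 0.3,
    n_states: int = 2,
) -> Dataset:
    """Fully synthetic base dataset with no eQTL effects.

    Donor genotypes are Binomial(2, MAF) draws with per-SNP MAF uniform on
    ``maf_range``; SNP and TSS positions are uniform on ``n_chrom``
    chromosomes; latent expression is intercepts N(0, intercept_sd^2) plus
    cell-level (sigma0) and donor-level (sigma1) noise; per-cell totals are
    LogNormal(log mean_reads, reads_logsd^2) rounded.  Donor-level noise at
    sigma1 = 2 stands in for the large inter-individual heterogeneity
    (ancestry, condition, batch) of real population-scale data, which is what
    gives downstream effect-size fits their spread.  Deterministic under
    ``seed``; cells are split across donors as evenly as possible and each
    carries one of ``n_states`` cell-state labels.
    """
    if min(n_donor, n_cell, n_gene, n_snp) <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snp)
    G = rng.binomial(2, maf[:, None], size=(n_snp, n_donor)).astype(np.int8)
    chrom_s = rng.integers(0, n_chrom, size=n_snp)
    pos_s = rng.integers(1, int(chrom_len), size=n_snp)
    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(n_snp)],
            "chrom": [f"chr{c + 1}" for c in chrom_s],
            "pos": pos_s,
            "ref": "A",
            "alt": "G",
        }
    )
    chrom_g = rng.integers(0, n_chrom, size=n_gene)
    tss = rng.integers(1, int(chrom_len), size=n_gene)
    gene_meta = pd.DataFrame(
        {
            "id": [f"G{i}" for i in range(n_gene)],
            "chrom": [f"chr{c + 1}" for c in chrom_g],
            "tss": tss,
        }
    )
    counts_per_donor = _even_split(n_cell, n_donor)
    donor_ids = [f"D{d}" for d in range(n_donor)]
    donors_of_cells = np.repeat(donor_ids, counts_per_donor)
    states = rng.choice([chr(ord("A") + k) for k in range(n_states)], size=n_cell)
    cell_meta = pd.DataFrame(
        {"cell": [f"C{c}" for c in range(n_cell)], "donor": donors_of_cells, "state": states}
    )

    alpha = rng.normal(0.0, intercept_sd, size=n_gene)
    latent = (
        alpha[:, None]
        + rng.normal(0.0, sigma0, size=(n_gene, n_cell))
        + _donor_noise(rng, sigma1, counts_per_donor, n_gene)
    )
    totals = np.maximum(
        1, np.round(rng.lognormal(np.log(mean_reads), reads_logsd, size=n_cell))
    ).astype(np.int64)
    counts = _counts_from_latent(latent, totals, rng)
    return Dataset(
        genotypes=G,
        snp_meta=snp_meta,
        counts=counts,
        gene_meta=gene_meta,
        cell_meta=cell_meta,
        covariates=np.ones((1, n_cell)),
        donor_ids=donor_ids,
    )


# ---------------------------------------------------------------------------
# resampling


def resample_and_permute(
    base: Dataset, dims: dict, seed: int, permute: bool = True
) -> Dataset:
    """Resample a base dataset to target dims and permute genotypes.

    Genes: autosomes only, downsampled to n_gene.  SNPs: restricted to within
    1 Mb of a surviving TSS, downsampled to n_snp.  Donors: down- or
    upsampled (with replacement; resampled donors become new distinct
    donors).  Cells: down/upsampled within the selected donors, keeping at
    least one cell per donor.  Finally each SNP's donor genotypes are
    independently permuted, which destroys LD and population structure while
    preserving every SNP's genotype multiset (hence its MAF).
    """
    rng = np.random.default_rng(seed)
    n_gene, n_snp = dims["n_gene"], dims["n_snp"]
    n_donor, n_cell = dims["n_donor"], dims["n_cell"]

    auto = ~base.gene_meta["chrom"].isin(["chrX", "chrY", "X", "Y"]).to_numpy()
    gidx = np.flatnonzero(auto)
    if n_gene > gidx.size:
        raise ValueError("not enough autosomal genes")
    if n_gene < gidx.size:
        gidx = np.sort(rng.choice(gidx, n_gene, replace=False))
    ds = base.subset(genes=gidx)

    near = np.zeros(ds.n_snp, dtype=bool)
    pos = ds.snp_meta["pos"].to_numpy()
    chrom = ds.snp_meta["chrom"].to_numpy()
    for _, g in ds.gene_meta.iterrows():
        near |= (chrom == g["chrom"]) & (np.abs(pos - g["tss"]) <= CIS_WINDOW)
    sidx = np.flatnonzero(near)
    if n_snp > sidx.size:
        raise ValueError("not enough SNPs within cis windows of surviving genes")
    if n_snp < sidx.size:
        sidx = np.sort(rng.choice(sidx, n_snp, replace=False))
    ds = ds.subset(snps=sidx)

    if n_donor != ds.n_donor or n_cell != ds.n_cell:
        ds = _resample_donors_cells(ds, n_donor, n_cell, rng)

    G = ds.genotypes.copy()
    if permute:
        for j in range(G.shape[0]):
            G[j] = G[j, rng.permutation(G.shape[1])]
    return Dataset(
        genotypes=G,
        snp_meta=ds.snp_meta,
        counts=ds.counts,
        gene_meta=ds.gene_meta,
        cell_meta=ds.cell_meta,
        covariates=ds.covariates,
        donor_ids=ds.donor_ids,
    )


def _resample_donors_cells(ds: Dataset, n_donor: int, n_cell: int, rng) -> Dataset:
    if n_cell < n_donor:
        raise ValueError("need at least one cell per donor")
    cur = ds.n_donor
    if n_donor <= cur:
        pick = rng.choice(cur, n_donor, replace=False)
    else:
        pick = np.concatenate([np.arange(cur), rng.choice(cur, n_donor - cur, replace=True)])
    new_ids = [f"D{k}" for k in range(n_donor)]
    didx = ds.cell_donor_index()
    cell_lists = [np.flatnonzero(didx == d) for d in pick]
    # one guaranteed cell per donor, remaining budget spread by donor pool size
    chosen: list = []
    new_donor_of_cell: list = []
    for k, cells in enumerate(cell_lists):
        c = rng.choice(cells)
        chosen.append(c)
        new_donor_of_cell.append(k)
    pool = np.concatenate(cell_lists)
    pool_donor = np.concatenate([[k] * len(c) for k, c in enumerate(cell_lists)])
    extra = n_cell - n_donor
    if extra > 0:
        take = rng.choice(pool.size, extra, replace=pool.size < extra)
        chosen.extend(pool[take])
        new_donor_of_cell.extend(pool_donor[take])
    chosen = np.array(chosen)
    new_donor_of_cell = np.array(new_donor_of_cell)
    order = np.argsort(new_donor_of_cell, kind="stable")
    chosen, new_donor_of_cell = chosen[order], new_donor_of_cell[order]
    cell_meta = ds.cell_meta.iloc[chosen].reset_index(drop=True)
    cell_meta["donor"] = [new_ids[k] for k in new_donor_of_cell]
    cell_meta["cell"] = [f"C{c}" for c in range(len(chosen))]
    return Dataset(
        genotypes=ds.genotypes[:, pick],
        snp_meta=ds.snp_meta,
        counts=ds.counts[:, chosen],
        gene_meta=ds.gene_meta,
        cell_meta=cell_meta,
        covariates=ds.covariates[:, chosen],
        donor_ids=new_ids,
    )


# ---------------------------------------------------------------------------
# effect-size fitting and injection


def _orthogonalize(rows: np.ndarray, against: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(against.T)
    return rows - (rows @ Q) @ Q.T


def _drop_duplicate_columns(cols: list, labels: list) -> tuple[list, list]:
    kept, kept_lab = [], []
    for c, lab in zip(cols, labels):
        dup = any(np.array_equal(c, k) or np.array_equal(c, 2 - k) for k in kept)
        if dup:
            logger.info("dropping collinear genotype column %s", lab)
        else:
            kept.append(c)
            kept_lab.append(lab)
    return kept, kept_lab


def _simulate(
    base: Dataset,
    dims: dict,
    seed: int,
    scale: float,
    sigma0: float,
    sigma1: float,
    cis_prob: float,
    spec_prob: float,
    celltype: bool,
    permute: bool,
    multinomial: bool = False,
    state_pair: tuple | None = None,
) -> tuple[Dataset, SimTruth]:
    rng = np.random.default_rng(seed)
    ds = resample_and_permute(base, dims, seed + 1 if permute else seed, permute=permute)
    norm = normalize_expression(ds.counts)
    rv = ds.repeats
    counts_per_donor = rv.counts
    n_gene, n_cell = ds.n_gene, ds.n_cell
    Gf = ds.genotypes.astype(float)
    snp_ids = ds.snp_meta["id"].to_numpy()
    gene_ids = ds.gene_meta["id"].tolist()

    if celltype:
        if state_pair is None:
            labels = sorted(ds.cell_meta["state"].unique())
            if len(labels) != 2:
                raise ValueError("cell-type simulation needs exactly two states")
            state_pair = tuple(labels)
        states = ds.cell_meta["state"].to_numpy()
        missing = [
            d
            for d in ds.donor_ids
            if len(set(states[ds.cell_meta["donor"] == d])) < 2
        ]
        if missing:
            import warnings

            warnings.warn(f"cell type absent in donors {missing[:5]}; proceeding")
        s = (states == state_pair[1]).astype(float)
        tech = _orthogonalize(norm.tech_covariates, np.vstack([np.ones(n_cell), s]))
        covs = np.vstack([np.ones(n_cell), s, tech])
    else:
        s = None
        tech = norm.tech_covariates
        covs = np.vstack([np.ones(n_cell), tech])

    # cis selection
    pos = ds.snp_meta["pos"].to_numpy()
    chrom = ds.snp_meta["chrom"].to_numpy()
    cis_rows, ct_rows = [], []
    latent = np.zeros((n_gene, n_cell))
    for i in range(n_gene):
        g = ds.gene_meta.iloc[i]
        window = np.flatnonzero((chrom == g["chrom"]) & (np.abs(pos - g["tss"]) <= CIS_WINDOW))
        sel = window[rng.random(window.size) < cis_prob]
        specific = (
            sel[rng.random(sel.size) < spec_prob] if celltype and sel.size else np.array([], int)
        )
        cols = [rv.expand(Gf[j]) for j in sel]
        cols, kept_sel = _drop_duplicate_columns(cols, list(sel))
        sel = np.array(kept_sel, dtype=int)
        specific = np.array([j for j in specific if j in set(kept_sel)], dtype=int)
        D_parts = [covs.T]
        if sel.size:
            D_parts.append(np.array(cols).T)
        if specific.size:
            D_parts.append(np.array([s * rv.expand(Gf[j]) for j in specific]).T)
        D = np.hstack(D_parts)
        coef, *_ = np.linalg.lstsq(D, norm.logexpr[i], rcond=None)
        conv = LN2 * norm.scale[i]  # standardized -> latent natural-log units
        n_cov = covs.shape[0]
        beta_lat = coef[n_cov : n_cov + sel.size] * conv * scale
        beta_int = coef[n_cov + sel.size :] * conv * scale

        if celltype:
            contrib = covs.T @ (coef[:n_cov] * conv)  # fitted covariate terms, no alpha_i
            latent[i] = contrib
        else:
            alpha_i = LN2 * float((norm.logexpr[i] * norm.scale[i]).mean())
            latent[i] = alpha_i
        for j, b in zip(sel, beta_lat):
            latent[i] += b * rv.expand(Gf[j])
            cis_rows.append({"snp": snp_ids[j], "gene": gene_ids[i], "beta": b})
        for j, b in zip(specific, beta_int):
            latent[i] += b * s * rv.expand(Gf[j])
            ct_rows.append({"snp": snp_ids[j], "gene": gene_ids[i], "beta": b})

    latent += rng.normal(0.0, sigma0, size=(n_gene, n_cell))
    latent += _donor_noise(rng, sigma1, counts_per_donor, n_gene)
    base_totals = np.asarray(ds.counts.sum(axis=0)).ravel().astype(np.int64)
    totals = rng.choice(base_totals, size=n_cell, replace=True)
    P = _softmax(latent)
    truth_genes = sorted(
        {r["gene"] for r in cis_rows} | {r["gene"] for r in ct_rows}
    )
    gidx = {g: i for i, g in enumerate(gene_ids)}
    gains, gains_state = _measurement_gains(
        P, totals, [(gidx[g], g) for g in truth_genes], s=s if celltype else None
    )
    counts = _sample_counts(P, totals, rng, multinomial=multinomial)
    out = Dataset(
        genotypes=ds.genotypes,
        snp_meta=ds.snp_meta,
        counts=counts,
        gene_meta=ds.gene_meta,
        cell_meta=ds.cell_meta,
        covariates=ds.covariates,
        donor_ids=ds.donor_ids,
    )
    truth = SimTruth(
        cis_effects=pd.DataFrame(cis_rows, columns=["snp", "gene", "beta"]),
        celltype_effects=pd.DataFrame(ct_rows, columns=["snp", "gene", "beta"]),
        sigma0=sigma0,
        sigma1=sigma1,
        scale=scale,
        gene_ids=gene_ids,
        gains=gains,
        gains_state=gains_state,
    )
    return out, truth


def simulate_eqtl_dataset(
    base: Dataset,
    dims: dict,
    seed: int,
    scale: float = 1.5,
    sigma0: float = 0.5,
    sigma1: float = 1.0,
    cis_prob: float = 0.5,
    multinomial: bool = False,
) -> tuple[Dataset, SimTruth]:
    """Benchmark dataset for marginal eQTL mapping.

    Each SNP within 1 Mb of a gene's TSS becomes its cis-eQTL with
    probability ``cis_prob``; effect sizes are least-squares fits of the
    resampled base expression on the selected genotypes plus covariates,
    scaled by ``scale``; counts are regenerated through the latent model with
    fresh cell-level (sigma0) and donor-level (sigma1) noise.
    """
    return _simulate(
        base,
        dims,
        seed,
        scale=scale,
        sigma0=sigma0,
        sigma1=sigma1,
        cis_prob=cis_prob,
        spec_prob=0.0,
        celltype=False,
        permute=True,
        multinomial=multinomial,
    )


def simulate_celltype_dataset(
    base: Dataset,
    dims: dict,
    seed: int,
    scale: float = 1.5,
    sigma0: float = 0.5,
    sigma1: float = 1.0,
    cis_prob: float = 0.5,
    spec_prob: float = 0.5,
    state_pair: tuple | None = None,
    permute: bool = True,
) -> tuple[Dataset, SimTruth]:
    """Benchmark dataset for cell-state-specific mapping.

    As :func:`simulate_eqtl_dataset`, with the binary cell-state label as an
    extra one-hot covariate throughout, technical covariates orthogonalized
    against it, and each cis-eQTL given ``spec_prob`` probability of an
    additional state-by-genotype interaction effect; covariate contributions
    replace the pseudo-bulk intercept.
    """
    return _simulate(
        base,
        dims,
        seed,
        scale=scale,
        sigma0=sigma0,
        sigma1=sigma1,
        cis_prob=cis_prob,
        spec_prob=spec_prob,
        celltype=True,
        permute=permute,
        state_pair=state_pair,
    )


def simulate_calibration_null(
    source: Dataset,
    seed: int,
    scale: float = 2.0,
    sigma0: float = 0.5,
    sigma1: float = 1.0,
    cis_prob: float = 0.5,
    state_pair: tuple | None = None,
) -> tuple[Dataset, SimTruth]:
    """Null dataset for interaction P-value calibration.

    Mimics ``source`` at identical dimensions: genotypes are NOT permuted,
    cis-eQTLs are present (effect scale 2.0) but none is cell-state-specific,
    so every interaction P value is a null draw under source-like conditions.
    """
    dims = {
        "n_gene": source.n_gene,
        "n_snp": source.n_snp,
        "n_donor": source.n_donor,
        "n_cell": source.n_cell,
    }
    out, truth = _simulate(
        source,
        dims,
        seed,
        scale=scale,
        sigma0=sigma0,
        sigma1=sigma1,
        cis_prob=cis_prob,
        spec_prob=0.0,
        celltype=True,
        permute=False,
        state_pair=state_pair,
    )
    assert truth.celltype_effects.empty
    return out, truth


# ---------------------------------------------------------------------------
# planted gene regulation (for end-to-end network benchmarks)


def plant_regulation_dataset(
    seed: int,
    gamma: float = 0.8,
    n_instruments: int = 4,
    n_donor: int = 200,
    n_cell: int = 6000,
    n_null_genes: int = 22,
    n_null_snps: int = 600,
    beta_mag: float = 0.6,
    sigma0: float = 0.5,
    sigma1: float = 0.3,
    mean_reads: float = 500.0,
) -> tuple[Dataset, dict]:
    """Dataset with one planted regulator -> target causal effect.

    A regulator gene on chr1 has ``n_instruments`` cis-SNPs with latent
    effects of magnitude ``beta_mag`` (alternating sign); a target gene on
    chr2 receives ``gamma`` times the regulator's genetic component, so every
    instrument's trans/cis effect ratio equals ``gamma``.  Null genes are
    placed > 1 Mb from the instruments so each instrument has a single cis
    gene.  Returns the dataset plus a truth dict with the planted strength.
    """
    rng = np.random.default_rng(seed)
    n_gene = 2 + n_null_genes
    n_snp = n_instruments + n_null_snps
    maf = rng.uniform(0.2, 0.5, size=n_snp)
    G = rng.binomial(2, maf[:, None], size=(n_snp, n_donor)).astype(np.int8)

    # layout: regulator at 5 Mb on chr1, instruments within its window;
    # null genes/SNPs beyond 10 Mb or on chr2
    inst_pos = 5_000_000 + rng.integers(-CIS_WINDOW // 2, CIS_WINDOW // 2, n_instruments)
    null_snp_chrom = rng.choice(["chr1", "chr2"], n_null_snps)
    null_snp_pos = rng.integers(10_000_000, 90_000_000, n_null_snps)
    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(n_snp)],
            "chrom": ["chr1"] * n_instruments + list(null_snp_chrom),
            "pos": np.r_[inst_pos, null_snp_pos],
            "ref": "A",
            "alt": "G",
        }
    )
    null_gene_chrom = rng.choice(["chr1", "chr2"], n_null_genes)
    null_gene_tss = rng.integers(10_000_000, 90_000_000, n_null_genes)
    gene_meta = pd.DataFrame(
        {
            "id": ["GREG", "GTAR"] + [f"GN{i}" for i in range(n_null_genes)],
            "chrom": ["chr1", "chr2"] + list(null_gene_chrom),
            "tss": np.r_[5_000_000, 50_000_000, null_gene_tss],
        }
    )
    counts_per_donor = _even_split(n_cell, n_donor)
    donor_ids = [f"D{d}" for d in range(n_donor)]
    cell_meta = pd.DataFrame(
        {
            "cell": [f"C{c}" for c in range(n_cell)],
            "donor": np.repeat(donor_ids, counts_per_donor),
            "state": "A",
        }
    )
    betas = beta_mag * np.where(np.arange(n_instruments) % 2 == 0, 1.0, -1.0)
    rvcounts = counts_per_donor
    genetic = np.zeros(n_cell)
    for j in range(n_instruments):
        genetic += betas[j] * np.repeat(G[j].astype(float), rvcounts)
    alpha = np.r_[1.0, 1.0, rng.normal(0.0, 1.0, n_null_genes)]
    latent = (
        alpha[:, None]
        + rng.normal(0.0, sigma0, size=(n_gene, n_cell))
        + _donor_noise(rng, sigma1, rvcounts, n_gene)
    )
    latent[0] += genetic
    # the target gets gamma times the genetic component plus compensating
    # donor-level noise so both genes carry equal variance; per-gene variance
    # standardization then leaves the normalized-scale estimand at gamma
    latent[1] += gamma * genetic
    if abs(gamma) < 1:
        comp_sd = np.sqrt((1 - gamma**2) * genetic.var())
        latent[1] += np.repeat(rng.normal(0.0, comp_sd, n_donor), rvcounts)
    totals = np.maximum(1, np.round(rng.lognormal(np.log(mean_reads), 0.3, n_cell))).astype(
        np.int64
    )
    counts = _counts_from_latent(latent, totals, rng)
    ds = Dataset(
        genotypes=G,
        snp_meta=snp_meta,
        counts=counts,
        gene_meta=gene_meta,
        cell_meta=cell_meta,
        covariates=np.ones((1, n_cell)),
        donor_ids=donor_ids,
    )
    truth = {
        "regulator": "GREG",
        "target": "GTAR",
        "gamma": gamma,
        "instruments": [f"rs{j}" for j in range(n_instruments)],
        "betas": betas,
    }
    return ds, truth
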