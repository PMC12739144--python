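from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sceqtl.air import RepeatVector, grm_eigendecompose, grm_from_genotypes
from sceqtl.data import Dataset

TOY_DIR = Path(__file__).parent / "data" / "toy"


@pytest.fixture
def toy_paths():
    return {
        "counts": TOY_DIR / "counts.mtx",
        "genes": TOY_DIR / "genes.tsv",
        "cells": TOY_DIR / "cells.tsv",
        "genotypes": TOY_DIR / "genotypes.tsv",
        "snp_meta": TOY_DIR / "snp_meta.tsv",
        "gene_meta": TOY_DIR / "gene_meta.tsv",
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_repeats(rng, n_donor=None, max_count=10):
    n_donor = n_donor or int(rng.integers(2, 21))
    return RepeatVector(rng.integers(1, max_count + 1, n_donor))


def random_grm(rng, repeats, n_snp=25):
    """Donor GRM from random non-monomorphic genotypes."""
    while True:
        G = rng.binomial(2, rng.uniform(0.2, 0.8, n_snp)[:, None], (n_snp, repeats.n_donor))
        if np.all(G.std(axis=1) > 0):
            break
    K = grm_from_genotypes(G.astype(float), repeats)
    return K, grm_eigendecompose(K, repeats)


def make_dataset(
    rng,
    n_snp=6,
    n_donor=4,
    cells_per_donor=(3, 2, 4, 3),
    n_gene=5,
    states=("A", "B"),
) -> Dataset:
    """Small in-memory dataset with consistent metadata, donor-block order."""
    cells_per_donor = np.asarray(cells_per_donor[:n_donor])
    n_cell = int(cells_per_donor.sum())
    G = rng.integers(0, 3, (n_snp, n_donor)).astype(np.int8)
    donor_ids = [f"D{d}" for d in range(n_donor)]
    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(n_snp)],
            "chrom": ["chr1" if j % 2 == 0 else "chr2" for j in range(n_snp)],
            "pos": rng.integers(1, 10**7, n_snp),
            "ref": "A",
            "alt": "G",
        }
    )
    gene_meta = pd.DataFrame(
        {
            "id": [f"G{i}" for i in range(n_gene)],
            "chrom": ["chr1" if i % 2 == 0 else "chr2" for i in range(n_gene)],
            "tss": rng.integers(1, 10**7, n_gene),
        }
    )
    counts = sp.csr_matrix(rng.poisson(3.0, (n_gene, n_cell)))
    cell_meta = pd.DataFrame(
        {
            "cell": [f"c{c}" for c in range(n_cell)],
            "donor": np.repeat(donor_ids, cells_per_donor),
            "state": [states[c % len(states)] for c in range(n_cell)],
        }
    )
    return Dataset(
        genotypes=G,
        snp_meta=snp_meta,
        counts=counts,
        gene_meta=gene_meta,
        cell_meta=cell_meta,
        covariates=np.ones((1, n_cell)),
        donor_ids=donor_ids,
    )
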