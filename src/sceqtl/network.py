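"""Mendelian-randomization inference of causal gene regulatory networks.

A SNP that is a credible cis-eQTL for exactly one gene (the regulator) and a
trans-eQTL for another (the target) serves as an instrumental variable: under
two-stage least squares the regulator -> target effect is the ratio of the
trans to the cis effect size.  Edges supported by at least two genotypically
unique instruments (allele flips count as identical) are retained, with the
median ratio as strength and a bounded relative-variability statistic plus a
sign-conflict flag as robustness measures.

FDR control uses Benjamini-Hochberg Q values; because trans scans only emit
P values below a cutoff, the step-up is computed on the sub-cutoff head with
global ranks, which is exactly the restriction of full BH to the head.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "bh_q_below_cutoff",
    "add_bh_q",
    "select_instruments",
    "tsls_effect",
    "unique_instruments",
    "relative_variability",
    "assemble_cgrn",
    "infer_cgrn",
]

CIS_Q = 0.1
TRANS_Q = 0.5
PLEIOTROPY_P = 0.1


def bh_q_below_cutoff(p_sub: np.ndarray, m_total: int, cutoff: float = 1.0) -> np.ndarray:
    """Benjamini-Hochberg Q values for the sorted head of a P-value list.

    ``p_sub`` must be sorted ascending with every entry <= cutoff, and
    ``m_total`` is the total number of tests performed (including the omitted
    ones, all > cutoff).  q_i = min_{j >= i} p_j * m_total / j with global
    ranks j.  Every omitted term in the full step-up minimum exceeds the
    cutoff, so the result equals full BH on the complete list wherever
    q <= cutoff -- the whole decision-relevant region -- and is never
    smaller elsewhere.
    """
    p = np.asarray(p_sub, dtype=float)
    if np.any(np.diff(p) < 0):
        raise ValueError("p_sub must be sorted ascending")
    if p.size and p[-1] > cutoff:
        raise ValueError("p_sub contains values above the cutoff")
    if m_total < p.size:
        raise ValueError("m_total smaller than the number of P values")
    if p.size == 0:
        return p
    ranks = np.arange(1, p.size + 1)
    q = np.minimum.accumulate((p * m_total / ranks)[::-1])[::-1]
    return np.minimum(q, 1.0)


def add_bh_q(records: pd.DataFrame, m_total: int | None = None) -> pd.DataFrame:
    """Attach a ``q`` column by BH over the given records (sorted internally)."""
    out = records.copy()
    order = np.argsort(out["p"].to_numpy(), kind="stable")
    q = bh_q_below_cutoff(out["p"].to_numpy()[order], m_total or len(out))
    out["q"] = np.empty(len(out))
    out.iloc[order, out.columns.get_loc("q")] = q
    return out


def select_instruments(cis: pd.DataFrame, trans: pd.DataFrame) -> pd.DataFrame:
    """Pick instrumental SNPs and pair them with their cis and trans genes.

    A SNP qualifies when it has exactly one cis gene at Q < 0.1 while every
    other cis association has raw P > 0.1 (pleiotropy filter); it is paired
    with each of its trans genes at Q < 0.5.  Gene names containing '-', '.'
    or '_' are excluded.  ``cis`` needs columns snp, gene, beta, p, q;
    ``trans`` needs snp, gene, beta, q.
    """
    for df, cols in ((cis, {"snp", "gene", "beta", "p", "q"}), (trans, {"snp", "gene", "beta", "q"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {missing}")
    bad_name = cis["gene"].str.contains(r"[-._]")
    cis = cis[~bad_name]
    trans = trans[~trans["gene"].str.contains(r"[-._]")]

    rows = []
    trans_by_snp = dict(iter(trans[trans["q"] < TRANS_Q].groupby("snp")))
    for snp, grp in cis.groupby("snp"):
        sig = grp[grp["q"] < CIS_Q]
        if len(sig) != 1:
            continue
        others = grp.drop(sig.index)
        if (others["p"] <= PLEIOTROPY_P).any():
            continue  # pleiotropy suspect
        hit = sig.iloc[0]
        for _, t in trans_by_snp.get(snp, pd.DataFrame(columns=trans.columns)).iterrows():
            if t["gene"] == hit["gene"]:
                continue
            rows.append(
                {
                    "snp": snp,
                    "cis_gene": hit["gene"],
                    "cis_beta": hit["beta"],
                    "cis_q": hit["q"],
                    "trans_gene": t["gene"],
                    "trans_beta": t["beta"],
                    "trans_q": t["q"],
                    "tsls_estimate": tsls_effect(hit["beta"], t["beta"]),
                }
            )
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "snp",
            "cis_gene",
            "cis_beta",
            "cis_q",
            "trans_gene",
            "trans_beta",
            "trans_q",
            "tsls_estimate",
        ],
    )


def tsls_effect(cis_beta: float, trans_beta: float) -> float:
    """Two-stage least-squares regulation effect: trans beta over cis beta."""
    if cis_beta == 0:
        raise ValueError("cis effect size must be nonzero")
    return trans_beta / cis_beta


def unique_instruments(genotype_vectors) -> int:
    """Count genotype-distinct instruments; x and 2 - x (allele flip) are one."""
    classes: list[np.ndarray] = []
    length = None
    for v in genotype_vectors:
        v = np.asarray(v)
        if length is None:
            length = v.size
        elif v.size != length:
            raise ValueError("genotype vectors differ in length")
        if not any(np.array_equal(v, c) or np.array_equal(v, 2 - c) for c in classes):
            classes.append(v)
    return len(classes)


def relative_variability(estimates) -> float:
    """(max - min) / (2 max |estimate|): 0 for identical estimates, 0.5 when
    one instrument sees no effect, 1 for equal-magnitude opposite signs."""
    e = np.asarray(estimates, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two estimates")
    m = np.abs(e).max()
    if m == 0:
        raise ValueError("all estimates are zero")
    return float((e.max() - e.min()) / (2.0 * m))


def assemble_cgrn(
    instruments: pd.DataFrame, genotypes: pd.DataFrame | dict, cell_state: str = ""
) -> pd.DataFrame:
    """Aggregate per-instrument 2SLS estimates into regulation edges.

    ``genotypes`` maps SNP id to its donor genotype vector (used for the
    uniqueness count).  Edges with fewer than 2 unique instruments are
    discarded (logged); strength is the median estimate; the relative
    variability and a sign-conflict flag summarize robustness.
    """
    rows = []
    for (reg, tar), grp in instruments.groupby(["cis_gene", "trans_gene"]):
        vecs = [np.asarray(genotypes[s]) for s in grp["snp"]]
        n_unique = unique_instruments(vecs)
        if n_unique < 2:
            logger.info("edge %s->%s discarded: %d unique instrument(s)", reg, tar, n_unique)
            continue
        est = grp["tsls_estimate"].to_numpy()
        rows.append(
            {
                "regulator": reg,
                "target": tar,
                "cell_state": cell_state,
                "n_instruments": n_unique,
                "strength_median": float(np.median(est)),
                "rel_variability": relative_variability(est),
                "conflict_flag": bool(np.sign(est).max() != np.sign(est).min()),
                "estimates": list(est),
            }
        )
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "regulator",
            "target",
            "cell_state",
            "n_instruments",
            "strength_median",
            "rel_variability",
            "conflict_flag",
            "estimates",
        ],
    )


def infer_cgrn(
    records: pd.DataFrame,
    donor_genotypes: dict,
    cell_state: str = "",
    m_trans_total: int | None = None,
) -> pd.DataFrame:
    """Full network inference from one association table.

    Splits cis and trans records, computes BH Q values separately (``m_trans
    _total`` supplies the global trans test count when the scan only kept
    sub-cutoff P values), selects instruments, and assembles edges.
    """
    cis = records[records["cis_or_trans"] == "cis"].copy()
    trans = records[records["cis_or_trans"] == "trans"].copy()
    cis = add_bh_q(cis)
    trans = add_bh_q(trans, m_total=m_trans_total)
    inst = select_instruments(cis, trans)
    return assemble_cgrn(inst, donor_genotypes, cell_state)
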