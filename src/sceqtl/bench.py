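"""Benchmarking and diagnostic statistics.

Effect-size estimation quality is summarized by a through-origin regression
slope of estimates on truth (systematic bias: deviation from 1) and by
1 - Pearson R (variance), optionally stratified by expression quartile.
P-value collections are checked against Uniform(0,1) with the two-sided KS
test, a 20-bin histogram with 3 sqrt(N) error bars, and Storey's pi1.
Networks inferred in two cell states are compared by edge overlap,
directionality agreement, Pearson R of strengths, and a scale factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "bias_variance",
    "storey_pi0",
    "storey_pi1",
    "pvalue_uniformity",
    "qq_data",
    "compare_cgrns",
    "complexity_speedup",
]


def complexity_speedup(n_snp: float, n_gene: float, n_donor: float, n_cell: float) -> dict:
    """Floating-point operation counts of an eQTL scan, dense vs compressed.

    Dense mixed-model mappers (FaST-LMM/GEMMA-style) cost
    (n_SNP + n_donor)(n_gene + n_cell) n_cell; the donor-compressed route
    costs n_gene n_cell + (n_SNP + n_donor)(n_gene + n_donor) n_donor.
    Returns both counts and their ratio (the expected acceleration).
    """
    dense = (n_snp + n_donor) * (n_gene + n_cell) * n_cell
    compressed = n_gene * n_cell + (n_snp + n_donor) * (n_gene + n_donor) * n_donor
    return {"dense_ops": dense, "compressed_ops": compressed, "speedup": dense / compressed}


def bias_variance(
    est: np.ndarray, truth: np.ndarray, strata: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-stratum bias slope and variance of effect-size estimation.

    bias_slope is the no-intercept least-squares slope of ``est`` on
    ``truth`` (sum xy / sum x^2); variance is 1 - PearsonR(est, truth).
    Strata with fewer than 3 pairs are skipped.  Pass strata=None for a
    single overall stratum.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("est and truth must match")
    if strata is None:
        strata = np.zeros(est.size, dtype=int)
    strata = np.asarray(strata)
    rows = []
    for lab in pd.unique(strata):
        m = strata == lab
        if m.sum() < 3:
            continue
        x, y = truth[m], est[m]
        slope = float((x @ y) / (x @ x))
        r = float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 and y.std() > 0 else np.nan
        rows.append(
            {"stratum": lab, "n": int(m.sum()), "bias_slope": slope, "variance": 1.0 - r}
        )
    return pd.DataFrame(rows)


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's estimate of the null fraction pi0.

    Computes pi0(L) = #{p > L} / (n (1 - L)) on the grid L = 0.05..0.95 and
    extrapolates to L -> 1 with a cubic polynomial smoother, clipped to
    [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > L).mean() / (1.0 - L) for L in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coeffs, 1.0))
    return float(np.clip(pi0, 0.0, 1.0))


def storey_pi1(p: np.ndarray) -> float:
    """Estimated fraction of true alternatives, 1 - pi0, clipped to [0, 1]."""
    return 1.0 - storey_pi0(p)


def pvalue_uniformity(p: np.ndarray, n_bins: int = 20) -> dict:
    """Uniformity diagnostics for a P-value collection.

    Returns the two-sided KS statistic and P against Uniform(0,1), a
    histogram over ``n_bins`` equal bins on [0, 1] with per-bin 3 sqrt(N)
    error bars, and Storey's pi1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    ks = scipy.stats.kstest(p, "uniform")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "hist_counts": counts,
        "hist_edges": edges,
        "hist_errorbars": 3.0 * np.sqrt(counts),
        "pi1": storey_pi1(p),
    }


def qq_data(p: np.ndarray) -> pd.DataFrame:
    """Expected-vs-observed quantile table for a QQ plot.

    observed = sorted p; expected = (i - 0.5) / n; both also emitted on the
    -log10 scale.  Sorted ascending in expected.
    """
    p = np.sort(np.asarray(p, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected": expected,
            "observed": p,
            "expected_nlog10": -np.log10(expected),
            "observed_nlog10": -np.log10(np.maximum(p, 1e-300)),
        }
    )


def qq_bulk_slope(p: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Through-origin slope of observed on expected quantiles over the bulk
    (expected quantiles between ``lo`` and ``hi``) of a QQ table."""
    tab = qq_data(p)
    m = (tab["expected"] >= lo) & (tab["expected"] <= hi)
    x = tab.loc[m, "expected"].to_numpy()
    y = tab.loc[m, "observed"].to_numpy()
    return float((x @ y) / (x @ x))


def compare_cgrns(A: pd.DataFrame, B: pd.DataFrame) -> dict:
    """Compare two inferred networks.

    overlap_rate = |A and B| / min(|A|, |B|) over (regulator, target) keys;
    on the overlap: directionality_diff = fraction with opposite strength
    signs, pearson_r of strengths, and regulation_scale = through-origin
    slope of B on A strengths, replaced by its reciprocal when < 1 (so
    identical networks give 1).  With an empty overlap the latter three are
    NaN.
    """
    key = ["regulator", "target"]
    a = A.set_index(key)["strength_median"]
    b = B.set_index(key)["strength_median"]
    common = a.index.intersection(b.index)
    denom = min(len(a), len(b))
    overlap = len(common) / denom if denom else np.nan
    if len(common) == 0:
        return {
            "overlap_rate": overlap,
            "directionality_diff": np.nan,
            "pearson_r": np.nan,
            "regulation_scale": np.nan,
        }
    x = a.loc[common].to_numpy()
    y = b.loc[common].to_numpy()
    direc = float((np.sign(x) != np.sign(y)).mean())
    r = float(np.corrcoef(x, y)[0, 1]) if len(common) > 1 and x.std() > 0 and y.std() > 0 else np.nan
    scale = float((x @ y) / (x @ x))
    if 0 < abs(scale) < 1:
        scale = 1.0 / scale
    return {
        "overlap_rate": overlap,
        "directionality_diff": direc,
        "pearson_r": r,
        "regulation_scale": scale,
    }
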