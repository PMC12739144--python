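"""Covariate-parameterized Beta-null recalibration of interaction P values.

Interaction tests on sparse single-cell data can be miscalibrated in ways
that depend on per-gene or per-SNP properties (expression level, zero
fraction, allele frequency).  The remedy: fit, on null P values from a
simulated effect-free dataset, the model

    p ~ Beta(exp(a0 + a1 x), exp(b0 + b1 x))

where x is one candidate parameter (standardized), then replace each observed
P value by the fitted Beta CDF at its own x.  If the null model is right this
is the probability integral transform and calibrated null P values are
uniform.  Calibration is monotone in p at fixed x, so it never reorders P
values sharing a covariate value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from sceqtl.data import Dataset
from sceqtl.qc import NormalizedExpression, pseudobulk_lcpm

__all__ = [
    "CANDIDATE_PARAMETERS",
    "candidate_parameter",
    "BetaNullModel",
    "fit_beta_null",
    "apply_calibration",
    "select_best_parameter",
]

P_CLIP = 1e-300

CANDIDATE_PARAMETERS = (
    "lcpm",
    "n0",
    "lcpmmin",
    "lcpmdiff",
    "lcpmdiffabs",
    "n0min",
    "n0diff",
    "n0diffabs",
    "maf",
    "l0",
)


def _zero_fraction(counts) -> np.ndarray:
    import scipy.sparse as sp

    X = sp.csr_matrix(counts)
    return 1.0 - np.asarray((X > 0).sum(axis=1)).ravel() / X.shape[1]


def candidate_parameter(
    name: str,
    ds: Dataset,
    norm: NormalizedExpression | None = None,
    lambda_hats: np.ndarray | None = None,
    state_pair: tuple | None = None,
) -> np.ndarray:
    """Per-gene (or per-SNP, for ``maf``) values of one candidate parameter.

    lcpm: pseudo-bulk log(CPM+1); n0: fraction of zero-count cells per gene;
    *min / *diff / *diffabs: per-state minimum, state-A minus state-B
    difference, and its absolute value; maf: min(f, 1-f) of the alt-allele
    frequency across donors; l0: the gene's lambda-hat.
    """
    if name not in CANDIDATE_PARAMETERS:
        raise ValueError(f"unknown candidate parameter {name!r}")
    if name == "maf":
        f = ds.genotypes.astype(float).mean(axis=1) / 2.0
        return np.minimum(f, 1.0 - f)
    if name == "l0":
        if lambda_hats is None:
            raise ValueError("l0 requires lambda_hats")
        return np.asarray(lambda_hats, dtype=float)
    base, variant = (name[:-3], "min") if name.endswith("min") else (
        (name[:-7], "diffabs") if name.endswith("diffabs") else (
            (name[:-4], "diff") if name.endswith("diff") else (name, None)
        )
    )
    func = pseudobulk_lcpm if base == "lcpm" else _zero_fraction
    if variant is None:
        return func(ds.counts)
    if state_pair is None:
        raise ValueError(f"{name} requires a state pair")
    state_a, state_b = state_pair
    states = ds.cell_meta["state"].to_numpy()
    va = func(ds.counts[:, states == state_a])
    vb = func(ds.counts[:, states == state_b])
    if variant == "min":
        return np.minimum(va, vb)
    diff = va - vb
    return np.abs(diff) if variant == "diffabs" else diff


@dataclass
class BetaNullModel:
    """Fitted Beta-null calibration for one candidate parameter."""

    param_name: str
    alpha0: float
    alpha1: float
    beta0: float
    beta1: float
    x_mean: float
    x_sd: float

    def shapes(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = (np.asarray(x, dtype=float) - self.x_mean) / self.x_sd
        return np.exp(self.alpha0 + self.alpha1 * z), np.exp(self.beta0 + self.beta1 * z)

    def apply(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        return apply_calibration(self, p, x)

    def to_dict(self) -> dict:
        return {
            "param_name": self.param_name,
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "x_mean": self.x_mean,
            "x_sd": self.x_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaNullModel":
        return cls(**d)


def fit_beta_null(
    p_null: np.ndarray,
    x: np.ndarray,
    lr: float = 1e-6,
    epochs: int = 20_000,
    param_name: str = "",
) -> BetaNullModel:
    """Fit Beta(exp(a0+a1 x), exp(b0+b1 x)) to null P values by gradient ascent.

    Full-batch ascent on the summed log-likelihood from (0,0,0,0) with the
    stated learning rate and epoch count as defaults; gradients use digamma
    terms.  P values below 1e-300 are clipped up first; x is standardized and
    the normalization stored.  A constant x freezes the slope parameters at 0
    with a warning.  The final log-likelihood is checked to be >= the initial.
    """
    p = np.asarray(p_null, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    p = np.clip(p, P_CLIP, 1.0 - 1e-16)
    x = np.asarray(x, dtype=float)
    if p.shape != x.shape:
        raise ValueError("p and x must match")
    x_mean, x_sd = float(x.mean()), float(x.std())
    frozen = x_sd == 0
    if frozen:
        import warnings

        warnings.warn("constant calibration parameter; slopes frozen at 0")
        x_sd = 1.0
    z = (x - x_mean) / x_sd
    lp, l1p = np.log(p), np.log1p(-p)

    theta = np.zeros(4)  # a0, a1, b0, b1

    def loglik(th):
        a = np.exp(th[0] + th[1] * z)
        b = np.exp(th[2] + th[3] * z)
        return float(
            np.sum(
                scipy.special.gammaln(a + b)
                - scipy.special.gammaln(a)
                - scipy.special.gammaln(b)
                + (a - 1) * lp
                + (b - 1) * l1p
            )
        )

    ll0 = loglik(theta)
    for _ in range(epochs):
        a = np.exp(theta[0] + theta[1] * z)
        b = np.exp(theta[2] + theta[3] * z)
        psi_ab = scipy.special.digamma(a + b)
        ga = a * (psi_ab - scipy.special.digamma(a) + lp)
        gb = b * (psi_ab - scipy.special.digamma(b) + l1p)
        grad = np.array([ga.sum(), (ga * z).sum(), gb.sum(), (gb * z).sum()])
        if frozen:
            grad[1] = grad[3] = 0.0
        theta = theta + lr * grad
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError("divergence during Beta-null fitting")
    if loglik(theta) < ll0 - 1e-9 * max(1.0, abs(ll0)):
        raise RuntimeError("Beta-null fit failed to improve the likelihood")
    return BetaNullModel(
        param_name=param_name,
        alpha0=float(theta[0]),
        alpha1=float(theta[1]),
        beta0=float(theta[2]),
        beta1=float(theta[3]),
        x_mean=x_mean,
        x_sd=x_sd,
    )


def apply_calibration(model: BetaNullModel, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Calibrated P value: the fitted Beta CDF evaluated at p, per-entry x."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    a, b = model.shapes(x)
    return scipy.stats.beta.cdf(p, a, b)


def select_best_parameter(null_runs: dict) -> tuple[str, pd.DataFrame]:
    """Pick the candidate whose calibrated null P values look most uniform.

    ``null_runs`` maps parameter name to its calibrated null P vector.
    Primary criterion: KS distance to Uniform(0,1); secondary: Storey pi1;
    final tie-break: lexicographic name.  Returns the winner plus the full
    diagnostic table.
    """
    from sceqtl.bench import storey_pi1

    if not null_runs:
        raise ValueError("empty candidate set")
    rows = []
    for name, p in null_runs.items():
        p = np.asarray(p, dtype=float)
        ks = scipy.stats.kstest(p, "uniform")
        rows.append(
            {"param": name, "ks_distance": ks.statistic, "ks_p": ks.pvalue, "pi1": storey_pi1(p)}
        )
    table = pd.DataFrame(rows).sort_values(
        ["ks_distance", "pi1", "param"], kind="stable"
    ).reset_index(drop=True)
    return table.loc[0, "param"], table
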