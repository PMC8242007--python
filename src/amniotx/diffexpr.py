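"""Gene-wise linear models with empirical-Bayes variance moderation.

Each gene is fit by ordinary least squares against a shared design
(intercept, group indicator, optional covariates).  Gene-wise residual
variances are then shrunk toward a common prior under the hierarchical
model s_g^2 ~ s0^2 * chi2_{d_g}/d_g with a scaled inverse-chi-square
prior on the true variances; the prior degrees of freedom d0 and prior
variance s0^2 are estimated by moment matching on log s_g^2 using
digamma/trigamma identities of the log-F distribution.  The moderated
t-statistic divides the group coefficient by the posterior standard
deviation and is referred to a t distribution on d0 + d_g degrees of
freedom.  Multiple testing uses Benjamini-Hochberg, and a gene is called
differentially expressed when both the fold change exceeds the threshold
(strictly, on the linear scale) and q falls below its threshold.

The positive fold-change direction is "higher in the imminent-delivery
group": code the group indicator as 1 for samples delivering within 24 h.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

logger = logging.getLogger("amniotx")


@dataclass
class GeneFit:
    """Per-gene OLS results: group coefficient, residual variance, shared
    residual df, and the unit-variance standard error scale of the
    coefficient (sqrt of the design's (X'X)^-1 diagonal entry)."""

    genes: list[str]
    beta: np.ndarray
    sigma2: np.ndarray
    df_residual: int
    se_unit: float


@dataclass
class ModerationParams:
    """Estimated prior df (may be +inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be nonnegative")
        if not np.isfinite(self.s0_sq) or self.s0_sq <= 0:
            raise ValueError("prior variance must be finite and positive")


def fit_gene_models(
    expr: pd.DataFrame,
    design: np.ndarray,
    coef_index: int = 1,
) -> GeneFit:
    """OLS of every gene on a shared full-rank design.

    ``design`` is samples x p with an intercept column; ``coef_index``
    selects the coefficient of interest (default: second column, the
    group indicator).
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n != expr.shape[1]:
        raise ValueError("design rows must equal the number of samples")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    Y = expr.to_numpy(dtype=float).T           # samples x genes
    pinv = np.linalg.pinv(X)
    coefs = pinv @ Y                           # p x genes
    resid = Y - X @ coefs
    df_residual = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df_residual
    # snap round-off residuals of exactly-fitting genes to zero
    scale = (Y ** 2).sum(axis=0) / df_residual
    sigma2[sigma2 < 1e-13 * np.maximum(scale, 1e-300)] = 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    se_unit = float(np.sqrt(xtx_inv[coef_index, coef_index]))
    return GeneFit(
        genes=list(expr.index),
        beta=coefs[coef_index],
        sigma2=sigma2,
        df_residual=df_residual,
        se_unit=se_unit,
    )


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if -step / x < tol:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df_residual: int) -> ModerationParams:
    """Moment-match the scaled-F model of gene variances on the log scale.

    With s^2 ~ s0^2 F(d, d0), e = log s^2 - digamma(d/2) + log(d/2) has
    mean log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2); inverting the trigamma gives d0.
    A sample variance of e at or below trigamma(d/2) yields d0 = +inf
    (complete pooling).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    positive = sigma2 > 0
    if positive.sum() == 0:
        raise ValueError("all gene variances are zero: moderation is degenerate")
    if positive.sum() < 10:
        warnings.warn("fewer than 10 genes with positive variance: hyperparameter "
                      "estimates are unstable", stacklevel=2)
    if not positive.all():
        warnings.warn(f"excluding {np.sum(~positive)} zero-variance genes from "
                      "hyperparameter estimation", stacklevel=2)
    s2 = sigma2[positive]
    d = float(df_residual)
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderate(
    fits: GeneFit,
    params: ModerationParams | None = None,
) -> tuple[ModerationParams, np.ndarray, np.ndarray]:
    """Shrink gene variances toward the prior and compute moderated t and p.

    ``params`` overrides the estimated hyperparameters (d0 = 0 gives the
    ordinary t; d0 = +inf pools all genes at the prior variance).
    Returns (params, moderated t, two-sided p).
    """
    if params is None:
        params = estimate_prior(fits.sigma2, fits.df_residual)
    d0, s0_sq = params.d0, params.s0_sq
    d = float(fits.df_residual)
    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * fits.sigma2) / (d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.beta / (fits.se_unit * np.sqrt(s2_post))
    t = np.where(np.isnan(t), 0.0, t)          # 0/0: no effect, no evidence
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return params, t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the input order;
    a stable sort makes tied p map to identical q.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(
    fits: GeneFit,
    t: np.ndarray,
    p: np.ndarray,
    fc_threshold: float = 1.25,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Assemble the differential-expression table and apply the joint call.

    A gene is DE iff its linear-scale fold change 2^|log2FC| strictly
    exceeds ``fc_threshold`` and its q-value is strictly below
    ``q_threshold``.
    """
    q = bh_adjust(p)
    log2fc = fits.beta
    fc = 2.0 ** np.abs(log2fc)
    is_de = (fc > fc_threshold) & (q < q_threshold)
    result = pd.DataFrame({
        "gene": fits.genes,
        "log2_fc": log2fc,
        "fold_change": np.sign(log2fc) * fc,
        "t": t,
        "p": p,
        "q": q,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "is_de": is_de,
    }).set_index("gene")
    logger.info("DE calls: %d of %d genes (%d up, %d down)",
                int(is_de.sum()), len(result),
                int((is_de & (log2fc > 0)).sum()),
                int((is_de & (log2fc < 0)).sum()))
    return result


def run_de(
    expr: pd.DataFrame,
    group_indicator: np.ndarray,
    covariates: np.ndarray | None = None,
    fc_threshold: float = 1.25,
    q_threshold: float = 0.1,
) -> tuple[pd.DataFrame, ModerationParams]:
    """Fit, moderate, adjust, and call in one step.

    ``group_indicator`` is 1 for the imminent-delivery group so positive
    fold changes mean up-regulation with imminent delivery.
    """
    g = np.asarray(group_indicator, dtype=float)
    cols = [np.ones_like(g), g]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    design = np.column_stack(cols)
    fits = fit_gene_models(expr, design, coef_index=1)
    params, t, p = moderate(fits)
    return call_de(fits, t, p, fc_threshold, q_threshold), params
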