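"""Batch-effect removal and principal-component analysis.

Batch correction fits, per gene, an ordinary least-squares model of
expression on protected covariates plus sum-to-zero-coded batch
indicators and subtracts only the fitted batch component, the standard
linear-model approach for expression matrices.  Protected covariates
(by default the study group) are included in the fit so their effects
are not absorbed into the batch term.  PCA operates on the gene-centered
matrix of all genes via singular value decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("amniotx")


@dataclass
class PCAResult:
    """Sample scores, per-component variance fractions, and gene loadings."""

    scores: np.ndarray            # n_samples x n_components
    variance_fractions: np.ndarray
    loadings: np.ndarray          # n_genes x n_components
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if (self.variance_fractions < 0).any():
            raise ValueError("variance fractions must be nonnegative")
        if self.variance_fractions.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def _sum_to_zero_batch(batch: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding: levels 1..B-1 get indicator columns,
    the last level is coded -1 in every column."""
    levels = sorted(pd.unique(batch).tolist())
    n = len(batch)
    B = np.zeros((n, len(levels) - 1))
    for j, level in enumerate(levels[:-1]):
        B[batch == level, j] = 1.0
    B[batch == levels[-1], :] = -1.0
    return B, levels


def remove_batch_effects(
    expr: pd.DataFrame,
    batch,
    protect: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Subtract the fitted additive batch component from each gene.

    Parameters
    ----------
    expr : genes x samples log2 matrix.
    batch : per-sample batch labels (length = n samples).
    protect : optional per-sample covariates (e.g. a group indicator)
        whose effects must survive correction.

    A single batch level returns the input unchanged.  A rank-deficient
    combined design (batch confounded with protected covariates) raises.
    """
    batch = np.asarray(batch)
    if batch.shape[0] != expr.shape[1]:
        raise ValueError("batch labels must match the number of samples")
    levels, counts = np.unique(batch, return_counts=True)
    if len(levels) < 2:
        return expr.copy()
    if (counts == 1).any():
        warnings.warn("a batch contains a single sample; its correction is "
                      "estimated from that sample alone", stacklevel=2)

    n = expr.shape[1]
    X = np.ones((n, 1))
    if protect is not None:
        P = np.asarray(protect, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        X = np.column_stack([X, P])
    B, _ = _sum_to_zero_batch(batch)
    full = np.column_stack([X, B])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("design is rank deficient: batch is confounded with "
                         "the protected covariates")

    Y = expr.to_numpy(dtype=float).T        # samples x genes
    coef, *_ = np.linalg.lstsq(full, Y, rcond=None)
    gamma = coef[X.shape[1]:, :]            # batch coefficients only
    corrected = (Y - B @ gamma).T
    logger.info("removed batch effects across %d batches (%d genes, %d samples)",
                len(levels), *expr.shape)
    return pd.DataFrame(corrected, index=expr.index, columns=expr.columns)


def pca(expr: pd.DataFrame) -> PCAResult:
    """PCA of samples on the gene-centered expression matrix.

    Components come from the SVD of the centered matrix; the variance
    fraction of component k is its squared singular value over the total.
    Component signs are arbitrary.
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    total = (Xc ** 2).sum()
    if total == 0:
        warnings.warn("constant expression matrix: all variance fractions are 0",
                      stacklevel=2)
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    fractions = (s ** 2) / total if total > 0 else np.zeros_like(s)
    scores = U * s
    return PCAResult(
        scores=scores,
        variance_fractions=fractions,
        loadings=Vt.T,
        sample_ids=list(expr.columns),
    )


def correlate_pc(pca_result: PCAResult, k: int, covariate) -> tuple[float, float]:
    """Pearson correlation (and two-sided t-based p) between component ``k``
    scores (0-based) and a per-sample covariate."""
    covariate = np.asarray(covariate, dtype=float)
    scores = pca_result.scores[:, k]
    if covariate.shape[0] != scores.shape[0]:
        raise ValueError("covariate length must equal the number of samples")
    if np.std(covariate) == 0:
        raise ValueError("covariate has zero variance")
    r, p = stats.pearsonr(scores, covariate)
    return float(r), float(p)
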