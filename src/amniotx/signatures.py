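"""Tissue/cell-type signatures, Z-score comparison, and gene-set enrichment.

A gene is specific to a tissue when its expression in that tissue is at
least ``ratio`` times (default 30, inclusive) the median of the other
tissues' values; the signature of a tissue keeps up to ``top_n`` such
genes ranked by the specificity ratio.  Per-sample signature scores
standardize each member gene against the reference study group (term
deliveries) and average the resulting Z scores over the top genes;
group differences are tested by a per-signature linear model with BH
adjustment across signatures.  Enrichment of a gene list against a
gene-set collection uses the upper-tail hypergeometric test on the
expression-matrix universe, again BH-adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger("amniotx")

_EPS = 1e-8


@dataclass
class SignatureDefinition:
    """One tissue/cell-type signature: genes ordered by descending
    specificity ratio, with the ratios."""

    name: str
    genes: list[str]
    ratios: list[float]


def _atlas_frame(atlas) -> pd.DataFrame:
    # accept either a TissueAtlas or a plain tissues x genes DataFrame
    return atlas.values if hasattr(atlas, "tissues") else atlas


def define_signatures(
    atlas,
    ratio: float = 30.0,
    top_n: int = 20,
    other_tissues: str = "pooled",
) -> dict[str, SignatureDefinition]:
    """Screen each tissue for genes whose expression is >= ``ratio`` times
    that of the other tissues.

    ``other_tissues`` chooses the comparator: ``"pooled"`` (default) takes
    the median over all other tissues' values pooled together; ``"max"``
    takes the maximum of the other tissues' values.  A zero comparator is
    replaced by the pseudocount 1e-8, keeping ratios finite for genes
    silent outside their tissue without perturbing attained ratios (the
    >= 30 boundary stays inclusive).
    """
    frame = _atlas_frame(atlas)
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 tissues to define specificity")
    if other_tissues not in ("pooled", "max"):
        raise ValueError("other_tissues must be 'pooled' or 'max'")
    values = frame.to_numpy(dtype=float)
    genes = np.array(frame.columns)
    signatures: dict[str, SignatureDefinition] = {}
    for t, tissue in enumerate(frame.index):
        others = np.delete(values, t, axis=0)
        denom = others.max(axis=0) if other_tissues == "max" else np.median(others, axis=0)
        ratios = values[t] / np.maximum(denom, _EPS)
        # relative tolerance so float rounding cannot flip the inclusive boundary
        keep = ratios >= ratio * (1.0 - 1e-12)
        # rank by ratio descending, stable in gene order for ties
        order = np.argsort(-ratios[keep], kind="stable")[:top_n]
        kept_genes = genes[keep][order]
        signatures[tissue] = SignatureDefinition(
            name=tissue,
            genes=kept_genes.tolist(),
            ratios=ratios[keep][order].tolist(),
        )
    return signatures


def signatures_to_collection(signatures: dict[str, SignatureDefinition]):
    from .io import GeneSetCollection

    return GeneSetCollection(
        sets={name: sig.genes for name, sig in signatures.items() if sig.genes},
        descriptions={name: "tissue signature" for name in signatures},
    )


def signature_scores(
    expr: pd.DataFrame,
    signatures: dict[str, SignatureDefinition],
    reference_samples,
    top_n: int = 20,
) -> pd.DataFrame:
    """Per-sample average Z score of each signature.

    Each member gene is standardized by the mean and (ddof=1) standard
    deviation computed on ``reference_samples`` only; scores average the
    Z of the first ``top_n`` member genes present in the matrix.  Member
    genes absent from the matrix, or with zero reference variance, are
    dropped with a warning; a signature with no usable genes is omitted.

    Returns samples x signatures.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("reference sample set is empty")
    missing_ref = set(reference_samples) - set(expr.columns)
    if missing_ref:
        raise ValueError(f"reference samples not in matrix: {sorted(missing_ref)[:5]}")

    scores: dict[str, np.ndarray] = {}
    for name, sig in signatures.items():
        present = [g for g in sig.genes if g in expr.index]
        if len(present) < len(sig.genes):
            warnings.warn(
                f"signature {name!r}: {len(sig.genes) - len(present)} member "
                "genes absent from the expression matrix", stacklevel=2)
        usable = []
        for g in present:
            ref = expr.loc[g, reference_samples].to_numpy(dtype=float)
            sd = ref.std(ddof=1) if len(ref) > 1 else 0.0
            if sd == 0:
                warnings.warn(f"signature {name!r}: gene {g} has zero reference "
                              "sd; dropped", stacklevel=2)
                continue
            usable.append((g, ref.mean(), sd))
            if len(usable) == top_n:
                break
        if not usable:
            warnings.warn(f"signature {name!r} has no usable genes; omitted",
                          stacklevel=2)
            continue
        z = np.vstack([
            (expr.loc[g].to_numpy(dtype=float) - m) / sd for g, m, sd in usable
        ])
        scores[name] = z.mean(axis=0)
    return pd.DataFrame(scores, index=expr.columns)


def compare_signatures(
    scores: pd.DataFrame,
    group_labels,
    positive_group: str,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-signature linear model of score on the group indicator.

    With a two-level factor this is the ordinary two-sample comparison:
    the difference is mean(positive group) - mean(other), the p-value the
    pooled-variance t test of the OLS slope.  q adjusts across
    signatures; ``significant`` flags q < ``q_threshold``.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("group labels must match the score table rows")
    x = (labels == positive_group).astype(float)
    n1, n0 = int(x.sum()), int((1 - x).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for name in scores.columns:
        y = scores[name].to_numpy(dtype=float)
        diff = y[x == 1].mean() - y[x == 0].mean()
        df = n1 + n0 - 2
        pooled = (((y[x == 1] - y[x == 1].mean()) ** 2).sum()
                  + ((y[x == 0] - y[x == 0].mean()) ** 2).sum()) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
        if se == 0:
            tstat, p = 0.0, 1.0
        else:
            tstat = diff / se
            p = 2.0 * stats.t.sf(abs(tstat), df)
        rows.append((name, diff, tstat, p))
    result = pd.DataFrame(rows, columns=["signature", "difference", "t", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] < q_threshold
    return result.set_index("signature")


def hypergeometric_enrichment(
    de_list,
    universe,
    genesets,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list in each set.

    For a universe of N genes, a set of K (after intersection with the
    universe), and a list of n, the p-value is P(X >= k) for
    X ~ Hypergeometric(N, K, n) including the observed overlap k.
    q adjusts across the tested sets.
    """
    universe = set(universe)
    de_set = set(de_list)
    if not universe:
        raise ValueError("empty universe")
    if not de_set:
        raise ValueError("empty gene list")
    if not de_set <= universe:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(universe), len(de_set)

    rows = []
    for name, members in genesets.items():
        in_universe = universe.intersection(members)
        K = len(in_universe)
        k = len(de_set & in_universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, N, K, n, k, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["enriched"] = result["q"] < q_threshold
    logger.info("enrichment: %d/%d sets significant at q<%g",
                int(result["enriched"].sum()), len(result), q_threshold)
    return result.set_index("set")
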