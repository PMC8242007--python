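"""Synthetic amniotic-fluid cell-free transcriptome cohorts.

The generator emulates the study design the rest of the pipeline assumes:
38 women sampled by amniocentesis after an episode of preterm labor, of
whom 10 deliver within 24 hours and 28 later.  A single latent
"intra-amniotic inflammation" score per sample drives both (a) the
expression of a planted block of response genes, on the log2 scale, and
(b) a shorter interval from amniocentesis to delivery.  Per-gene residual
variances are drawn from a scaled inverse-chi-square distribution so the
hierarchical model underlying empirical-Bayes variance moderation holds
exactly and its hyperparameters can be recovered.  Additive per-batch,
per-gene shifts emulate processing batches.

Companion generators produce a tissue reference atlas with planted
tissue-specific gene blocks and a gene-set collection with planted
enriched terms, so the signature and enrichment stages are testable with
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GeneSetCollection

GROUP_IMMINENT = "imminent_le_24h"
GROUP_LATER = "later_gt_24h"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort, atlas, and gene-set generators.

    Defaults mirror the study design the pipeline targets: a 38-sample
    cohort split (10, 28), ~2000 genes of which 200 respond to the
    inflammation axis with a 2-fold (1 log2 unit) shift between groups,
    and per-gene variances from a scaled inverse-chi-square(df=4,
    scale=0.05) prior.
    """

    n_genes: int = 2000
    n_samples: int = 38
    n_batches: int = 2
    group_sizes: tuple[int, int] = (10, 28)
    n_response_genes: int = 200
    #: log2 expression shift per unit of latent inflammation; the group
    #: means of the latent score differ by 1, so this equals the expected
    #: log2 fold change between groups.
    effect_size_log2: float = 1.0
    #: scaled inverse-chi-square prior on per-gene residual variances
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.05
    batch_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    #: latent inflammation score: imminent ~ N(z_shift, z_sd_imminent),
    #: later ~ N(0, z_sd_later)
    z_shift: float = 1.0
    z_sd_imminent: float = 0.15
    z_sd_later: float = 0.35
    #: time-to-delivery (weeks) = max(floor, a - b*z + noise)
    ttd_intercept: float = 5.0
    ttd_slope: float = 8.0
    ttd_noise_sd: float = 1.0
    ttd_floor: float = 0.02
    # gene-set annotation parameters
    n_terms: int = 20
    term_size: int = 40
    planted_terms: int = 3
    planted_fraction: float = 0.5
    # tissue atlas parameters
    n_tissues: int = 5
    sig_block_size: int = 20
    sig_fold: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_batches) <= 0:
            raise ValueError("n_genes, n_samples and n_batches must be positive")
        if len(self.group_sizes) != 2 or min(self.group_sizes) < 0:
            raise ValueError("group_sizes must be a pair of nonnegative counts")
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError(
                f"group_sizes {self.group_sizes} do not sum to n_samples={self.n_samples}"
            )
        if self.n_response_genes > self.n_genes:
            raise ValueError("n_response_genes exceeds n_genes")
        if self.term_size > self.n_genes:
            raise ValueError("term_size exceeds the gene universe")
        for name in ("var_prior_df", "var_prior_scale", "batch_sd",
                     "z_sd_imminent", "z_sd_later", "ttd_noise_sd", "ttd_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Cohort:
    """A generated cohort: expression, sample metadata, and ground truth.

    ``expression`` is a genes x samples log2 matrix whose columns match
    ``samples['sample_id']`` in order.  ``truth`` records the planted
    response genes, the per-sample latent inflammation score, and (once
    gene sets are generated) the planted enriched terms.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.samples["sample_id"]):
            raise ValueError("expression columns must equal sample ids, same order")
        resp = set(self.truth.get("response_genes", ()))
        if not resp <= set(self.expression.index):
            raise ValueError("truth response genes not a subset of expression rows")


@dataclass
class TissueAtlas:
    """Nonnegative linear-scale reference expression, tissues x genes."""

    values: pd.DataFrame  # index = tissue labels, columns = gene ids

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("atlas values must be nonnegative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated tissue labels in atlas")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated gene identifiers in atlas")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a synthetic cohort; deterministic given ``config`` (incl. seed).

    Sampling order is fixed, so identical configs give byte-identical
    output.  The imminent group's latent score is high enough that its
    time-to-delivery is floored near zero (mean well below 24 h = 0.143
    weeks); the later group spans roughly 1-10 weeks.
    """
    rng = np.random.default_rng(config.seed)
    n0, n1 = config.group_sizes
    n = config.n_samples

    group = np.array([GROUP_IMMINENT] * n0 + [GROUP_LATER] * n1)
    z = np.concatenate([
        rng.normal(config.z_shift, config.z_sd_imminent, n0),
        rng.normal(0.0, config.z_sd_later, n1),
    ])
    ttd = np.maximum(
        config.ttd_floor,
        config.ttd_intercept - config.ttd_slope * z + rng.normal(0.0, config.ttd_noise_sd, n),
    )
    ga_amnio = np.clip(rng.normal(31.0, 2.3, n), 24.0, 35.0)
    # term (reference) deliveries: gestational age at delivery >= 37 weeks
    reference = (ga_amnio + ttd) >= 37.0
    # noisy surrogate of an IL-6 >= 2.6 ng/ml determination
    il6_high = (z + rng.normal(0.0, 0.4, n)) > 0.55
    batch = np.array([f"B{i % config.n_batches + 1}" for i in range(n)])

    gene_ids = _gene_ids(config.n_genes)
    response_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_response_genes, replace=False)
    )

    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    # scaled inverse-chi-square: sigma2 = df*scale / chi2_df
    sigma2 = (
        config.var_prior_df * config.var_prior_scale
        / rng.chisquare(config.var_prior_df, config.n_genes)
    )
    batch_offsets = rng.normal(0.0, config.batch_sd, (config.n_genes, config.n_batches))
    batch_idx = np.array([int(b[1:]) - 1 for b in batch])

    expr = mu[:, None] + batch_offsets[:, batch_idx]
    expr[response_idx] += config.effect_size_log2 * z[None, :]
    expr += rng.standard_normal((config.n_genes, n)) * np.sqrt(sigma2)[:, None]

    sample_ids = _sample_ids(n)
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group,
        "batch": batch,
        "gestational_age_at_amnio": ga_amnio,
        "time_to_delivery": ttd,
        "reference_group": reference,
        "il6_high": il6_high,
    })
    truth = {
        "response_genes": [gene_ids[i] for i in response_idx],
        "inflammation": dict(zip(sample_ids, z.tolist())),
        "config": asdict(config),
    }
    return Cohort(expression=expression, samples=samples, truth=truth)


def generate_atlas(config: SimConfig) -> TissueAtlas:
    """Build a tissue atlas with one disjoint specific gene block per tissue.

    Background expression of a gene is a constant level shared across
    tissues (drawn once per gene); each tissue's block genes are raised to
    ``sig_fold`` times their background level in that tissue only, so the
    tissue-vs-rest median ratio of a block gene is exactly ``sig_fold``
    and of a background gene exactly 1.
    """
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if config.sig_block_size < 1:
        raise ValueError("sig_block_size must be >= 1")
    if config.n_tissues * config.sig_block_size > config.n_genes:
        raise ValueError("tissue blocks exceed the gene universe")
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = _gene_ids(config.n_genes)
    background = rng.uniform(5.0, 15.0, config.n_genes)
    values = np.tile(background, (config.n_tissues, 1))
    for t in range(config.n_tissues):
        block = slice(t * config.sig_block_size, (t + 1) * config.sig_block_size)
        values[t, block] = config.sig_fold * background[block]
    tissues = [f"tissue_{t + 1}" for t in range(config.n_tissues)]
    return TissueAtlas(values=pd.DataFrame(values, index=tissues, columns=gene_ids))


def generate_genesets(config: SimConfig, truth: dict) -> GeneSetCollection:
    """Draw gene-set annotations; the first ``planted_terms`` sets are
    enriched for the cohort's planted response genes.

    Planted sets draw ``planted_fraction`` of their members from the
    response genes and the rest from non-response genes; the remaining
    sets draw uniformly from all genes.  The planted set names are
    appended to ``truth['planted_terms']``.
    """
    if config.term_size > config.n_genes:
        raise ValueError("term_size exceeds the gene universe")
    rng = np.random.default_rng(config.seed + 2)
    gene_ids = np.array(_gene_ids(config.n_genes))
    response = np.array(sorted(truth["response_genes"]))
    non_response = np.setdiff1d(gene_ids, response)

    sets: dict[str, list[str]] = {}
    planted_names: list[str] = []
    n_from_resp = int(round(config.planted_fraction * config.term_size))
    n_from_resp = min(n_from_resp, len(response))
    for i in range(config.n_terms):
        name = f"TERM{i + 1:03d}"
        if i < config.planted_terms:
            members = np.concatenate([
                rng.choice(response, size=n_from_resp, replace=False),
                rng.choice(non_response, size=config.term_size - n_from_resp,
                           replace=False),
            ])
            planted_names.append(name)
        else:
            members = rng.choice(gene_ids, size=config.term_size, replace=False)
        sets[name] = sorted(members.tolist())
    truth["planted_terms"] = planted_names
    return GeneSetCollection(
        sets=sets,
        descriptions={name: "planted" if name in planted_names else "null"
                      for name in sets},
    )
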