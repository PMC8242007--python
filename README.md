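# amniotx

Analysis pipeline for the **amniotic-fluid cell-free transcriptome in
spontaneous preterm labor**: given gene-level log2 expression from
amniotic fluid sampled by amniocentesis after an episode of preterm
labor, the package asks which genes and tissue/cell-type signatures
change when delivery is imminent, and how well the transcriptome
predicts the interval from amniocentesis to delivery.  It is written for
perinatal transcriptomics researchers who want the full workflow —
simulation, preprocessing, inference, prediction, and clinical table
statistics — as tested, scriptable Python rather than a collection of
one-off analysis scripts.

## What it computes

* **Batch correction & PCA** — per-gene least squares on protected
  covariates plus sum-to-zero batch indicators, subtracting only the
  batch component; PCA of the gene-centered matrix by SVD.
* **Moderated differential expression** — gene-wise OLS with
  empirical-Bayes variance moderation: posterior variance
  s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) with (d₀, s₀²) estimated by
  trigamma-inversion moment matching on log s²_g; moderated
  t_g = β̂_g/(se·s̃_g) on d₀ + d df; Benjamini–Hochberg q-values; a gene
  is called DE when fold change > 1.25 and q < 0.1.
* **Tissue/cell-type signatures** — genes whose atlas expression is
  ≥ 30× the median of other tissues form a signature (top 20 by ratio);
  per-sample scores average reference-standardized Z scores; group
  differences tested per signature with BH at q < 0.05.
* **Gene-set enrichment** — upper-tail hypergeometric P(X ≥ k) of DE
  lists against GMT collections on the expression-matrix universe.
* **Time-to-delivery prediction** — sparse-HSIC (HSIC-lasso) feature
  selection, min_{α≥0} ½‖L̄ − Σ_g α_g K̄_g‖²_F + λ‖α‖₁ over centered,
  normalized Gaussian-kernel Gram matrices, with λ bisected to a target
  support; 1000-tree random-forest regression inside leave-one-out
  cross-validation (selection repeated per fold); Spearman ρ, RMSE, and
  AUROC for delivery within 24 h / 1 wk / 2 wk; Jaccard/kappa selection
  stability and a binomial consensus gene list.
* **Clinical characteristics** — median (IQR) with Welch's t,
  n (%) with two-sided Fisher's exact tests.

A synthetic-cohort generator (`amniotx.simulate`) reproduces the study
design the pipeline assumes — 38 samples (10 delivering ≤ 24 h after
amniocentesis, 28 later), a latent inflammation axis driving both a
planted gene block and shorter time-to-delivery, batch structure, a
tissue atlas with planted specificity blocks, and gene sets with planted
enrichment — so every stage is testable against known ground truth.
See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import numpy as np
from amniotx import (SimConfig, generate_cohort, remove_batch_effects,
                     run_de, loocv, evaluate)

cfg = SimConfig(seed=1)                      # 2000 genes x 38 samples
cohort = generate_cohort(cfg)
group = (cohort.samples["group"] == "imminent_le_24h").to_numpy()
expr = remove_batch_effects(cohort.expression,
                            cohort.samples["batch"].to_numpy(),
                            group.astype(float))

de, prior = run_de(expr, group.astype(float))
print(f"DE genes: {int(de.is_de.sum())}  "
      f"(planted: {len(cohort.truth['response_genes'])})")

ttd = cohort.samples["time_to_delivery"].to_numpy()
cv = loocv(expr, ttd, target_size=50, n_trees=1000, seed=1)
m = evaluate(cv, ttd)
print(f"Spearman rho {m.spearman_rho:.2f}, RMSE {m.rmse:.2f} weeks, "
      f"AUROC(24h) {m.auroc[24/168]:.2f}")
```

prints

```
DE genes: 205  (planted: 200)
Spearman rho 0.93, RMSE 1.25 weeks, AUROC(24h) 1.00
```

— the moderated-t stage recovers essentially the planted 200-gene block
at the joint fold-change/q thresholds, and the cross-validated forest
predicts the held-out time-to-delivery to 1.25 weeks (the response sd is
3.3 weeks), separating imminent from later deliveries perfectly on this
noise-free-by-construction cohort.  The same pipeline is available from
the shell: `amniotx all --seed 1 --outdir out/` chains simulation,
preprocessing, DE, enrichment, signatures, and prediction.

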