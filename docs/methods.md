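# Methods

`amniotx` re-implements, as a tested library, the analysis workflow used
to study the cell-free transcriptome of amniotic fluid sampled after an
episode of spontaneous preterm labor: who is about to deliver, which
genes and cell-type signatures change as delivery approaches, and how
well the transcriptome predicts the interval from amniocentesis to
delivery.  This note records the models, the defaults and why, the
numerical choices, and what the synthetic cohorts do and do not show.

## The synthetic cohort generator

No raw cohort is publicly deposited, so the package ships a generator
whose defaults encode the study design the pipeline assumes: 38 samples,
10 in the imminent-delivery group (delivery ≤ 24 h after amniocentesis)
and 28 delivering later, profiled over 2 processing batches on ~2000
genes (log2 scale).

A single latent scalar `z_i` per sample stands in for intra-amniotic
inflammation, the biological driver of imminent delivery.  It is drawn
N(1, 0.15) in the imminent group and N(0, 0.35) in the later group, so
the group means differ by exactly 1: the planted log2 fold change of a
response gene equals `effect_size_log2` (default 1, i.e. 2-fold — strong
inflammatory genes in this setting change severalfold, and 2-fold keeps
the DE power check non-trivial).  Two hundred response genes gain
`effect_size_log2 · z_i`; all genes get a baseline N(7, 1), an additive
per-gene batch offset N(0, 0.3), and residual noise with gene-wise
variance drawn from a scaled inverse-chi-square with df 4 and scale
0.05 — exactly the hierarchical model the variance-moderation stage
assumes, so its hyperparameters are recoverable quantities, not tuning
knobs.

Time-to-delivery (weeks) is `max(0.02, 5 − 8·z_i + N(0, 1))`.  With the
defaults this floors the imminent group near zero (mean ≈ 0.03 weeks,
well below the 24 h = 0.143-week horizon) and spreads the later group
over roughly 1–10 weeks.  Gestational age at amniocentesis is
N(31, 2.3) weeks clipped to [24, 35]; samples whose implied gestational
age at delivery reaches 37 weeks are flagged as the term-delivery
reference group (≈ 11 of 38), which the signature stage standardizes
against.

Companion generators produce (a) a tissue atlas in which each tissue
owns a disjoint gene block raised `sig_fold`-fold above a per-gene
background constant across tissues — so specificity ratios are exactly
`sig_fold` for block genes and exactly 1 otherwise — and (b) gene-set
annotations in which planted terms draw half their members from the
response genes.

What the simulation does **not** emulate: probe-level microarray
structure, correlated gene modules beyond the single inflammation axis,
heavy-tailed or outlying samples, missing clinical covariates, and any
mismatch between array annotation and gene-set namespaces.  Passing
tests therefore demonstrate correctness of the machinery and calibration
under the assumed generative model, not field performance on real
cohorts.

## Batch correction and PCA

Batch correction fits, per gene, least squares of expression on
protected covariates (default: the study group) plus sum-to-zero-coded
batch indicators, and subtracts only the fitted batch component.
Sum-to-zero coding makes the removed component average to zero over
batches, preserving the grand mean; including the protected design keeps
group effects out of the batch term.  The operation is idempotent and
refuses confounded (rank-deficient) designs.  PCA runs on the
gene-centered (not standardized) matrix of all genes via SVD; component
k's variance fraction is its squared singular value over the total.
Component signs are arbitrary, and all tests are sign-invariant.

## Moderated differential expression

Each gene is fit by OLS against (intercept, group indicator); the group
coefficient is the log2 fold change, positive when higher in the
imminent group.  Variances are moderated under the standard
empirical-Bayes hierarchical model: the posterior variance is

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),

with (d₀, s₀²) estimated by moment matching on log s²_g — the mean and
variance of `log s² − ψ(d/2) + log(d/2)` identify s₀² and d₀ through
digamma/trigamma identities of the log-F distribution, with the
trigamma inverted by Newton iteration.  The moderated t is referred to a
t distribution on d₀ + d df (normal when d₀ = ∞; d₀ = 0 recovers the
ordinary t).  This reproduces the R/Bioconductor reference
implementation to machine precision on shared fixtures (a subprocess
cross-check in the test suite).  One simplification: the reference also
caps the total df at the pooled residual df, which only matters when d₀
is estimated enormous; we use d₀ + d as stated.

Residual variances within one relative ulp of an exact fit (below
1e-13 of the per-gene signal energy) are snapped to zero so that
exactly-fitting genes are recognized as degenerate rather than entering
the log-variance moment fit with round-off values.

Multiple testing uses Benjamini–Hochberg (step-up, stable sort so tied p
share q).  A gene is called DE when the linear fold change strictly
exceeds 1.25 **and** q is strictly below 0.1 — both inequalities strict,
matching the printed thresholds.  On default planted cohorts this
yields sensitivity ≥ 0.98 at an observed false-discovery proportion
≤ 0.05 (the acceptance suite requires ≥ 0.9 and ≤ 0.15).

## Tissue signatures and enrichment

A gene is specific to a tissue when its atlas value is at least 30 times
the median of the other tissues' values (inclusive: "30 times higher"
names an attained ratio).  The comparator is the pooled median of other
tissues by default; a stricter max-of-others variant is available.  Zero
comparators are replaced by a 1e-8 pseudocount — replaced, not added, so
attained ratios are not perturbed and the boundary stays exact; a 1e-12
relative tolerance guards the comparison against float rounding.  Each
signature keeps up to 20 genes ranked by ratio (ranking by ratio rather
than absolute expression is a documented choice; it is what
"preferentially expressed" measures).

Signature scores standardize each member gene by the mean and sd of the
term-delivery reference group and average the Z scores, so reference
samples have mean score 0 by construction.  Group comparison is the
per-signature OLS on a group indicator (equivalently the pooled-variance
two-sample t), BH-adjusted across signatures at q < 0.05.

Enrichment of a DE list is the upper-tail hypergeometric probability
P(X ≥ k) with the expression matrix as universe (array practice: genes
off the matrix were never testable), BH-adjusted across sets at
q < 0.05; up- and down-regulated lists are tested separately.

## Time-to-delivery prediction

Feature selection is the sparse-HSIC (HSIC-lasso) program

    min_{α ≥ 0} ½‖L̄ − Σ_g α_g K̄_g‖²_F + λ‖α‖₁,

where K̄_g and L̄ are doubly-centered, Frobenius-normalized Gram
matrices of gene g and of the response, both under Gaussian kernels with
the median-heuristic bandwidth.  The inner product ⟨K̄_g, L̄⟩ is a
normalized HSIC dependence, and ⟨K̄_g, K̄_h⟩ penalizes redundancy, so
the program selects genes that jointly maximize dependence with
time-to-delivery while sharing weight among correlated genes.  It is
solved by cyclic coordinate descent (closed-form nonnegative
soft-threshold updates; the normalized Grams give a unit diagonal).
Instead of fixing a penalty constant, λ is bisected to the largest
support not exceeding a target size (default 50, the parsimony scale of
a "few dozen genes" panel); this makes the sparsity level an
interpretable parameter and the procedure deterministic.

Prediction uses a 1000-tree regression random forest with classic
regression defaults (a third of features per split, minimum node size
5), seeded per fold as `seed + fold`.  Evaluation is leave-one-out: each
fold repeats selection and fitting on the 37 training samples, so the
held-out sample never influences its own prediction — a contract
enforced by a test that corrupts the held-out response and checks the
fold is unchanged.

Metrics: Spearman ρ with its two-sided p, RMSE in weeks, and AUROC for
delivery within 24 h (= 24/168 weeks exactly), 1 week, and 2 weeks,
scoring risk as the negative predicted time-to-delivery and using the
midrank Mann–Whitney formula (equal to exhaustive pair counting; a
horizon with one class is reported missing, and constant predictions
give 0.5).

Stability across the 38 fold selections is the mean pairwise Jaccard
similarity and mean pairwise Cohen's kappa of inclusion vectors over all
genes entering selection (the kappa universe is switchable to the union
of selections).  The consensus list tests each gene's selection count
one-sided against Binomial(n_folds, p₀) with p₀ = mean fold set size /
universe size, Bonferroni-corrected at α = 0.05 — a deliberately
conservative reading of frequency-based "self-consistent" selection,
since the correction under LOOCV's strongly dependent folds is not
canonical; the genes selected in every fold are reported separately.

On the default planted cohort (seed 1) the full LOOCV yields Spearman
ρ ≈ 0.93, RMSE ≈ 1.3 weeks against a response sd of 3.3, AUROC 1.0 at
24 h, mean Jaccard ≈ 0.57 and kappa ≈ 0.72 — a cleaner signal than any
real cohort, which is why the tests assert only directional properties
(positive ρ, above-chance AUROC, RMSE below the response sd).  On null
cohorts (no expression signal) the mean 24 h AUROC over repeated runs
sits near chance (observed ≈ 0.42 over 20 seeds at reduced scale,
inside the (0.35, 0.65) calibration band; slight pessimism of
mean-reverting LOOCV predictors is expected).

## Clinical table statistics

Continuous variables: median and type-7 (linearly interpolated)
quartiles per group, compared by Welch's t with Welch–Satterthwaite df.
Categorical variables: count/denominator (%) with non-missing
denominators, compared by the two-sided Fisher's exact test defined as
the sum of same-margin table probabilities not exceeding the observed
one (within 1e-7 relative tolerance for float ties) — the convention
required to reproduce published clinical-table p-values, which the
package does exactly at 3-decimal rounding from the printed counts.

## Problem sizes and determinism

Default analyses run at the study scale (2000 genes × 38 samples;
5000 genes for hyperparameter recovery; 10–20 seeds for power and
calibration summaries; null-calibration runs use 250-gene cohorts with
100-tree forests).  Every stochastic step is driven by an explicit seed:
generators use `numpy.random.default_rng(seed)` with fixed draw order,
fold forests use `seed + fold`, and identical configurations are
byte-identical on disk.

## Known limitations

- The moderation stage assumes a shared residual df across genes (one
  common design); per-gene missingness is out of scope.
- The HSIC-lasso solver materializes the per-gene Gram stack
  (O(genes · n²) memory) and the gene-gene Gram inner-product matrix
  (O(genes²)); comfortable at array scale on one CPU, not tuned for
  n ≫ 100 samples.
- Signature definitions take the atlas at face value; no cross-platform
  normalization between atlas and cohort is attempted beyond reference
  standardization.
- The consensus binomial null treats folds as independent, which LOOCV
  violates; the Bonferroni correction partly offsets this, and the
  always-selected list is the conservative companion readout.
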