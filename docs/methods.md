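# Methods

## Data model and normalization

Input is an isoform × sample matrix of (possibly fractional) counts with a
gene ↔ isoform mapping and a two-condition design with at least two samples
per condition.  Normalization is plain counts-per-million on raw library
sizes followed by log₂(cpm + 0.5); no TMM or upper-quartile scaling is
applied, so the expression shift β is interpreted on the cpm scale.
Fractional expected counts (e.g. RSEM) are used as-is.  The default
low-count filter keeps isoforms with a count of at least 1 in **every**
sample; genes reduced to a single isoform remain in the analysis for
expression only, since a splicing perturbation is undefined for T = 1.

## Mean–variance trend

A two-group-means linear model (intercept + condition indicator) is fit to
every row of the log-cpm matrix; the LOWESS curve (span 0.5, 3 robustifying
iterations) of √(residual sd) against the row's mean log-cpm is the trend.
Rows contribute one point each, pooled across conditions.  Per-observation
variances are the 4th power of the curve evaluated at the observation's
fitted value, which under the two-group model is the row's condition mean;
evaluation outside the fitted support clamps to the boundary.  Gene-level
and isoform-level matrices get independent trends.  Smoothed curve values
are floored at 10⁻⁶ so read-back variances stay positive.

## Hierarchical model

Per gene: β ~ N(0, 5); β₀ ~ N(μ₁, 5) with μ₁ the observed control mean of
the gene's log₂-cpm; gene observations N(β₀ (+β), σ̂²) with gene-trend
variances; p, α ~ Dirichlet(1); isoform observations
N(β₀ (+β) + log₂ p(′)ᵢ, σ̂²) with isoform-trend variances, where
p′ = Aitchison-perturbation(p, α).  The prior scale 5 is on the log₂-cpm
scale.  The isoform-mean linkage log₂(pᵢ · 2^gene-mean) = gene-mean + log₂ pᵢ
was the open design point; it makes the gene mean the log of the summed mean
isoform levels (Σᵢ pᵢ 2^β₀ = 2^β₀) and keeps the likelihood log-linear in
(β₀, β).

Genes are conditionally independent given the two trends, so the joint model
factorizes and is fitted gene-wise; the result is distribution-equivalent to
one joint fit.

## Sampler

The sampler is written in-package and alternates:

1. **Exact Gibbs for (β₀, β).** Conditional on (p, α) every observation mean
   is linear in (β₀, β) with known variance, so the full conditional is
   bivariate normal and is drawn exactly (2×2 Cholesky), vectorized across
   genes.
2. **Adaptive random-walk Metropolis for p and α** in additive-log-ratio
   coordinates (T−1 free logits per block, last entry as reference; the
   change-of-variables adds Σ log fractions to the log density, and the
   Dirichlet(1) prior is flat on the simplex).  Per-gene scalar proposal
   scales adapt every 25 warmup iterations toward acceptance 0.28 and are
   frozen afterwards, so retained draws come from a fixed kernel.  Because
   random-walk mixing degrades with dimension, each Gibbs sweep performs
   3 + (T − 2) Metropolis sub-steps per block.

Genes sharing an isoform count are updated as one vectorized batch, which
keeps a 1000-gene dataset at 2500 iterations in the tens of seconds on one
core.  All randomness flows from a single integer seed
(`numpy.random.SeedSequence`); identical seeds give identical draws.
Defaults are 1 chain, 2000 warmup, 10000 total steps; benchmark-scale runs
in the tests use 500/2500 to keep the suite fast, and full-length chains
(2000/10000) where calibration is asserted.  An ensemble MCMC (emcee) on the
same per-gene density is the independent cross-check in the test suite.

## Posterior summaries and classification

- P(DE): fraction of β draws sharing the sign of the posterior mean; draws
  within 10⁻¹² of zero count to neither side (the exact null point, up to
  floating-point rounding), and a mean of exactly zero reports 0.5.
- P(DS), gene level: per isoform, the larger of the fractions of αᵢ draws
  above and below 1/T; the gene reports the maximum over isoforms.
- P(DS), isoform level: the reference becomes the draw-wise dot product
  α·p, which equals 1/T exactly when α is uniform.
- Fold changes: expression, the posterior mean of β (log₂ scale); splicing,
  perturb(mean p, mean α)ᵢ / (mean p)ᵢ with both mean vectors renormalized
  onto the simplex first (means of simplex draws sum to 1 only up to
  rounding).
- Categories: DGE / DAST / DAST-DGE / static by comparing P(DE) and P(DS)
  to thresholds (defaults 0.99 gene level, 0.999 isoform level).  Across
  many sub-cohort comparisons, a gene counts as DE/DS in a comparison when
  called in ≥ 3 sub-cohorts; final groups use the "at least twice as many
  comparisons" dominance rule, with ties at exactly twice going to the
  dominant label.  Whether mixed calls must co-occur within one comparison
  is ambiguous; per-gene totals across comparisons are used.

## Convergence diagnostic

Geweke z-scores compare the first 10% and last 50% of each single-chain
series, standardized by spectral-density standard errors at frequency zero.
S(0) is estimated by a Yule-Walker AR fit solved with the Levinson-Durbin
recursion, order chosen by AIC up to min(50, n/10) — the same construction
as coda's `spectrum0.ar`.  Constant segments yield NaN with a warning.  The
reported summary is the fraction of parameters significant after
Benjamini-Hochberg correction at 0.05; on a converged full run of a complete
simulated dataset this fraction is 0.

## Simulator

The generator extends a voom-style expression simulation to isoforms.  Study
conditions (defaults): 1000 genes, 5 samples per condition, base library
2×10⁶ (equal mode; unequal mode draws uniformly from [base/3, 3·base]), 10%
DE and 10% DS genes, disjoint sets.  Isoform counts per gene are 2–10 with
probabilities (0.4, 0.2, 0.1, 0.05 ×6); a gene's expected proportion is
split evenly across its isoforms.  DE doubles the whole gene in one random
condition; DS doubles one random isoform in cases and a different one in
controls, which leaves the gene's expected total exactly unchanged
(pre-renormalization proportions are kept in the truth table so this is
testable exactly).  Counts are negative binomial with genewise dispersion
φ = 0.1 + 1/Gamma(shape 10, scale 25), i.e. typical φ ≈ 0.104 and a
biological CV near 0.32, typical of bulk RNA-seq; φ → 0 falls back to
Poisson.  Gene abundances are normalized log-normal(0, 1.5) draws.

What the generator does *not* emulate: positional/length biases, correlated
isoform quantification errors (each isoform is an independent NB draw),
batch effects, outlier samples, and the long low-count tail of annotation-
wide quantification.  Passing benchmarks here therefore demonstrate correct
behaviour under clean count noise, not robustness to quantifier artefacts.

## Evaluation

Splicing truth positives are isoforms of DS genes whose within-gene fraction
changes at least 2-fold in either direction.  PR curves for probability
scores sweep a fixed grid on [0, 1] (step 10⁻⁴); the area integrates the
best achievable precision at each distinct recall (score ties — many genes
at probability exactly 1.0 — make recall levels multivalued), anchored flat
to recall 0.  OSTP converts counts to "proportion of the other isoforms",
takes a Welch t-statistic per isoform (the pooled/Welch choice is not pinned
down; Welch is safer under unequal libraries), and for each false-positive
count picks the |t| cutoff maximizing true positives — an oracle upper
bound usable only on simulation.  Mean curves LOWESS-smooth precision over
recall per dataset, impute missing precision by carrying the nearest lower
recall value, and average pointwise.  The expression reference detector is
a per-gene Welch t-test on gene-level log-cpm scored as 1 − p.

## Known limitations

- **Information double-counting.** The model observes both the gene-level
  log-cpm and the isoform-level log-cpm, but the gene value is the log of
  the summed isoform counts — a deterministic function of the same data.
  Treating the blocks as independent roughly doubles the Fisher information
  on β, so the β posterior sd is ~√2 too small.  Consequences: 99% credible
  intervals for null genes cover zero slightly less often than nominal, and
  with short chains a few percent of null genes place *all* draws on one
  side of zero, tying with true positives at probability exactly 1.0 and
  capping the precision of expression calls.  Splicing calls are less
  affected because α only enters the isoform block.  Longer chains reduce
  the saturation; the structure itself is part of the model.
- Posterior probabilities are reported raw; no FDR calibration is applied.
- Only two-condition designs; no covariates, no multi-group contrasts.
- The trend assigns one variance per (row, condition); gene-specific
  dispersion beyond the trend is not modelled (no empirical-Bayes
  moderation of residual variances).
- Desk-scale problem sizes in the test suite (1000-gene datasets, 5 seeds,
  200-gene full-model convergence runs, 500/2500 benchmark chains and
  2000/10000 calibration chains) were chosen to keep the suite fast while
  leaving every property measurable; paper-scale settings are plain config
  values (`n_genes`, `warmup`, `steps`).
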