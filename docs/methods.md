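# Methods

This note documents the statistical machinery of `methclock`: the models
each stage assumes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A cohort is a samples x CpG-sites matrix of methylated/unmethylated read
counts.  Positions are 0-based internally; bismark-style coverage files
are treated as 1-based and shifted once at the read boundary.  Chromosome
labels are normalized by stripping a leading `chr`.  The percentage column
of coverage files is advisory only (validated within 0.5 percentage
points); counts are authoritative, and multiple runs of one sample are
collapsed by summing reads.  A cell is *missing* iff its total depth is
zero; otherwise its fraction equals meth/(meth+unmeth) exactly.

Months are days / 30.4375 (= 365.25/12) everywhere.

## Synthetic cohorts

`simulate_cohort` draws, per site, a baseline fraction and (for the
age-drifting subset) a slope on the log2(age in days) axis: gain sites
start low (baseline U(0.05, 0.25), slope +`slope_scale` jittered by
U(0.75, 1.25)), loss sites mirror them.  The latent per-cell value is

    clamp(baseline + slope * log2(effective_age), 0, 1) + shift_batch + scale_batch * N(0, noise_sd)

followed by read sampling: depth ~ Poisson(`mean_depth`), methylated reads
~ Binomial(depth, clamp(latent, 0, 1)); cells hit by `missing_rate` or
drawn at depth 0 are missing.  Treatment acts multiplicatively on the age
axis (`effective_age = treatment_rate * age`), matching the observation
that clock slowing scales with age rather than subtracting a constant.
`entropy_drift > 0` contracts latent fractions toward 0.5 by
exp(−drift · log2(age)), producing rising per-sample disorder.  Everything
is a deterministic function of the seed.

Defaults (100 samples, 500 sites, 100 age sites, slope 0.04 per log2-day,
noise sd 0.02, depth 20, 5 % dropout) describe a mid-sized pooled
RRBS/WGBS liver study; ages default to a log-uniform draw over ~0.2–26
months.  Deliberately **not** emulated: sequence context, spatial
correlation between neighboring CpGs, bisulfite-conversion error,
cell-type composition shifts with age, and nonlinear (developmental-phase)
methylation trajectories.  Passing tests therefore demonstrate that the
pipeline recovers the signal it assumes — log-linear drift plus
location/scale batch structure — not that real livers obey that model.

The orthologous-pair generator plants a forced overlap
`round(shared_fraction * min(n_age_a, n_age_b))` between two cohorts'
age-site sets over a common site universe, with the remainder of B's sites
drawn from all non-forced sites (so `shared_fraction = 0` reproduces the
hypergeometric chance-overlap distribution).  It also emits the
coordinate-mapping table and probe manifest used to exercise the
ortholog-space construction.

## Filtering profiles

Three profiles, all ending in site-mean imputation computed after sample
removal (the mean over the profile's observed cells, so imputation never
moves a site's observed mean):

| profile | observed cell | site rules | sample rule |
|---|---|---|---|
| cross-species | ≥ 5 reads | missing < 20 % across all pooled samples; unique mapping on chromosomes 1–19 | missing > 40 % of kept sites |
| clock | ≥ 2 reads | present in ≥ 97 % of samples; chromosomes 1–19; sd of observed fractions > 0 and ≤ 0.20 | missing > 30 % of kept sites |
| relaxed | ≥ 1 read | restricted to the clock's site set | — |

Choices where the rules underdetermine behavior: the 97 % presence rule is
inclusive (≥ 0.97); standard deviation uses the n−1 denominator on
pre-imputation fractions; "distinct mapping" is enforced as coordinate
uniqueness, duplicates removed entirely; the presence/removal rules run
once in the stated order (site rules, sample rule, imputation), not
iterated — re-running a profile on its own output is the identity.  The
sd ceiling exists because array-free bisulfite data is noisy at extreme
fractions; note it also removes genuinely large-amplitude age effects, so
the clock works within the ≤ 0.20-sd stratum.  Thresholds are overridable
via `FilterProfile` (YAML-loadable for the CLI).

## Age association and entropy

Each site's fraction is regressed on the configured covariates
(categoricals one-hot against the lexically first level) plus a continuous
age term; the drop-one F-test compares the full model against the model
without age: F = (RSS_r − RSS_f) / (RSS_f / (n − p)) on (1, n − p) degrees
of freedom.  The F statistic is invariant to affine age transforms, so
days vs log2(days) only changes the reported coefficient.
Benjamini–Hochberg q-values use the step-up rule with monotonicity
enforcement; replication applies BH *within* the primary-significant
subset (matching a candidate-restricted re-test) rather than genome-wide —
the anti-conservative alternative is one flag away for sensitivity
analysis.

Entropy per sample over N sites is
(1/(N log ½)) Σ [MF log MF + (1−MF) log(1−MF)]: 1 when all fractions are
0.5, 0 when all are 0 or 1.  Terms at exactly 0 *or* 1 contribute zero
(the limit is identical on both sides); the normalizer cancels the
logarithm base.  Its correlation with age is reported against age in
months (untransformed), the axis disorder is usually plotted on, while the
clock operates on log2(days).

## Batch correction

The ComBat algorithm: per site, fit batch indicators plus covariates (age
as log2 days, sex, treatment) by least squares; standardize by the
weighted grand mean, the covariate fit, and the pooled residual variance;
estimate per-batch location (γ) and scale (δ) on the standardized data;
shrink across sites by empirical Bayes; adjust and restore the covariate
signal.  Two priors: **parametric** (normal/inverse-gamma with the usual
fixed-point iteration) and **nonparametric** (default), where each site's
posterior is the likelihood-weighted average of all *other* sites'
(γ̂, δ̂) atoms — an exact sum over the empirical prior, hence
deterministic.  δ̂ uses the population (1/n) variance around the batch
mean so that a fit on batch-free data adjusts to the identity exactly;
the difference from the n−1 convention is O(1/n) and shrinks further
under EB.  Adjusted values may leave [0, 1] and are *not* clamped before
clock training (clamping would bias the linear model); clamp only in
exported per-site reports.  Singleton batches and covariates confounded
with batch are hard errors.  The default is a joint fit over all samples;
`apply_batch_model` supports frozen-apply to new samples of known batches.

The diagnostic reports the R² of the top two principal-component scores on
the batch factor before vs after adjustment.

## The clock

Elastic net on log2(age in days), features = adjusted fractions.  The λ
path is auto-scaled from the data (log-spaced from the smallest λ that
zeroes all weights down by 10³), ρ defaults to
{0.1, 0.3, 0.5, 0.7, 0.9, 1.0}; folds are a seeded shuffle split into
contiguous blocks, unstratified.  Model selection maximizes the mean
held-out Pearson r (the metric the clock is judged by); mean squared error
is available via `criterion="mse"` and yields slightly better calibrated
(less shrunk) predictions at the same ranking accuracy.  The winner is
refit on all training data.  Because r is scale-free, predictions carry
the usual ridge/lasso shrinkage toward the training mean — treatment
reductions estimated from predicted ages are therefore mildly attenuated
relative to the planted effect (recovered within ~10–25 % on the default
cohorts).

Per-site direction (gain/loss with age) is the sign of the Pearson
correlation with log2(age) over training samples; exact zeros are reported
"flat" and excluded from gain/loss counts.  Region enrichment of clock
sites uses one Fisher 2x2 per region over a single-label assignment with
precedence enhancer > promoter > exon > intron > intergenic.

The permutation control shuffles the covariate rows (age, sex, treatment)
within each study, refits the batch model, retrains the clock, and records
the mean |residual| of the designated evaluation samples against their
*true* ages; the real pipeline should rank first when a genuine age signal
exists.

## Cross-species mapping

LiftOver is consumed as a precomputed two-column coordinate table; lifted
sites intersect probe coordinates exactly (a configurable slop, default 0,
covers manifest conventions that use probe intervals).  Mouse sites
sharing a probe are collapsed by the unweighted mean of nonmissing
fractions (missing only if all members are missing).  Region enrichment is
marginal — one 2x2 per region, in-region vs not for that region alone, so
multi-label sites are counted once per test; the Fisher test is two-sided
since both under- and over-representation are of interest.  Overlap
significance is the upper-tail hypergeometric probability P(X ≥ k).

## Longevity evaluation

Reductions are mean(control epigenetic age) − mean(treated), in months,
within (age group, strain); the default test is Student's equal-variance
two-sided t (Welch via `equal_var=False`), with a one-way ANOVA across the
old-age groups (strain can be added as a covariate option).  PCA is
centered, unscaled SVD with PC1 sign fixed to correlate positively with
age; PC1 is regressed on age + treatment per genetic background.
Hierarchical clustering uses average linkage on Euclidean distances after
per-site min-max scaling to [0, 1] (the convention of the common heatmap
tools; z-scoring available), with the top-k-variance site ranking (n−1
denominator) computed over a designated sample set; zero-range sites are
dropped with a warning, and ties follow scipy's deterministic
lowest-index-first merge order.

## Numerical choices and degenerate inputs

RSS via thin-QR projection (no explicit normal equations in the pipeline
path); pooled variances floored at 1e-12; elastic-net coordinate descent
at tol 1e-4 / max_iter 10000, with λ = 0 delegated to an SVD least-squares
solver; Fisher tables with a zero margin report an undefined odds ratio
and p = 1; constant held-out predictions score Pearson r = 0 during model
selection.  Empty site sets, all-removed filters, singleton batches,
rank-deficient designs and unseen batch labels raise informative errors.

## Problem sizes used by tests and the acceptance script

Unit and end-to-end checks run on cohorts of 40–140 samples and 50–500
sites (100-seed replication for batch/slope preservation, 20 seeds for
clock accuracy and treatment slowing, 20 permutations for the shuffle
control, 200–500 replicates for FDR calibration); these sizes give the
relevant statistics comfortable sampling error at desk scale while the
algorithms themselves are dimension-agnostic.

## Known limitations

* The generator's log-linear drift makes the elastic net well-specified;
  accuracy numbers on synthetic cohorts are upper bounds on real-data
  performance.
* Site-mean imputation shrinks between-sample variance at poorly covered
  sites; no model-based imputation is provided.
* The nonparametric EB integration is O(sites² x samples) per batch —
  fine to a few thousand sites, quadratic beyond.
* Beta-regression, mixed models, cell-type deconvolution and nonlinear
  age transforms are out of scope.
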