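# methclock

A tested, reusable pipeline for building and evaluating a **mouse liver
epigenetic clock** from bisulfite-sequencing DNA-methylation data, and for
asking whether lifespan-extending interventions (dwarfism, calorie
restriction, rapamycin) *slow* that clock.

## Who this is for

Epigenomics researchers working with per-CpG methylation call tables
(bismark-style coverage files from RRBS or WGBS) and sample metadata (age,
sex, strain, treatment, sequencing study).  The package provides every
analysis stage as a library function with a thin `methclock` CLI on top,
plus a synthetic-cohort generator with known ground truth so every stage
can be validated before touching real data.

## The model

Each CpG site *j* in sample *i* carries a methylation fraction
`x_ij = meth_ij / (meth_ij + unmeth_ij) ∈ [0, 1]`.  The clock is a
penalized linear regression of log-age on those fractions:

```
min_{b,w}  (1/2n) Σ_i (log2(age_i) − b − Σ_j w_j x_ij)²
           + λ [ ρ‖w‖₁ + (1−ρ)/2 ‖w‖₂² ]
```

with age in days, λ/ρ chosen by 4-fold cross-validation (scored by mean
held-out Pearson r), and the epigenetic age of a new sample given by
`2^(b + Σ w_j x_j)`.  The residual (epigenetic − chronological age, in
months) is the readout for treatment effects: a treatment that slows the
clock multiplicatively (effective age = rate · age) shows up as a negative
mean residual relative to age-matched controls.

Around the clock sit the supporting stages:

* **Filtering profiles** — read-depth / missingness / variability rules for
  pooled cross-study matrices, for clock training, and a relaxed projection
  for single-time-point cohorts, each ending in site-mean imputation.
* **Batch correction** — empirical-Bayes location/scale adjustment (the
  ComBat algorithm, parametric and nonparametric priors) preserving the
  age, sex and treatment covariates.
* **Age association** — per-site drop-one F-tests with Benjamini–Hochberg
  FDR control, cross-cohort replication, and the methylome **entropy**
  statistic `(1/(N log ½)) Σ_i [MF_i log MF_i + (1−MF_i) log(1−MF_i)]`
  that quantifies rising disorder with age.
* **Cross-species comparison** — mapping mouse CpGs through a precomputed
  liftOver table onto array probes, region enrichment by Fisher's exact
  test, and hypergeometric overlap testing.
* **Longevity evaluation** — t-tests/ANOVA of treated vs matched controls,
  PCA of the clock's sites, and average-linkage hierarchical clustering.

## Worked example

Simulate a 140-mouse cohort (500 CpGs, 100 of them drifting with log-age),
train on 100 and predict the held-out 40:

```python
import numpy as np
from scipy import stats
import methclock as mc
from methclock.filters import impute_site_mean

spec = mc.CohortSpec(n_samples=140, n_sites=500, n_age_sites=100,
                     slope_scale=0.04, mean_depth=20, seed=1)
matrix, meta, truth = mc.simulate_cohort(spec)
frac = impute_site_mean(matrix)[0].fraction

train, test = list(frac.index[:100]), list(frac.index[100:])
model, report = mc.train_clock(frac.loc[train], meta, seed=1,
                               n_alphas=20, l1_ratios=(0.5, 1.0))
pred = mc.predict_age(model, frac.loc[test], meta)
```

which prints (via `report` and `pred`):

```
selected sites : 83
per-fold CV r  : 0.992, 0.985, 0.989, 0.971 (mean 0.984)
held-out r     : 0.991
mean |error|   : 2.00 months
```

`model.weights` holds the selected CpGs with weights in log2(days) per
methylation-fraction unit; `pred.table` has one row per sample with
epigenetic age in days and months and the residual in months.  A held-out
correlation near 0.99 and a ~2-month error say the clock recovered the
planted log-linear drift almost perfectly under 20x coverage — real data,
with its unmodeled biology, will sit well below that ceiling.

The same flow is available from the shell:

```
methclock filter  --profile clock --coverage-dir cov/ --metadata meta.tsv --out filtered.tsv
methclock combat  --matrix filtered.tsv --metadata meta.tsv --out adjusted.tsv
methclock train   --matrix adjusted.tsv --metadata meta.tsv --out model.tsv
methclock predict --model model.tsv --matrix adjusted.tsv --metadata meta.tsv --out pred.tsv
```

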