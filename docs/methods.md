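# Methods

## Model and procedure

The outcome is right-censored age of onset: time `t_i ≥ 0`, event indicator
`δ_i ∈ {0,1}` (cases contribute events at diagnosis age, controls are
censored at interview age), optional covariates `x_i` (e.g. smoking).
Genotypes are additive minor-allele dosages in {0, 1, 2} with a missing
sentinel.

1. **Null fit.** A Cox proportional-hazards model with covariates only (no
   genetic terms) is fit by Newton–Raphson on the Breslow partial
   likelihood. With no covariates the baseline cumulative hazard is the
   Nelson–Aalen estimator.
2. **Surrogate outcome.** Martingale residuals
   `M_i = δ_i − Λ̂₀(t_i)·exp(β̂ᵀx_i)` replace (t, δ). Each residual is ≤ 1
   and the sum over the fitting sample is 0 up to solver tolerance.
3. **Cell labeling.** For a k-tuple of SNPs, subjects map to one of 3^k
   cells (row-major, first SNP most significant; subjects missing any of
   the k genotypes are excluded for that model only). A cell is high-risk
   when its residual sum is ≥ 0 (ties to high, extending the subject-level
   ≥ 0 rule), low-risk when negative, empty when unpopulated. At test time
   a cell that was empty in training is treated as low-risk (conservative).
4. **Scoring.** High cells are pooled against low cells and scored with a
   pooled-variance two-sample t statistic on the residuals (high minus
   low); Welch is available as an option. A model with one empty pool
   scores 0.
5. **Cross-validated search.** Subjects are split into seeded disjoint
   folds (default 2, unstratified). Per fold, labels are learned on the
   training portion; the t statistic on the training portion is the train
   score and, using the trained labels, on the held-out portion the test
   score. Exhaustive enumeration over all C(m, k) models is vectorized as
   per-(model, cell) moment accumulations and is chunkable by model index
   with bit-identical results.

**Why residuals.** For any subject group G, with residuals from the
covariate-free null fit, `Σ_{i∈G} M_i = O_G − E_G`, the log-rank
observed-minus-expected numerator for G vs the rest (exact under
Breslow/Nelson–Aalen tie handling — the test suite checks it to 1e-8 on
10,000 random groupings). Cell labeling by residual sums therefore
partitions genotype cells identically to the log-rank rule of the log-rank
MDR baseline, while costing one pass of additions instead of a risk-set
computation per cell, and generalizing to covariate-adjusted residuals.

## Selection and reporting

Per fold the winning model maximizes the **training** score.
Cross-validation consistency (CVC) is the number of folds a model wins.
The champion per k is the highest-CVC winner, ties broken by the
winning-fold training score. The reported test score of a fold winner is
the mean of its held-out scores **over the folds it won**; models that won
no fold report their mean test score over all folds (descriptive only).
Across k, the overall best model is the champion with the largest CVC,
ties broken by reported test score.

This selection discipline is deliberate. With two folds, each fold's test
set is the other fold's training set; any rule that consults test scores
during selection (or averages a chosen model's test scores over all folds)
contaminates the reported score with the data it is evaluated on. Measured
on null data, such leaky variants inflate the exceedance of the 1.645
threshold to 10–19 %. The rule above keeps every selection decision on
training data, so the reported null score is close to standard normal
(Kolmogorov–Smirnov distance < 0.05 at 1000 replicates, m=20, n=400 — the
suite's null-calibration tests compute this), making the fixed
standard-normal 95th-quantile threshold usable. The procedure is mildly
conservative (measured type-I error ≈ 3.5–6 % across sample sizes for all
k), and in particular the three-way search shows no excess type-I error
under this implementation.

Significance options: the standard-normal 95 % quantile 1.6449 (default for
residual scores), the χ²(1) 95 % quantile 3.8415 (log-rank baseline, whose
scores are squared statistics), or an empirical 95th percentile
(type-7/linear interpolation) of user-supplied null scores. The
permutation test permutes residuals across subjects, keeps the fold split
fixed, and recomputes the model's mean held-out score; p uses the add-one
estimator (1 + #{perm ≥ obs}) / (1 + n_perm).

## Simulation generators

**Null study.** m SNPs with MAF ~ U(0.1, 0.5), genotypes Binomial(2, MAF),
outcomes i.i.d. N(0, 1) drawn independently of the genotypes and consumed
directly as the continuous surrogate. Type-I error is the fraction of
replicates whose chosen model's reported score exceeds the threshold.

**Epistatic study.** A 3×3 penetrance table f (P(high-risk | g1, g2)) is
drawn by projecting random Gaussian tables onto the subspace with equal
marginal penetrance under Hardy–Weinberg weights (purely epistatic: no
main effects, both margins identically K) and rescaling to the target
broad-sense heritability h² = Σ p_i q_j (f_ij − K)² / (K(1−K)) exactly;
where the rescaled table leaves [0, 1] a clip/re-project/re-scale loop
walks it to a boundary-feasible table. Prevalence defaults to **K = 1/3**,
which balances the f ≥ 0 floor against the f ≤ 1 ceiling and makes the
whole grid h² ≤ 0.4 × MAF ∈ {0.2, 0.4} attainable (at K = 0.25 the
MAF 0.2 / h² 0.4 corner is infeasible).

Cohorts are balanced by rejection sampling: n/2 high-risk and n/2 low-risk
subjects, risk ~ Bernoulli(f_{g1,g2}) with genotypes under HWE. Event
times follow a Cox–Weibull model: baseline Weibull with shape a = 5 and
scale s = 2, hazard multiplied by exp(β·risk); censoring times are
U(0, u = 4); observed time = min(T, C), status = 1{T ≤ C}; 18 independent
noise SNPs (MAF ~ U(0.1, 0.5)) are appended.

**Effect-size calibration.** β is not a free dial: the generator's target
is 40 % overall censoring, and with balanced risk groups the censoring
fraction is E[min(T, u)]/u ≈ s·Γ(1 + 1/a)·(1 + e^(−β/a)) / (2u), giving

    β = −a · log( 2·0.40·u / (s·Γ(1 + 1/a)) − 1 ) ≈ 1.489

at the defaults (hazard ratio ≈ 4.4). The generator reproduces 40 % ± 0.5 %
censoring over 10,000 subjects (a test computes this). β = 0 would give
≈ 46 %, so the censoring target pins the scale of the effect.

**Power.** Per (MAF, h², n) cell, several penetrance tables (default 5)
are cycled across replicates. Stringent power counts a replicate as a
success when the overall best model is exactly the functional pair and its
score clears the threshold; flexible power also accepts a 3-way superset
containing the pair. The consistency-first cross-k rule matters here: with
score-only selection, 3-way supersets of the true pair (which split their
fold wins across 18 candidates) steal a noticeable share of stringent wins
from the exact pair (which wins both folds).

**What the generators do not emulate.** Independent markers only (no LD
except what the pruner tests construct), HWE, no population structure, no
genotyping error, noninformative uniform censoring, proportional hazards
exactly true. Passing tests therefore demonstrate calibration and power of
the algorithm under its stated model, not robustness to real-data
violations of it.

## Prediction pipeline

Greedy LD pruning in map order drops any SNP whose squared Pearson
correlation with a retained SNP (within a trailing window) exceeds r²_max
(default 0.1, mean-imputing missing calls for the correlation only).
Subjects are split 2/3 train / 1/3 test (seeded). The null model is fit on
the training set; exhaustive 1-/2-way searches run on training residuals;
the SNPs appearing in the top models of each order are pooled. The Lasso
Cox design contains the pooled dosages plus the high-risk indicator
attribute of the top two-way MDR models — an additive dosage column cannot
represent a purely epistatic pair (its marginal effect is zero by
construction), whereas the MDR attribute is exactly the one-dimensional
variable built for it. Covariates enter with penalty factor 0 (never
shrunk). The penalty path is fit by coordinate descent
(scikit-survival); the penalty is chosen by k-fold cross-validated
held-out Breslow partial log-likelihood computed by this package's own
survival module. Selected SNPs are those appearing in any nonzero feature.

Risk scores on the held-out third are the penalized linear predictor.
Time-dependent ROC uses the cumulative-cases / dynamic-controls
definition — sensitivity(c, t) = Pr{f(X) > c | event by t},
specificity(c, t) = Pr{f(X) ≤ c | event-free at t} — estimated by
Kaplan–Meier within score strata (no nearest-neighbor smoothing), swept
over all observed cutoffs; AUC(t) by trapezoid after lexicographic
(fpr, tpr) ordering. AUC(t) is invariant to strictly monotone transforms
of the score and is undefined (flagged) at horizons with no events or no
survivors. KM risk stratification labels held-out subjects with the
trained model and reports covariate-adjusted Cox hazard ratios with Wald
95 % intervals.

## Numerical choices

* Breslow tie handling throughout (matches the Breslow baseline); Λ̂₀ is a
  right-continuous step function, carried flat beyond the last event time
  and 0 before the first.
* Newton–Raphson: tolerance 1e-9 on the partial log-likelihood, max 100
  iterations, step-halving line search, error on non-convergence or
  singular information.
* Cell-sum tie at exactly 0 → high-risk; empty-in-training cell at test
  time → low-risk.
* Empirical quantiles use linear (type-7) interpolation.
* The exhaustive scan accumulates per-(model, cell) count/sum/sum-of-
  squares with a numba kernel when numba is importable; the numpy bincount
  fallback is bit-identical. Chunking over models never changes results.
* Seeded `numpy.random.default_rng` everywhere; fold assignment is a
  seeded permutation taken modulo the fold count.

## Problem sizes used by the test and acceptance runs

Null calibration: m=20, n ∈ {200, 400, 800, 1600, 3200}, 1000 replicates
per n. Power: MAF 0.4, n=1600, h² ∈ {0.05, 0.2, 0.4}, 100 replicates per
cell, 5 penetrance tables. Censoring calibration: 10,000 subjects.
Pipeline recovery: m=200 SNPs, n=2000 subjects, 20 seeded runs. These
sizes are the package's chosen desk-scale study conditions; the generators
and engine scale to larger panels by chunking.

## Limitations

* The residual surrogate discards the variance structure of the log-rank
  statistic (variance is effectively set to one); a weighted-residual
  refinement could recover power for model selection.
* Two-fold cross-validation trades variance for unbiased held-out scoring;
  the reported score of a fold winner rests on a single half-sample unless
  it wins both folds.
* The log-rank baseline supports no covariate adjustment and no missing
  genotypes in its vectorized search path.
* k is limited to small orders (the interface targets k ≤ 3); the
  penalized-Cox stage assumes the pooled feature set fits in memory.
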