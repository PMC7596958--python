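# esmdr — efficient survival multifactor dimensionality reduction

Detecting gene–gene interactions (epistasis) that shift the **age of disease
onset** is a combinatorial problem: an exhaustive two-way scan over even a
pruned GWAS panel means millions of models, and the natural outcome —
censored time-to-event data — makes each model expensive to score with a
log-rank test and impossible to adjust for confounders such as smoking.

`esmdr` implements a residual-based variant of multifactor dimensionality
reduction (MDR) for survival outcomes, aimed at statistical geneticists and
epidemiologists analyzing age-of-onset GWAS data. The censored outcome
(time *t*, event indicator δ) is replaced once, up front, by **martingale
residuals from a covariate-only Cox null fit**

    M_i = δ_i − Λ̂₀(t_i) · exp(β̂ᵀx_i)

where Λ̂₀ is the Breslow baseline cumulative hazard (Nelson–Aalen when there
are no covariates) and x are adjustment covariates. Each k-SNP genotype
combination (3^k cells) is labeled **high-risk** when the sum of residuals
in the cell is ≥ 0 and low-risk otherwise; pooling cells yields a
one-dimensional attribute scored with a two-sample *t* statistic under
two-fold cross-validation. The key identity (exact under Breslow/Nelson–
Aalen tie handling, no covariates):

    Σ_{i ∈ cell} M_i  =  O_cell − E_cell   (the log-rank numerator),

so the residual sums reproduce the log-rank-based classification of
Surv-MDR at a tiny fraction of the cost — residuals are computed once, cell
sums are additive and fully vectorizable — while additionally allowing
covariate adjustment, which a log-rank statistic cannot.

The package also ships, as first-class tested code:

* the **log-rank Surv-MDR baseline** (`esmdr.survmdr`) for power comparisons;
* **simulation studies**: null SNP/outcome generation and type-I error
  estimation; purely epistatic 3×3 penetrance tables (equal marginal
  penetrance, exact target heritability) with Cox–Weibull event times
  (shape 5, scale 2) and uniform censoring on (0, 4) calibrated to 40 %
  censoring; power estimation, stringent and flexible modes;
* the **prediction pipeline**: greedy LD pruning (r² ≤ 0.1), 2/3–1/3
  train/test split, exhaustive 1-/2-way search, top-model SNP pooling,
  Lasso Cox selection (covariates unpenalized), Kaplan–Meier risk
  stratification with adjusted hazard ratios, and Heagerty-style
  cumulative/dynamic time-dependent ROC/AUC;
* PLINK bed/bim/fam and tabular I/O plus a thin `esmdr` command-line tool
  (`simulate-null`, `simulate-epistasis`, `type1`, `power`, `search`,
  `predict`).

## Worked example

```bash
python examples/02_search_epistasis.py
```

prints (seeded):

```
1600 subjects, 962 events (40% censored); threshold 1.645
k=1: best noise5             consistency 1/2  test score +0.88
k=2: best SNP1+SNP2          consistency 2/2  test score +6.09*
k=3: best SNP1+SNP2+noise6   consistency 1/2  test score +3.53*

permutation p for the 2-way champion: 0.005
```

The two functional SNPs carry no marginal effects — the 1-way search sees
nothing (score +0.88, below the 1.645 significance threshold) — yet the
2-way search selects exactly `SNP1+SNP2` in both cross-validation folds
with a held-out score of +6.09, confirmed by a permutation test. The other
examples demonstrate the residual/log-rank identity, null calibration,
power against the log-rank baseline, and the full prediction pipeline
(planted-signal recovery, held-out AUC ≈ 0.70, adjusted hazard ratio ≈ 2.1
between MDR risk groups).

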