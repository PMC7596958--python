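"""Martingale residuals as a surrogate survival outcome.

Fits the covariate-only Cox null model on a small simulated cohort,
computes martingale residuals, and shows the identity that makes the
residual-based search equivalent to log-rank classification: the residual
sum over any subject group equals the group's log-rank observed-minus-
expected event count.
"""
import numpy as np

from esmdr.survival import (
    SurvivalData,
    fit_cox_null,
    logrank,
    martingale_residuals,
)

rng = np.random.default_rng(7)
n = 300
smoking = rng.integers(0, 2, n).astype(float)
T = rng.exponential(2.0 * np.exp(-0.6 * smoking))  # smokers have events earlier
C = rng.uniform(0, 4, n)
data = SurvivalData(np.minimum(T, C), (T <= C).astype(int), smoking[:, None])

fit = fit_cox_null(data)
resid = martingale_residuals(fit, data).values
print(f"smoking log-HR estimate: {fit.beta[0]:+.3f} (truth 0.6)")
print(f"residual range: [{resid.min():+.3f}, {resid.max():+.3f}]  (always <= 1)")
print(f"residual sum:   {resid.sum():+.2e}            (~0 on the fitting data)")

# The identity: with residuals from the covariate-FREE null fit, the sum
# over any subject group equals the group's log-rank O - E numerator.
plain = SurvivalData(data.time, data.status)  # same outcomes, no covariates
resid0 = martingale_residuals(fit_cox_null(plain), plain).values
group = rng.integers(0, 2, n).astype(bool)  # any grouping, e.g. a genotype cell
lr = logrank(plain, group)
print(f"\nresidual sum over group:  {resid0[group].sum():+.6f}")
print(f"log-rank O - E for group: {lr.observed - lr.expected:+.6f}")
print("-> identical: summing residuals per genotype cell reproduces the")
print("   log-rank classification at a fraction of the cost; with covariates")
print("   in the null fit the same sums become covariate-ADJUSTED O - E,")
print("   which is what the log-rank-based search cannot provide.")
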