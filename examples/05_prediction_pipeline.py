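"""End-to-end discovery + prediction on a synthetic age-of-onset cohort.

Plants one additive SNP and one purely epistatic pair among 200 markers in
2000 subjects (with a smoking covariate), then runs the whole chain:
LD pruning -> 2/3-1/3 split -> exhaustive 1-/2-way residual search ->
SNP pooling -> Lasso Cox selection -> held-out time-dependent AUC and
Kaplan-Meier risk stratification.
"""
import numpy as np

from esmdr.pipeline import run_pipeline, simulate_gwas

geno, data, truth = simulate_gwas(n=2000, m=200, seed=42)
names = geno.snp_ids
print(f"planted: main effect {names[truth['main']]}, "
      f"epistatic pair {names[truth['pair'][0]]}+{names[truth['pair'][1]]}")

res = run_pipeline(geno, data, seed=42, auc_grid=np.linspace(1.0, 2.5, 7))

print(f"\nSNPs after LD pruning: {len(res.kept)} of {geno.m}")
print(f"train/test sizes: {len(res.train_idx)}/{len(res.test_idx)}")
best2 = res.searches[2].chosen
print(f"best 2-way model: {'+'.join(best2.snp_names)} "
      f"(consistency {best2.cv_consistency}/2, test score {best2.test_score:+.2f})")
print(f"Lasso-selected features: {len(res.lasso.selected)} "
      f"-> SNPs involved: {res.selected_snps[:6]}{' ...' if len(res.selected_snps) > 6 else ''}")
planted = {names[truth["main"]], names[truth["pair"][0]], names[truth["pair"][1]]}
print(f"all planted SNPs recovered: {planted <= set(res.selected_snps)}")
print(f"\nheld-out AUC at the median event age: {res.auc:.3f} "
      "(0.5 = uninformative)")
print("AUC(t) sweep:", np.round(res.auc_sweep, 3))
if res.km is not None:
    lo, hi = res.km["hr_ci"]
    print(f"high- vs low-risk hazard ratio (smoking-adjusted): "
          f"{res.km['hr']:.2f} [{lo:.2f}, {hi:.2f}]")
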