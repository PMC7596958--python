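"""Applied analysis chain: prune -> search -> pool -> penalized Cox -> ROC.

Mirrors, at desk scale, the discovery pipeline used on age-of-onset GWAS
data: LD pruning to an approximately independent marker set, a 2/3–1/3
train/test split, exhaustive 1-/2-way residual-based MDR search on the
training set, pooling of the SNPs involved in the top-ranked models, Lasso
Cox selection of a parsimonious predictive set, Kaplan–Meier risk
stratification, and Heagerty-style cumulative/dynamic time-dependent
ROC/AUC on the held-out set.

The Lasso design contains the pooled SNP dosages plus the high-risk
indicator attribute of the top two-way MDR models: an additive dosage
column cannot represent a purely epistatic pair (its marginal effect is
zero by construction), while the MDR attribute is exactly the
one-dimensional variable the search built for it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .genotypes import GenotypeMatrix
from .mdr import MDRModel, SearchResult, assign_cells, cv_search, high_mask
from .sim import (
    CENSOR_UPPER,
    WEIBULL_SCALE,
    WEIBULL_SHAPE,
    calibrate_log_hr,
    make_penetrance,
)
from .survival import (
    SurvivalData,
    cox_partial_loglik,
    fit_cox,
    fit_cox_null,
    km_curve,
    km_eval,
    martingale_residuals,
)

__all__ = [
    "ld_prune",
    "split_train_test",
    "pool_top_snps",
    "lasso_cox_select",
    "td_roc",
    "td_auc_sweep",
    "km_risk_groups",
    "simulate_gwas",
    "run_pipeline",
    "PipelineResult",
]


def ld_prune(geno: GenotypeMatrix, r2_max: float = 0.1, window: int | None = 200):
    """Greedy LD pruning in map order.

    A SNP is dropped when its squared Pearson correlation with any retained
    SNP (within the trailing ``window`` retained SNPs; ``None`` = all)
    exceeds ``r2_max``.  Returns ``(pruned GenotypeMatrix, kept indices)``.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    g = geno.geno.astype(float)
    g[geno.geno < 0] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    kept: list[int] = []
    for j in range(geno.m):
        if sd[j] == 0:
            continue  # monomorphic, uninformative
        block = kept if window is None else kept[-window:]
        if block:
            B = g[:, block]
            r = (B * g[:, [j]]).mean(axis=0) / (sd[block] * sd[j])
            if np.any(r**2 > r2_max):
                continue
        kept.append(j)
    return geno.subset_snps(kept), np.asarray(kept, dtype=int)


def split_train_test(n: int, ratio: float = 2 / 3, seed: int = 0):
    """Seeded disjoint exhaustive partition into train/test index arrays."""
    if n < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def pool_top_snps(results: list[SearchResult], top_m: int = 1000) -> list[int]:
    """Union of SNP indices involved in the ``top_m`` best models of each
    search (ranked by reported test score), deduplicated, order of first
    appearance preserved."""
    seen: dict[int, None] = {}
    for res in results:
        order = np.argsort(-res.mean_test)
        for idx in order[:top_m]:
            for s in res.combos[idx]:
                seen.setdefault(int(s), None)
    return list(seen)


@dataclass
class LassoResult:
    alpha: float
    coefs: np.ndarray
    feature_names: list[str]
    selected: list[str]
    cv_loglik: np.ndarray
    alphas: np.ndarray


def lasso_cox_select(
    X: np.ndarray,
    data: SurvivalData,
    feature_names: list[str] | None = None,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    alphas: np.ndarray | None = None,
    cv_folds: int = 10,
    l1_ratio: float = 1.0,
    seed: int = 0,
) -> LassoResult:
    """L1-penalized Cox selection with unpenalized covariates.

    The regularization path is fit by coordinate descent; the penalty is
    chosen by ``cv_folds``-fold cross-validated held-out Breslow partial
    log-likelihood; features with nonzero coefficients at the chosen
    penalty are returned.  Covariate columns carry penalty factor 0 and are
    never shrunk away.
    """
    if data.n_events < 1:
        raise ValueError("no events")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != X.shape[0]:
            covariates = covariates.T
        c = covariates.shape[1]
        design = np.column_stack([covariates, X])
        names = list(covariate_names or [f"cov{j}" for j in range(c)]) + list(feature_names)
        pf = np.r_[np.zeros(c), np.ones(p)]
    else:
        c = 0
        design = X
        names = list(feature_names)
        pf = np.ones(p)
    y = Surv.from_arrays(event=data.status.astype(bool), time=data.time)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, penalty_factor=pf, alphas=alphas, alpha_min_ratio=0.01
    )
    path.fit(design, y)
    alphas_used = np.asarray(path.alphas_)
    # cross-validated held-out partial log-likelihood per alpha
    rng = np.random.default_rng(seed)
    fold_id = np.empty(data.n, dtype=int)
    fold_id[rng.permutation(data.n)] = np.arange(data.n) % cv_folds
    cv_ll = np.zeros(alphas_used.size)
    for f in range(cv_folds):
        te = fold_id == f
        tr = ~te
        if data.status[te].sum() == 0 or data.status[tr].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, penalty_factor=pf, alphas=alphas_used, alpha_min_ratio=0.01
        )
        m.fit(design[tr], y[tr])
        fitted = np.asarray(m.alphas_)
        for a_idx, a in enumerate(alphas_used):
            j = int(np.argmin(np.abs(fitted - a)))
            beta = m.coef_[:, j]
            cv_ll[a_idx] += cox_partial_loglik(beta, data.time[te], data.status[te], design[te])
    best = int(np.argmax(cv_ll))
    coefs = path.coef_[:, best]
    selected = [names[j] for j in range(len(names)) if j >= c and coefs[j] != 0]
    return LassoResult(
        alpha=float(alphas_used[best]),
        coefs=coefs,
        feature_names=names,
        selected=selected,
        cv_loglik=cv_ll,
        alphas=alphas_used,
    )


def _km_at(data: SurvivalData, mask: np.ndarray, t: float) -> float:
    if mask.sum() == 0:
        return 1.0
    times, surv, _ = km_curve(data.subset(np.flatnonzero(mask)))["all"]
    return km_eval(times, surv, t)


def td_roc(scores: np.ndarray, data: SurvivalData, t: float):
    """Cumulative/dynamic time-dependent ROC at horizon ``t``.

    Sensitivity(c, t) = Pr{f(X) > c | event by t} and specificity(c, t) =
    Pr{f(X) <= c | event-free at t}, estimated with the Kaplan–Meier
    within-stratum estimator (cumulative cases, dynamic controls; no
    nearest-neighbor smoothing).  Returns ``(fpr, tpr, auc)`` with the
    curve swept over all observed score cutoffs; AUC by trapezoid.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != data.n:
        raise ValueError("score length mismatch")
    times_all, surv_all, _ = km_curve(data)["all"]
    S_t = km_eval(times_all, surv_all, t)
    if S_t >= 1.0:
        raise ValueError(f"no events by time {t}")
    if S_t <= 0.0:
        raise ValueError(f"no survivors past time {t}")
    cutoffs = np.unique(scores)
    sens = [1.0]
    spec = [0.0]
    n = data.n
    for c in cutoffs:
        above = scores > c
        p_above = above.mean()
        S_hi = _km_at(data, above, t)
        S_lo = _km_at(data, ~above, t)
        se = (1.0 - S_hi) * p_above / (1.0 - S_t)
        sp = S_lo * (1.0 - p_above) / S_t
        sens.append(min(max(se, 0.0), 1.0))
        spec.append(min(max(sp, 0.0), 1.0))
    sens = np.round(np.asarray(sens), 12)
    fpr = np.round(1.0 - np.asarray(spec), 12)
    order = np.lexsort((sens, fpr))  # vertical runs ascend within equal fpr
    fpr, tpr = fpr[order], sens[order]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def td_auc_sweep(scores: np.ndarray, data: SurvivalData, grid: np.ndarray):
    """AUC(t) over a grid of horizons; entries without events (or without
    survivors) are NaN."""
    out = np.full(len(grid), np.nan)
    for i, t in enumerate(grid):
        try:
            out[i] = td_roc(scores, data, t)[2]
        except ValueError:
            pass
    return out


def km_risk_groups(model: MDRModel, geno, data: SurvivalData):
    """KM curves for the model's high/low groups plus a covariate-adjusted
    Cox hazard ratio of high vs low."""
    cells = assign_cells(geno, model.snps)
    ok = cells >= 0
    hi = high_mask(model.cell_labels, cells)
    if hi[ok].sum() == 0 or (ok & ~hi).sum() == 0:
        raise ValueError("one risk group is empty")
    sub = data.subset(np.flatnonzero(ok))
    grp = hi[ok].astype(int)
    curves = km_curve(sub, grp)
    design = grp[:, None].astype(float)
    if sub.covariates is not None:
        design = np.column_stack([design, sub.covariates])
    fit = fit_cox(sub.time, sub.status, design)
    hr = float(np.exp(fit.beta[0]))
    se = fit.beta_se[0]
    ci = (float(np.exp(fit.beta[0] - 1.96 * se)), float(np.exp(fit.beta[0] + 1.96 * se)))
    return {"curves": curves, "group": grp, "hr": hr, "hr_ci": ci, "fit": fit}


def simulate_gwas(
    n: int = 2000,
    m: int = 200,
    seed: int = 0,
    main_idx: int | None = None,
    pair_idx: tuple[int, int] | None = None,
    beta_main: float = 0.35,
    beta_pair: float | None = None,
    beta_smoking: float = 0.5,
    pair_maf: float = 0.4,
    pair_h2: float = 0.4,
    pair_prevalence: float = 0.5,
):
    """Synthetic cohort with one additive 1-way signal and one purely
    epistatic 2-way pair, plus a binary smoking covariate.

    Event times follow the Cox–Weibull model (baseline shape 5, scale 2)
    with hazard multiplier exp(beta_main*g + beta_pair*risk + beta_smoking*s)
    and uniform censoring on (0, 4).  Returns (GenotypeMatrix, SurvivalData,
    truth dict).
    """
    if beta_pair is None:
        beta_pair = calibrate_log_hr()  # same effect scale as the power study
    if main_idx is None:
        main_idx = m // 10
    if pair_idx is None:
        pair_idx = (m // 3, m // 3 + 1)
    if max(main_idx, *pair_idx) >= m:
        raise ValueError("signal indices exceed SNP count")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    pm = make_penetrance(pair_maf, pair_h2, rng, K=pair_prevalence)
    a, b = pair_idx
    G[:, a] = rng.binomial(2, pair_maf, n)
    G[:, b] = rng.binomial(2, pair_maf, n)
    risk = (rng.random(n) < pm.f[G[:, a], G[:, b]]).astype(float)
    smoke = rng.integers(0, 2, n).astype(float)
    eta = beta_main * G[:, main_idx] + beta_pair * risk + beta_smoking * smoke
    E = rng.exponential(1.0, n)
    T = WEIBULL_SCALE * (E / np.exp(eta)) ** (1.0 / WEIBULL_SHAPE)
    C = rng.uniform(0.0, CENSOR_UPPER, n)
    geno = GenotypeMatrix(G, snp_ids=[f"rs{j:05d}" for j in range(m)], orient_minor=False)
    data = SurvivalData(np.minimum(T, C), (T <= C).astype(int), smoke[:, None])
    truth = {"main": main_idx, "pair": (a, b), "penetrance": pm}
    return geno, data, truth


@dataclass
class PipelineResult:
    kept: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    searches: dict[int, SearchResult]
    pooled: list[str]
    lasso: LassoResult
    selected_snps: list[str]
    test_scores: np.ndarray | None = None
    auc: float | None = None
    auc_grid: np.ndarray | None = None
    auc_sweep: np.ndarray | None = None
    km: dict | None = field(default=None, repr=False)


def _pair_feature_matrix(models: list[MDRModel], geno: GenotypeMatrix):
    """High-risk indicator column per two-way model (test-time rule for
    unseen cells: low)."""
    cols, names = [], []
    for mdl in models:
        cells = assign_cells(geno, mdl.snps)
        cols.append(high_mask(mdl.cell_labels, cells).astype(float))
        names.append("x".join(mdl.snp_names))
    if not cols:
        return np.empty((geno.n, 0)), []
    return np.column_stack(cols), names


def run_pipeline(
    geno: GenotypeMatrix,
    data: SurvivalData,
    ks=(1, 2),
    r2_max: float = 0.1,
    split_ratio: float = 2 / 3,
    seed: int = 0,
    top_m: int = 50,
    n_pair_features: int = 10,
    cv_folds: int = 5,
    folds: int = 2,
    auc_grid: np.ndarray | None = None,
    chunk_size: int = 4096,
) -> PipelineResult:
    """End-to-end discovery and prediction on one cohort.

    Prune, split, fit the covariate-only null model on the training set,
    run the exhaustive residual-based search per k, pool SNPs from the top
    models, select predictors by Lasso Cox (pooled dosages + top two-way
    high-risk attributes, covariates unpenalized), then evaluate the
    selected model's risk score on the held-out third: time-dependent AUC
    and KM risk stratification for the best model.
    """
    pruned, kept = ld_prune(geno, r2_max=r2_max)
    train_idx, test_idx = split_train_test(data.n, ratio=split_ratio, seed=seed)
    g_tr = pruned.subset_subjects(train_idx)
    d_tr = data.subset(train_idx)
    g_te = pruned.subset_subjects(test_idx)
    d_te = data.subset(test_idx)
    fit = fit_cox_null(d_tr)
    resid = martingale_residuals(fit, d_tr).values
    searches = {
        k: cv_search(g_tr, resid, k, folds=folds, seed=seed + k, top=max(top_m, n_pair_features),
                     chunk_size=chunk_size)
        for k in ks
    }
    pooled_idx = pool_top_snps(list(searches.values()), top_m=top_m)
    pooled_names = [pruned.snp_ids[j] for j in pooled_idx]
    X_tr = g_tr.geno[:, pooled_idx].astype(float)
    X_te = g_te.geno[:, pooled_idx].astype(float)
    pair_models = searches[2].models[:n_pair_features] if 2 in searches else []
    P_tr, pair_names = _pair_feature_matrix(pair_models, g_tr)
    P_te, _ = _pair_feature_matrix(pair_models, g_te)
    design_tr = np.column_stack([X_tr, P_tr]) if P_tr.size else X_tr
    design_te = np.column_stack([X_te, P_te]) if P_te.size else X_te
    names = pooled_names + pair_names
    lasso = lasso_cox_select(
        design_tr,
        d_tr,
        feature_names=names,
        covariates=d_tr.covariates,
        cv_folds=cv_folds,
        seed=seed,
    )
    selected_snps: list[str] = []
    for feat in lasso.selected:
        for s in feat.split("x"):
            if s not in selected_snps:
                selected_snps.append(s)
    n_cov = 0 if d_tr.covariates is None else d_tr.covariates.shape[1]
    beta = lasso.coefs
    score_te = design_te @ beta[n_cov:]
    if n_cov:
        score_te = score_te + d_te.covariates @ beta[:n_cov]
    auc = auc_sweep = None
    try:
        horizon = float(np.median(d_te.time[d_te.status == 1]))
        _, _, auc = td_roc(score_te, d_te, horizon)
    except (ValueError, IndexError):
        pass
    if auc_grid is not None:
        auc_sweep = td_auc_sweep(score_te, d_te, auc_grid)
    km = None
    best = max((s.chosen for s in searches.values()),
               key=lambda mdl: (mdl.cv_consistency, mdl.test_score))
    try:
        km = km_risk_groups(best, g_te, d_te)
    except ValueError:
        pass
    return PipelineResult(
        kept=kept,
        train_idx=train_idx,
        test_idx=test_idx,
        searches=searches,
        pooled=pooled_names,
        lasso=lasso,
        selected_snps=selected_snps,
        test_scores=score_te,
        auc=auc,
        auc_grid=auc_grid,
        auc_sweep=auc_sweep,
        km=km,
    )
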