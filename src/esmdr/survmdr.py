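"""Log-rank-based survival MDR — the power-comparison baseline.

Surv-MDR labels each multi-locus genotype cell high-risk when the log-rank
observed-minus-expected count for the cell (cell vs. everyone else) is
nonnegative, pools cells into high/low groups exactly as the residual-based
engine does, and scores the pooled split with the *squared* log-rank
statistic.  It consumes time/status directly and offers no covariate
adjustment — the limitation the residual-based method removes.

For speed the per-cell O-E numerators are computed in counting-process
form: over any sample, O-E for a subject group equals the sum over the
group of ``status_i - NelsonAalen(t_i)`` evaluated on that same sample (an
exact algebraic identity under Breslow/Nelson-Aalen tie handling).  The
explicit risk-table log-rank in :mod:`esmdr.survival` provides the
independent route against which this is tested.
"""
from __future__ import annotations

import numpy as np

from .mdr import (
    EMPTY,
    HIGH,
    LOW,
    MDRModel,
    SearchResult,
    _as_geno_array,
    _half_stats,
    assign_cells,
    cells_matrix,
    enumerate_combos,
    high_mask,
    make_folds,
)
from .survival import SurvivalData, fit_cox, logrank

__all__ = ["survmdr_label_cells", "survmdr_score", "survmdr_cv_search"]


def _na_residuals(time: np.ndarray, status: np.ndarray) -> np.ndarray:
    """status_i - NelsonAalen(t_i), computed on the sample itself."""
    fit = fit_cox(time, status, None)
    return status.astype(float) - fit.cumhaz(time)


def survmdr_label_cells(cells: np.ndarray, data: SurvivalData, k: int | None = None) -> np.ndarray:
    """HIGH where the cell's log-rank O-E (cell vs rest) is >= 0, LOW where
    negative, EMPTY where unpopulated."""
    cells = np.asarray(cells)
    if k is None:
        k = 1
        while 3**k <= cells.max(initial=0):
            k += 1
    C = 3**k
    r = _na_residuals(data.time, data.status)
    valid = cells >= 0
    cnt = np.bincount(cells[valid], minlength=C)
    oe = np.bincount(cells[valid], weights=r[valid], minlength=C)
    labels = np.where(oe >= 0, HIGH, LOW).astype(np.int8)
    labels[cnt == 0] = EMPTY
    return labels


def survmdr_score(cell_labels: np.ndarray, cells: np.ndarray, data: SurvivalData) -> float:
    """Squared log-rank statistic between the pooled high and low groups.

    Returns 0.0 when either pooled group is empty.
    """
    hi = high_mask(np.asarray(cell_labels), np.asarray(cells))
    ok = np.asarray(cells) >= 0
    if hi.sum() == 0 or (ok & ~hi).sum() == 0:
        return 0.0
    sub = data.subset(np.flatnonzero(ok))
    return float(logrank(sub, hi[ok]).chi2)


def _logrank_chi2_many(time: np.ndarray, status: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Squared log-rank statistic per column of the group-indicator matrix
    ``Z`` (n x M).  Degenerate groupings (all/none) score 0."""
    n, M = Z.shape
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = status[order].astype(float)
    Zs = Z[order]
    uniq, first = np.unique(t, return_index=True)
    suffix = np.cumsum(Zs[::-1], axis=0)[::-1]
    Y1 = suffix[first]  # at-risk in group at each unique time (U, M)
    Y = (n - first).astype(float)
    d_u = np.add.reduceat(d, first)
    d1_u = np.add.reduceat(Zs * d[:, None], first, axis=0)
    ev = d_u > 0
    frac = Y1[ev] / Y[ev, None]
    num = (d1_u[ev] - d_u[ev, None] * frac).sum(axis=0)
    Ye = Y[ev]
    de = d_u[ev]
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = de[:, None] * frac * (1 - frac) * ((Ye - de) / np.maximum(Ye - 1, 1))[:, None]
    V = vterm.sum(axis=0)
    out = np.zeros(M)
    good = V > 0
    out[good] = num[good] ** 2 / V[good]
    return out


def survmdr_cv_search(
    geno,
    data: SurvivalData,
    k: int,
    folds: int = 2,
    seed: int = 0,
    top: int = 10,
    chunk_size: int = 4096,
) -> SearchResult:
    """Exhaustive cross-validated k-way Surv-MDR search.

    Mirrors the residual-based search: per fold, cells are labeled on the
    training portion (by train-portion O-E signs) and the squared log-rank
    score is computed on the training portion and on the held-out portion
    under the trained labels.  Selection and reporting follow the same
    training-only rule as :func:`esmdr.mdr.cv_search`.
    """
    G, names = _as_geno_array(geno)
    n, m = G.shape
    if (G < 0).any():
        raise ValueError("survmdr search does not support missing genotypes")
    combos = enumerate_combos(m, k)
    C = 3**k
    M = combos.shape[0]
    fold_id = make_folds(n, folds, seed)
    fold_idx = [np.flatnonzero(fold_id == f) for f in range(folds)]
    for fi in fold_idx:
        if data.status[np.setdiff1d(np.arange(n), fi)].sum() < 2:
            raise ValueError("fewer than 2 events in a training fold")
    # per-fold training residuals (Nelson-Aalen on the training portion),
    # stored full-length so the shared accumulator can subset by index
    r_train = np.zeros((folds, n))
    for f, fi in enumerate(fold_idx):
        tr = np.setdiff1d(np.arange(n), fi)
        r_train[f, tr] = _na_residuals(data.time[tr], data.status[tr])
    train_scores = np.empty((folds, M))
    test_scores = np.empty((folds, M))
    for lo in range(0, M, chunk_size):
        hi_ = min(lo + chunk_size, M)
        cells = cells_matrix(G, combos[lo:hi_])
        mc = hi_ - lo
        offs = np.arange(mc, dtype=np.int64) * C
        for f in range(folds):
            te = fold_idx[f]
            tr = np.setdiff1d(np.arange(n), te)
            cnt_tr, s_tr, _ = _half_stats(cells, r_train[f], tr, C)
            high = (s_tr >= 0) & (cnt_tr > 0)  # (mc, C)
            flat = high.ravel()
            Z_tr = flat[cells[tr].astype(np.int64) + offs[None, :]]
            Z_te = flat[cells[te].astype(np.int64) + offs[None, :]]
            train_scores[f, lo:hi_] = _logrank_chi2_many(data.time[tr], data.status[tr], Z_tr)
            test_scores[f, lo:hi_] = _logrank_chi2_many(data.time[te], data.status[te], Z_te)
    winners = train_scores.argmax(axis=1)
    consistency = np.bincount(winners, minlength=M)
    mean_train = train_scores.mean(axis=0)
    won = np.zeros((folds, M), dtype=bool)
    won[np.arange(folds), winners] = True
    won_mean = np.where(
        consistency > 0, (test_scores * won).sum(axis=0) / np.maximum(consistency, 1), 0.0
    )
    reported = np.where(consistency > 0, won_mean, test_scores.mean(axis=0))
    win_train = np.full(M, -np.inf)
    np.maximum.at(win_train, winners, train_scores[np.arange(folds), winners])
    tiebreak = np.where(consistency > 0, win_train, mean_train)
    order = np.lexsort((-tiebreak, -consistency))

    def _build(idx: int) -> MDRModel:
        snps = tuple(int(v) for v in combos[idx])
        labels = survmdr_label_cells(assign_cells(G, snps), data, k=k)
        return MDRModel(
            snps=snps,
            cell_labels=labels,
            train_score=float(mean_train[idx]),
            test_score=float(reported[idx]),
            cv_consistency=int(consistency[idx]),
            snp_names=tuple(names[s] for s in snps),
            fold_test_scores=test_scores[:, idx].copy(),
        )

    n_report = M if top is None else min(top, M)
    models = [_build(i) for i in order[:n_report]]
    return SearchResult(
        k=k,
        models=models,
        chosen=models[0],
        seed=seed,
        folds=folds,
        combos=combos,
        mean_test=reported,
        mean_train=mean_train,
        consistency=consistency,
    )
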