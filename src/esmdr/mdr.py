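"""Residual-based MDR engine.

The search collapses each k-tuple of SNPs into 3**k genotype-combination
cells, labels a cell high-risk when the sum of martingale residuals of its
training subjects is >= 0 (low-risk otherwise), pools the high and low cells
into a one-dimensional attribute, and scores the pooled split with a
two-sample t statistic on the residuals (high minus low).  Model selection
follows the quantitative-MDR convention: per cross-validation fold the model
with the largest training score wins; cross-validation consistency is the
number of folds won; ties are broken by mean held-out score; the reported
score of a model is the mean of its per-fold held-out scores.

Everything is vectorized over models so an exhaustive k-way scan over
thousands of SNP tuples is a handful of fused accumulation passes per fold.
A numba kernel is used for the accumulation when numba is importable; the
pure-numpy fallback is bit-identical.

A note on the reported score.  With two folds each fold's held-out set is
the other fold's training set, so any selection step that consults test
scores (or averages a model's test scores over *all* folds) contaminates the
reported score with the data it is evaluated on and grossly inflates the
null exceedance rate.  Selection here therefore uses training information
only, and the reported test score of a model is the mean of its held-out
scores over the folds it won — a quantity whose null distribution is close
to standard normal, which is what makes the fixed 1.645 significance
threshold usable without a per-dataset permutation null.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix

HIGH, LOW, EMPTY = 1, 0, -1

try:  # optional fused accumulation kernel
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in supported envs
    _HAVE_NUMBA = False


@dataclass
class MDRModel:
    """A k-tuple of SNPs with its learned cell labeling and CV scores."""

    snps: tuple[int, ...]
    cell_labels: np.ndarray  # (3**k,) values in {HIGH, LOW, EMPTY}
    train_score: float
    test_score: float
    cv_consistency: int
    snp_names: tuple[str, ...] = ()
    fold_test_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.snps)


@dataclass
class SearchResult:
    """Ranked exhaustive-search output for one interaction order k."""

    k: int
    models: list[MDRModel]
    chosen: MDRModel
    seed: int
    folds: int
    null_threshold: float | None = None
    # full per-model arrays (ranking reproducibility / downstream pooling)
    combos: np.ndarray | None = field(default=None, repr=False)
    mean_test: np.ndarray | None = field(default=None, repr=False)
    mean_train: np.ndarray | None = field(default=None, repr=False)
    consistency: np.ndarray | None = field(default=None, repr=False)


def _as_geno_array(geno) -> tuple[np.ndarray, list[str]]:
    if isinstance(geno, GenotypeMatrix):
        return geno.geno, list(geno.snp_ids)
    g = np.asarray(geno)
    return g, [f"snp{j}" for j in range(g.shape[1])]


def enumerate_combos(m: int, k: int) -> np.ndarray:
    """All C(m, k) SNP index tuples, in lexicographic order."""
    return np.array(list(itertools.combinations(range(m), k)), dtype=np.int32)


def assign_cells(geno, snps) -> np.ndarray:
    """Map each subject to a cell index in {0..3^k-1} (row-major; first SNP
    most significant).  Subjects missing any of the k genotypes get -1."""
    g, _ = _as_geno_array(geno)
    snps = tuple(int(s) for s in np.atleast_1d(snps))
    cells = np.zeros(g.shape[0], dtype=np.int32)
    missing = np.zeros(g.shape[0], dtype=bool)
    for s in snps:
        col = g[:, s]
        missing |= col == MISSING
        cells = cells * 3 + np.where(col == MISSING, 0, col)
    cells[missing] = -1
    return cells


def label_cells(cells: np.ndarray, residuals, k: int | None = None) -> np.ndarray:
    """Label each cell HIGH if its residual sum is >= 0, LOW if negative,
    EMPTY if unpopulated.  The >= 0 tie rule mirrors the subject-level
    high-risk convention."""
    cells = np.asarray(cells)
    y = np.asarray(residuals, dtype=float)
    if k is None:
        k = 1
        while 3**k <= (cells.max(initial=0)):
            k += 1
    C = 3**k
    valid = cells >= 0
    cnt = np.bincount(cells[valid], minlength=C)
    sums = np.bincount(cells[valid], weights=y[valid], minlength=C)
    labels = np.where(sums >= 0, HIGH, LOW).astype(np.int8)
    labels[cnt == 0] = EMPTY
    return labels


def cell_label_test_rule(cell_labels: np.ndarray, cell: int) -> int:
    """Test-time rule: EMPTY-in-training cells are treated as LOW."""
    lab = int(cell_labels[cell])
    return HIGH if lab == HIGH else LOW


def high_mask(cell_labels: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Per-subject pooled-group indicator under the trained labeling
    (EMPTY -> LOW); subjects with missing cells are excluded (False)."""
    mask = np.zeros(cells.shape[0], dtype=bool)
    ok = cells >= 0
    mask[ok] = cell_labels[cells[ok]] == HIGH
    return mask


def t_score(cell_labels: np.ndarray, cells: np.ndarray, residuals, welch: bool = False) -> float:
    """Pooled two-sample t statistic, high-risk group minus low-risk group.

    Returns 0.0 when either pooled group is empty (uninformative model);
    raises on zero pooled variance.
    """
    y = np.asarray(residuals, dtype=float)
    ok = np.asarray(cells) >= 0
    hi = high_mask(np.asarray(cell_labels), np.asarray(cells)) & ok
    lo = ok & ~hi
    if hi.sum() == 0 or lo.sum() == 0:
        return 0.0
    a, b = y[hi], y[lo]
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise ValueError("zero pooled variance")
    t, _ = sps.ttest_ind(a, b, equal_var=not welch)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance")
    return float(t)


# ---------------------------------------------------------------------------
# vectorized internals


def cells_matrix(G: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """(n, M) int8 cell index per subject and model; -1 where missing."""
    n = G.shape[0]
    M, k = combos.shape
    cells = np.zeros((n, M), dtype=np.int16 if 3**k > 127 else np.int8)
    missing = np.zeros((n, M), dtype=bool)
    for j in range(k):
        col = G[:, combos[:, j]]
        missing |= col == MISSING
        cells = (cells * 3 + np.where(col == MISSING, 0, col)).astype(cells.dtype)
    cells[missing] = -1
    return cells


if _HAVE_NUMBA:

    @njit(cache=True)
    def _acc_kernel(cells, y, idx, C):  # pragma: no cover - exercised via wrapper
        M = cells.shape[1]
        cnt = np.zeros((M, C), np.float64)
        s = np.zeros((M, C), np.float64)
        ss = np.zeros((M, C), np.float64)
        for ii in range(idx.shape[0]):
            i = idx[ii]
            yi = y[i]
            yi2 = yi * yi
            row = cells[i]
            for j in range(M):
                c = row[j]
                if c >= 0:
                    cnt[j, c] += 1.0
                    s[j, c] += yi
                    ss[j, c] += yi2
        return cnt, s, ss


def _half_stats(cells: np.ndarray, y: np.ndarray, idx: np.ndarray, C: int):
    """Per-(model, cell) count / residual sum / residual sum-of-squares over
    the subject subset ``idx``.  Returns three (M, C) arrays."""
    if _HAVE_NUMBA:
        return _acc_kernel(cells, y, idx.astype(np.int64), C)
    M = cells.shape[1]
    sub = cells[idx].astype(np.int64)
    yv = y[idx]
    offs = np.arange(M, dtype=np.int64) * C
    flat = sub + offs[None, :]
    valid = sub >= 0
    if valid.all():
        flat = flat.ravel()
        w = np.repeat(yv, M)
    else:
        flat = flat[valid]
        w = np.broadcast_to(yv[:, None], sub.shape)[valid]
    cnt = np.bincount(flat, minlength=M * C).astype(float)
    s = np.bincount(flat, weights=w, minlength=M * C)
    ss = np.bincount(flat, weights=w * w, minlength=M * C)
    return cnt.reshape(M, C), s.reshape(M, C), ss.reshape(M, C)


def _t_from_stats(high, cnt, s, ss, welch=False):
    """Vectorized pooled (or Welch) t statistic per model from cell moments."""
    n1 = (cnt * high).sum(1)
    s1 = (s * high).sum(1)
    q1 = (ss * high).sum(1)
    nt = cnt.sum(1)
    n0 = nt - n1
    s0 = s.sum(1) - s1
    q0 = ss.sum(1) - q1
    out = np.zeros(n1.shape[0])
    valid = (n1 > 0) & (n0 > 0) & (nt > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m0 = s0 / n0
        if welch:
            v1 = (q1 - n1 * m1**2) / np.maximum(n1 - 1, 1)
            v0 = (q0 - n0 * m0**2) / np.maximum(n0 - 1, 1)
            denom = np.sqrt(v1 / n1 + v0 / n0)
        else:
            sp2 = (q1 - n1 * m1**2 + q0 - n0 * m0**2) / (nt - 2)
            denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        t = (m1 - m0) / denom
    out[valid] = np.where(np.isfinite(t[valid]), t[valid], 0.0)
    return out


def make_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded uniform random partition into ``folds`` near-equal folds."""
    rng = np.random.default_rng(seed)
    fold_id = np.empty(n, dtype=np.int64)
    fold_id[rng.permutation(n)] = np.arange(n) % folds
    return fold_id


def _cv_scores(G, y, combos, fold_id, folds, C, welch=False, chunk_size=8192):
    """Per-fold train/test scores for every model; vectorized, chunked over
    models so results are identical regardless of chunking."""
    M = combos.shape[0]
    train_scores = np.empty((folds, M))
    test_scores = np.empty((folds, M))
    fold_idx = [np.flatnonzero(fold_id == f) for f in range(folds)]
    for lo in range(0, M, chunk_size):
        hi = min(lo + chunk_size, M)
        cells = cells_matrix(G, combos[lo:hi])
        stats = [_half_stats(cells, y, fi, C) for fi in fold_idx]
        tot = [sum(s[j] for s in stats) for j in range(3)]
        for f in range(folds):
            cnt_te, s_te, ss_te = stats[f]
            cnt_tr = tot[0] - cnt_te
            s_tr = tot[1] - s_te
            ss_tr = tot[2] - ss_te
            high = (s_tr >= 0) & (cnt_tr > 0)
            train_scores[f, lo:hi] = _t_from_stats(high, cnt_tr, s_tr, ss_tr, welch)
            test_scores[f, lo:hi] = _t_from_stats(high, cnt_te, s_te, ss_te, welch)
    return train_scores, test_scores


def cv_search(
    geno,
    residuals,
    k: int,
    folds: int = 2,
    seed: int = 0,
    top: int = 10,
    welch: bool = False,
    chunk_size: int = 8192,
    null_threshold: float | None = None,
) -> SearchResult:
    """Exhaustive cross-validated k-way search.

    Subjects are split into ``folds`` disjoint seeded folds.  For each fold,
    cells are labeled on the training portion; the t score is computed on the
    training portion (train score) and on the held-out portion under the
    trained labels (test score).  The per-fold winner maximizes the train
    score; cross-validation consistency counts fold wins; the chosen model
    has the highest consistency, ties among fold winners broken by the
    winning-fold training score.  A fold winner's reported test score is the
    mean of its held-out scores over the folds it won (held out from all the
    data that selected it); other models report their mean test score over
    all folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    G, names = _as_geno_array(geno)
    y = np.asarray(residuals, dtype=float)
    n, m = G.shape
    if y.shape[0] != n:
        raise ValueError("residual length mismatch")
    if k < 1 or k > m:
        raise ValueError("invalid interaction order k")
    combos = enumerate_combos(m, k)
    C = 3**k
    fold_id = make_folds(n, folds, seed)
    train_scores, test_scores = _cv_scores(
        G, y, combos, fold_id, folds, C, welch=welch, chunk_size=chunk_size
    )
    M = combos.shape[0]
    winners = train_scores.argmax(axis=1)
    consistency = np.bincount(winners, minlength=M)
    mean_test_all = test_scores.mean(axis=0)
    mean_train = train_scores.mean(axis=0)
    # reported score: mean held-out score over won folds; mean over all folds
    # for models that won none (descriptive only, never used for selection)
    won = np.zeros((folds, M), dtype=bool)
    won[np.arange(folds), winners] = True
    with np.errstate(invalid="ignore"):
        won_mean = np.where(
            consistency > 0, (test_scores * won).sum(axis=0) / np.maximum(consistency, 1), 0.0
        )
    reported = np.where(consistency > 0, won_mean, mean_test_all)
    # tie-break among fold winners: the winning-fold training score
    win_train = np.full(M, -np.inf)
    fold_win_scores = train_scores[np.arange(folds), winners]
    np.maximum.at(win_train, winners, fold_win_scores)
    tiebreak = np.where(consistency > 0, win_train, mean_train)
    order = np.lexsort((-tiebreak, -consistency))

    def _build(idx: int) -> MDRModel:
        snps = tuple(int(v) for v in combos[idx])
        labels = label_cells(assign_cells(G, snps), y, k=k)
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
    chosen = models[0] if n_report else _build(order[0])
    return SearchResult(
        k=k,
        models=models,
        chosen=chosen,
        seed=seed,
        folds=folds,
        null_threshold=null_threshold,
        combos=combos,
        mean_test=reported,
        mean_train=mean_train,
        consistency=consistency,
    )


def _model_cv_score(cells, y, fold_id, folds, C, welch=False) -> float:
    """Mean held-out t score of a single model under fixed folds."""
    out = 0.0
    for f in range(folds):
        te = fold_id == f
        tr = ~te
        # train labels on the training portion, score on the held-out fold
        valid_tr = cells[tr] >= 0
        cnt = np.bincount(cells[tr][valid_tr], minlength=C)
        sums = np.bincount(cells[tr][valid_tr], weights=y[tr][valid_tr], minlength=C)
        lab = np.where((sums >= 0) & (cnt > 0), HIGH, LOW).astype(np.int8)
        lab[cnt == 0] = EMPTY
        try:
            out += t_score(lab, cells[te], y[te], welch=welch)
        except ValueError:
            out += 0.0
    return out / folds


def permutation_test(
    geno,
    residuals,
    model: MDRModel,
    n_perm: int,
    seed: int = 0,
    folds: int = 2,
    observed: float | None = None,
) -> float:
    """Permutation p-value for a model's cross-validated test score.

    Residuals are permuted across subjects; the model's mean held-out score
    (over all folds — the model is fixed, so every fold is clean) is
    recomputed per permutation under the same fold split; the add-one
    estimator p = (1 + #{perm >= observed}) / (1 + n_perm) is returned.
    The observed value is recomputed with the same functional unless
    ``observed`` is supplied explicitly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    G, _ = _as_geno_array(geno)
    y = np.asarray(residuals, dtype=float)
    cells = assign_cells(G, model.snps)
    C = 3 ** len(model.snps)
    fold_id = make_folds(G.shape[0], folds, seed)
    obs = _model_cv_score(cells, y, fold_id, folds, C) if observed is None else observed
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if _model_cv_score(cells, yp, fold_id, folds, C) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def null_threshold(null_scores=None, mode: str = "empirical") -> float:
    """Significance threshold for the reported test score.

    ``empirical``: 95th percentile (linear / type-7 interpolation) of
    supplied null scores (at least 100 required).  ``normal``: the standard
    normal 95th quantile 1.6449.
    """
    if mode == "normal":
        return float(sps.norm.ppf(0.95))
    if mode == "empirical":
        scores = np.asarray(null_scores, dtype=float)
        if scores.size < 100:
            raise ValueError("need at least 100 null scores")
        return float(np.percentile(scores, 95))
    raise ValueError(f"unknown mode {mode!r}")
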