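"""Survival-analysis substrate for the residual-based MDR search.

Implements the pieces of classical survival analysis the method is built on:

* a Cox proportional-hazards fitter (Newton–Raphson on the Breslow partial
  likelihood) used to fit the *null* model — covariates only, no genetic
  factor — with a Breslow baseline cumulative hazard that reduces to the
  Nelson–Aalen estimator when there are no covariates;
* martingale residuals ``delta_i - Lambda0(t_i) * exp(beta.x_i)``, the
  continuous surrogate outcome the MDR engine consumes;
* the two-group log-rank statistic in explicit risk-table form;
* Kaplan–Meier product-limit curves.

The central algebraic fact exploited downstream: for any binary grouping, the
sum of martingale residuals from a null fit (without the grouping as a
covariate) over one group equals the log-rank observed-minus-expected
numerator for that group, i.e. the log-rank statistic with its variance set
to one.  Log-rank here is deliberately implemented by explicit risk-table
sweeps so that this identity can be verified between two independent code
paths.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurvivalData",
    "CoxNullFit",
    "MartingaleResiduals",
    "LogRankResult",
    "fit_cox",
    "fit_cox_null",
    "cox_partial_loglik",
    "martingale_residuals",
    "logrank",
    "km_curve",
]


@dataclass
class SurvivalData:
    """Right-censored survival outcomes with optional per-subject covariates.

    Parameters
    ----------
    time : array of shape (n,)
        Nonnegative event or censoring times (e.g. age at diagnosis for
        cases, age at interview for censored controls).
    status : array of shape (n,)
        Event indicator, 1 = event observed, 0 = censored.
    covariates : array of shape (n, p), optional
        Adjustment covariates (e.g. smoking status).  ``None`` or an
        ``(n, 0)`` array means no covariates.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        if self.time.shape != self.status.shape:
            raise ValueError("time and status must have equal length")
        if np.any(self.time < 0):
            raise ValueError("negative survival time")
        uniq = np.unique(self.status)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("status must be 0/1")
        self.status = self.status.astype(np.int8)
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.time.shape[0]:
                if self.covariates.shape[1] == self.time.shape[0]:
                    self.covariates = self.covariates.T
                else:
                    raise ValueError("covariate matrix must have n rows")
            if self.covariates.shape[1] == 0:
                self.covariates = None

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalData":
        cov = None if self.covariates is None else self.covariates[idx]
        return SurvivalData(self.time[idx], self.status[idx], cov)


@dataclass
class CoxNullFit:
    """A fitted Cox model: covariate log hazard ratios plus Breslow baseline.

    ``baseline_times``/``baseline_cumhaz`` describe the right-continuous step
    function Lambda0(t); evaluation beyond the last event time carries the
    last value forward, and before the first event time Lambda0 = 0.
    """

    beta: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    loglik: float
    n_iter: int = 0
    beta_cov: np.ndarray | None = field(default=None, repr=False)

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        """Evaluate Lambda0 at times ``t`` (flat extrapolation both sides)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.baseline_times, t, side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]

    @property
    def beta_se(self) -> np.ndarray:
        if self.beta_cov is None:
            return np.zeros_like(self.beta)
        return np.sqrt(np.diag(self.beta_cov))


@dataclass
class MartingaleResiduals:
    """Per-subject martingale residuals; each value is at most 1 and the sum
    over the fitting sample is ~0."""

    values: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass
class LogRankResult:
    observed: float
    expected: float
    variance: float
    statistic: float

    @property
    def chi2(self) -> float:
        return self.statistic**2


def _prepare_sorted(time: np.ndarray, status: np.ndarray, X: np.ndarray | None):
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = status[order]
    x = None if X is None else X[order]
    return order, t, d, x


def cox_partial_loglik(
    beta: np.ndarray, time: np.ndarray, status: np.ndarray, X: np.ndarray
) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector.

    Used both inside the Newton iterations and as a held-out score when
    cross-validating penalized fits.
    """
    beta = np.asarray(beta, dtype=float)
    _, t, d, x = _prepare_sorted(np.asarray(time, float), np.asarray(status), np.asarray(X, float))
    eta = x @ beta
    w = np.exp(eta)
    # suffix sums: risk set of an event at time t is {j : t_j >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ev = d == 1
    return float(np.sum(eta[ev]) - np.sum(np.log(s0[first[ev]])))


def _cox_newton(t, d, x, tol=1e-9, max_iter=100):
    n, p = x.shape
    beta = np.zeros(p)
    first = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(d == 1)
    ev_first = first[ev]
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = x @ beta
        eta -= eta.max()  # guard overflow; cancels in all ratios
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
        xw = x * w[:, None]
        s2 = np.cumsum((xw[:, :, None] * x[:, None, :])[::-1], axis=0)[::-1]
        r0 = s0[ev_first]
        r1 = s1[ev_first]
        r2 = s2[ev_first]
        mean = r1 / r0[:, None]
        grad = x[ev].sum(axis=0) - mean.sum(axis=0)
        hess = -(r2 / r0[:, None, None]).sum(axis=0) + np.einsum("ij,ik->jk", mean, mean)
        ll = float(np.sum(eta[ev]) - np.sum(np.log(r0)))
        if abs(ll - ll_old) < tol and it > 1:
            cov = np.linalg.inv(-hess)
            return beta, ll, it, cov
        ll_old = ll
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix (collinear covariates?)") from exc
        # step-halving line search
        for _ in range(30):
            cand = beta + step
            eta_c = x @ cand
            eta_c = eta_c - eta_c.max()
            w_c = np.exp(eta_c)
            s0_c = np.cumsum(w_c[::-1])[::-1]
            ll_c = float(np.sum(eta_c[ev]) - np.sum(np.log(s0_c[ev_first])))
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
    raise ValueError(f"Cox fit did not converge in {max_iter} iterations")


def fit_cox(
    time: np.ndarray,
    status: np.ndarray,
    X: np.ndarray | None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxNullFit:
    """Fit a Cox PH model by Newton–Raphson with Breslow tie handling.

    With ``X`` empty or ``None`` the partial likelihood is constant and the
    baseline cumulative hazard is the Nelson–Aalen estimator.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    n = time.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if status.sum() < 1:
        raise ValueError("no events")
    _, t, d, x = _prepare_sorted(time, status, X)
    if x is None or x.shape[1] == 0:
        beta = np.zeros(0)
        loglik = 0.0
        n_iter = 0
        cov = np.zeros((0, 0))
        w = np.ones(n)
    else:
        if np.any(np.ptp(x, axis=0) == 0):
            raise ValueError("constant covariate column")
        beta, loglik, n_iter, cov = _cox_newton(t, d, x, tol=tol, max_iter=max_iter)
        eta = x @ beta
        w = np.exp(eta - eta.max())
    # Breslow baseline: Lambda0(t) = sum_{u<=t} d_u / sum_{R(u)} exp(x beta)
    uniq, counts = np.unique(t[d == 1], return_counts=True)
    starts = np.searchsorted(t, uniq, side="left")
    scale = 1.0
    if x is not None and x.shape[1] > 0:
        # normalise eta for overflow safety; the shift cancels via `scale`
        eta_full = x @ beta
        m = eta_full.max()
        w = np.exp(eta_full - m)
        scale = np.exp(-m)
    s0 = np.cumsum(w[::-1])[::-1]
    increments = counts / s0[starts] * scale
    cumhaz = np.cumsum(increments)
    return CoxNullFit(
        beta=beta,
        baseline_times=uniq,
        baseline_cumhaz=cumhaz,
        loglik=loglik,
        n_iter=n_iter,
        beta_cov=cov,
    )


def fit_cox_null(data: SurvivalData, tol: float = 1e-9, max_iter: int = 100) -> CoxNullFit:
    """Fit the covariate-only null model from which residuals are taken."""
    return fit_cox(data.time, data.status, data.covariates, tol=tol, max_iter=max_iter)


def martingale_residuals(fit: CoxNullFit, data: SurvivalData) -> MartingaleResiduals:
    """delta_i - Lambda0(t_i) exp(beta . x_i) for each subject."""
    lam = fit.cumhaz(data.time)
    if fit.beta.size:
        if data.covariates is None or data.covariates.shape[1] != fit.beta.size:
            raise ValueError("covariate schema does not match fit")
        lam = lam * np.exp(data.covariates @ fit.beta)
    return MartingaleResiduals(values=data.status.astype(float) - lam)


def null_martingale_residuals(data: SurvivalData) -> np.ndarray:
    """Convenience: residuals from the covariate-only null fit, as an array."""
    fit = fit_cox_null(data)
    return martingale_residuals(fit, data).values


def logrank(data: SurvivalData, group: np.ndarray) -> LogRankResult:
    """Two-group log-rank test via explicit risk tables.

    ``group`` is a binary vector; observed/expected totals refer to group 1.
    The standardized statistic is (sum O - sum E)/sqrt(sum V); its square is
    the usual chi-square form.
    """
    group = np.asarray(group).astype(bool)
    if group.shape[0] != data.n:
        raise ValueError("group length mismatch")
    if group.all() or (~group).all():
        raise ValueError("degenerate grouping")
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    d = data.status[order]
    g = group[order]
    n = t.shape[0]
    uniq = np.unique(t[d == 1])
    O1 = E1 = V = 0.0
    for u in uniq:
        at_risk = t >= u
        Y = int(at_risk.sum())
        Y1 = int((at_risk & g).sum())
        ev = (t == u) & (d == 1)
        dj = int(ev.sum())
        d1 = int((ev & g).sum())
        O1 += d1
        E1 += dj * Y1 / Y
        if Y > 1:
            V += dj * (Y1 / Y) * (1 - Y1 / Y) * (Y - dj) / (Y - 1)
    stat = (O1 - E1) / np.sqrt(V) if V > 0 else 0.0
    return LogRankResult(observed=O1, expected=E1, variance=V, statistic=float(stat))


def km_curve(data: SurvivalData, group: np.ndarray | None = None):
    """Kaplan–Meier product-limit estimate, optionally per binary group.

    Returns a dict ``label -> (times, survival, at_risk)`` where ``times``
    are the unique event times, ``survival`` the step values just after each
    time, and ``at_risk`` the risk-set sizes.  With ``group=None`` there is a
    single entry under key ``"all"``.
    """
    if group is None:
        groups = {"all": np.ones(data.n, dtype=bool)}
    else:
        group = np.asarray(group)
        labels = np.unique(group)
        if labels.size < 2:
            raise ValueError("empty group: both group labels must be present")
        groups = {int(v): group == v for v in labels}
    out = {}
    for label, mask in groups.items():
        if not mask.any():
            raise ValueError(f"empty group {label!r}")
        t = data.time[mask]
        d = data.status[mask]
        uniq = np.unique(t[d == 1])
        surv = []
        at_risk = []
        s = 1.0
        for u in uniq:
            Y = int((t >= u).sum())
            dj = int(((t == u) & (d == 1)).sum())
            s *= 1.0 - dj / Y
            surv.append(s)
            at_risk.append(Y)
        out[label] = (uniq, np.asarray(surv), np.asarray(at_risk, dtype=int))
    return out


def km_eval(times: np.ndarray, surv: np.ndarray, t: float) -> float:
    """Evaluate a KM step function at time ``t`` (right-continuous)."""
    idx = np.searchsorted(times, t, side="right")
    if idx == 0:
        return 1.0
    return float(surv[idx - 1])
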