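"""Cox proportional-hazards baselines.

The hazard is ``h(t|x) = h0(t) exp(x' beta)``; ``beta`` maximises the
Breslow-tie partial likelihood by Newton-Raphson.  Variable selection is
offered two ways: an L1 (LASSO) penalty solved by cyclic coordinate
descent on the local quadratic approximation, with the penalty weight
tuned by the cross-validated log partial likelihood (Verweij-van
Houwelingen), and a group-wise backward elimination driven by approximate
multi-degree-of-freedom Wald statistics (Lawless-Singhal).  Survival
prediction uses the Breslow baseline cumulative hazard:
``S(t|x) = exp(-H0(t) exp((x - x_bar)' beta))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .discretize import SurvivalDataset

__all__ = [
    "CoxFit",
    "fit_cox",
    "predict_cox_survival",
    "fit_cox_lasso",
    "lasso_lambda_max",
    "cvpl",
    "select_lambda",
    "backward_eliminate",
    "log_partial_likelihood",
]


def _design(data: SurvivalDataset) -> np.ndarray:
    return data.covariates.to_numpy(dtype=float)


def _breslow(X, time, event, beta, order=2):
    """Breslow-tie log partial likelihood and, optionally, its gradient
    and observed information.

    Risk-set sums are suffix cumulative sums over subjects sorted by
    time; tied event times share one risk-set term weighted by the tie
    multiplicity.
    """
    n, p = X.shape
    srt = np.argsort(time, kind="stable")
    Xs, ts, ds = X[srt], time[srt], event[srt].astype(bool)
    eta = Xs @ beta if p else np.zeros(n)
    eta = eta - eta.max()  # stabilise exp; partial likelihood terms are ratios
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    ll = float(eta[ds].sum())
    if p:
        S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    # first index of each distinct time = start of its risk set
    first = np.r_[True, ts[1:] != ts[:-1]]
    risk_start = np.maximum.accumulate(np.where(first, np.arange(n), 0))
    ev_idx = np.flatnonzero(ds)
    ev_start = risk_start[ev_idx]
    ll -= float(np.log(S0[ev_start]).sum())
    if order == 0:
        return ll, None, None
    if p == 0:
        return ll, np.zeros(0), np.zeros((0, 0))
    mean = S1[ev_start] / S0[ev_start, None]  # (D, p)
    grad = Xs[ev_idx].sum(axis=0) - mean.sum(axis=0)
    if order == 1:
        return ll, grad, None
    S2 = np.cumsum((w[:, None, None] * Xs[:, :, None] * Xs[:, None, :])[::-1], axis=0)[::-1]
    info = np.zeros((p, p))
    for r, s0 in zip(ev_start, S0[ev_start]):
        m = S1[r] / s0
        info += S2[r] / s0 - np.outer(m, m)
    return ll, grad, info


def log_partial_likelihood(data: SurvivalDataset, beta) -> float:
    """Breslow log partial likelihood at an arbitrary coefficient vector
    (invariant to covariate centering)."""
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _breslow(_design(data), data.time, data.event, beta, order=0)
    return ll


@dataclass
class CoxFit:
    """Result of a Cox-family fit.

    ``beta`` is on the original covariate scale; the prognostic index of
    the mean covariate vector is 0 (covariates are centered at ``means``).
    ``baseline_times``/``baseline_cumhaz`` give the Breslow step estimate
    of H0(t) for that centered reference.
    """

    beta: pd.Series
    se: pd.Series
    cov: np.ndarray
    loglik: float
    loglik_null: float
    means: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n: int
    n_events: int
    lambda_: float | None = None
    active_set: list[str] = field(default_factory=list)
    elimination_trace: list[dict] = field(default_factory=list)
    n_iter: int = 0

    @property
    def z(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    def prognostic_index(self, covariates) -> np.ndarray:
        X = covariates[list(self.beta.index)].to_numpy(dtype=float) \
            if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return (X - self.means) @ self.beta.to_numpy()


def _breslow_baseline(X, time, event, beta, means):
    """Breslow increments dH0(t) = d_t / sum_{R(t)} exp(PI) at each
    distinct event time, for centered covariates."""
    Xc = X - means
    srt = np.argsort(time, kind="stable")
    Xs, ts, ds = Xc[srt], time[srt], event[srt].astype(bool)
    w = np.exp(Xs @ beta) if X.shape[1] else np.ones(len(ts))
    S0 = np.cumsum(w[::-1])[::-1]
    first = np.r_[True, ts[1:] != ts[:-1]]
    risk_start = np.maximum.accumulate(np.where(first, np.arange(len(ts)), 0))
    ev = np.flatnonzero(ds)
    ev_times = ts[ev]
    uniq, counts = np.unique(ev_times, return_counts=True)
    increments = []
    for t_u, d_u in zip(uniq, counts):
        r = risk_start[np.searchsorted(ts, t_u, side="left")]
        increments.append(d_u / S0[r])
    return uniq, np.cumsum(increments)


def fit_cox(data: SurvivalDataset, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Unpenalized fit by Newton-Raphson with step-halving; converged when
    the relative log-likelihood change drops below ``tol``.  Standard
    errors come from the inverse observed information."""
    if data.event.sum() < 1:
        raise ValueError("no events; Cox model undefined")
    X = _design(data)
    n, p = X.shape
    means = X.mean(axis=0) if p else np.zeros(0)
    Xc = X - means
    names = data.covariate_names
    ll_null, _, _ = _breslow(Xc, data.time, data.event, np.zeros(p), order=0)
    beta = np.zeros(p)
    ll = ll_null
    n_iter = 0
    if p:
        for n_iter in range(1, max_iter + 1):
            ll, grad, info = _breslow(Xc, data.time, data.event, beta)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError("singular information matrix; covariates collinear?") from exc
            # step-halving keeps the likelihood non-decreasing
            factor = 1.0
            for _ in range(30):
                ll_new, _, _ = _breslow(Xc, data.time, data.event, beta + factor * step, order=0)
                if ll_new >= ll or not np.isfinite(ll_new):
                    break
                factor /= 2.0
            if not np.isfinite(ll_new):
                raise RuntimeError("log partial likelihood diverged (separation?)")
            beta = beta + factor * step
            if np.abs(beta).max() > 50:
                raise RuntimeError("coefficients diverging; monotone likelihood (separation)")
            if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
                ll = ll_new
                break
            ll = ll_new
        else:
            raise RuntimeError(f"Newton-Raphson did not converge in {max_iter} iterations")
        _, grad, info = _breslow(Xc, data.time, data.event, beta)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    else:
        cov = np.zeros((0, 0))
        se = np.zeros(0)
    bt, bh = _breslow_baseline(X, data.time, data.event, beta, means)
    return CoxFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov=cov,
        loglik=ll,
        loglik_null=ll_null,
        means=means,
        baseline_times=bt,
        baseline_cumhaz=bh,
        n=n,
        n_events=int(data.event.sum()),
        active_set=[nm for nm, b in zip(names, beta) if b != 0],
        n_iter=n_iter,
    )


def predict_cox_survival(fit: CoxFit, covariates, times) -> np.ndarray:
    """Survival matrix ``S(t|x) = exp(-H0(t) exp(PI))`` at the requested
    times; beyond the last event time the last baseline value is carried
    forward."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    pi = fit.prognostic_index(covariates)
    idx = np.searchsorted(fit.baseline_times, times, side="right") - 1
    H0 = np.where(idx >= 0, fit.baseline_cumhaz[np.maximum(idx, 0)], 0.0)
    return np.exp(-np.outer(np.exp(pi), H0))


def _soft_threshold(x, lam):
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def lasso_lambda_max(data: SurvivalDataset) -> float:
    """Smallest penalty that shrinks every coefficient to zero: the max
    absolute score at beta = 0 on the standardized scale."""
    X = _design(data)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    _, grad, _ = _breslow(Xs, data.time, data.event, np.zeros(X.shape[1]), order=1)
    return float(np.abs(grad).max())


def fit_cox_lasso(
    data: SurvivalDataset,
    lambda_: float,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """L1-penalized fit minimising ``-loglik + lambda * sum |beta_j|``
    (beta on the internally standardized scale; returned on the original
    scale).  Solved by repeated cyclic coordinate descent on the local
    quadratic approximation of the partial likelihood."""
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    if data.event.sum() < 1:
        raise ValueError("no events; Cox model undefined")
    X = _design(data)
    n, p = X.shape
    means = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column; drop it before penalized fitting")
    Xs = (X - means) / sd
    ll_null, _, _ = _breslow(Xs, data.time, data.event, np.zeros(p), order=0)
    beta = np.zeros(p)
    obj_old = -ll_null
    for outer in range(1, max_iter + 1):
        ll, grad, info = _breslow(Xs, data.time, data.event, beta)
        b = beta.copy()
        Hd = np.diag(info).copy()
        Hd[Hd <= 1e-12] = 1e-12
        for _ in range(200):
            b_prev = b.copy()
            for j in range(p):
                # partial residual of the quadratic model in coordinate j
                r_j = grad[j] - info[j] @ (b - beta) + Hd[j] * b[j]
                b[j] = _soft_threshold(r_j, lambda_) / Hd[j]
            if np.abs(b - b_prev).max() < 1e-12:
                break
        # step-halving on the penalized objective
        step = b - beta
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_c, _, _ = _breslow(Xs, data.time, data.event, cand, order=0)
            obj_c = -ll_c + lambda_ * np.abs(cand).sum()
            if obj_c <= obj_old + 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if abs(obj_old - obj_c) < tol * (abs(obj_old) + 1.0):
            obj_old = obj_c
            break
        obj_old = obj_c
    else:
        raise RuntimeError(f"coordinate descent did not converge in {max_iter} outer iterations")
    beta_orig = beta / sd
    names = data.covariate_names
    bt, bh = _breslow_baseline(X, data.time, data.event, beta_orig, means)
    ll_final, _, _ = _breslow(Xs, data.time, data.event, beta, order=0)
    return CoxFit(
        beta=pd.Series(beta_orig, index=names),
        se=pd.Series(np.full(p, np.nan), index=names),
        cov=np.full((p, p), np.nan),
        loglik=ll_final,
        loglik_null=ll_null,
        means=means,
        baseline_times=bt,
        baseline_cumhaz=bh,
        n=n,
        n_events=int(data.event.sum()),
        lambda_=float(lambda_),
        active_set=[nm for nm, bj in zip(names, beta) if bj != 0],
        n_iter=outer,
    )


def _stratified_folds(event, n_folds, seed):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(event)), event)]


def cvpl(data: SurvivalDataset, lambda_: float, n_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated log partial likelihood (Verweij-van Houwelingen):
    for each fold, fit on the complement and add ``l_full(beta_hat) -
    l_without_fold(beta_hat)``.  Folds are stratified by event status.
    Higher is better."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    total = 0.0
    for fold_idx in _stratified_folds(data.event, n_folds, seed):
        mask = np.ones(data.n, dtype=bool)
        mask[fold_idx] = False
        train = data.subset(np.flatnonzero(mask))
        if train.event.sum() == 0:
            raise ValueError("a training fold has zero events; use fewer folds or reseed")
        fit = fit_cox_lasso(train, lambda_) if lambda_ > 0 else fit_cox(train)
        beta = fit.beta.to_numpy()
        ll_full = log_partial_likelihood(data, beta)
        ll_train = log_partial_likelihood(train, beta)
        total += ll_full - ll_train
    return total


def select_lambda(
    data: SurvivalDataset,
    grid,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Penalty maximising the CVPL over a grid; exact ties resolve toward
    the larger (sparser) penalty."""
    grid = sorted(float(l) for l in grid)
    if not grid:
        raise ValueError("empty lambda grid")
    rows = [{"lambda": l, "cvpl": cvpl(data, l, n_folds=n_folds, seed=seed)} for l in grid]
    table = pd.DataFrame(rows)
    best = table["cvpl"].max()
    chosen = table.loc[table["cvpl"] == best, "lambda"].max()
    return float(chosen), table


def _group_columns(data: SurvivalDataset) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for col, parent in data.group_map.items():
        groups.setdefault(parent, []).append(col)
    return groups


def backward_eliminate(data: SurvivalDataset, alpha_stay: float = 0.05) -> CoxFit:
    """Group-wise backward elimination on factors.

    At each step the fitted model's coefficient vector and covariance give
    each remaining factor an approximate multi-df Wald statistic
    ``beta_g' cov_gg^{-1} beta_g`` (no per-candidate refit); the factor
    with the largest p-value above ``alpha_stay`` is dropped and the model
    refitted, until every remaining factor satisfies the stay criterion.
    """
    current = data
    trace: list[dict] = []
    while True:
        if current.covariates.shape[1] == 0:
            warnings.warn("all factors eliminated; returning the null model", stacklevel=2)
            fit = fit_cox(current)
            fit.elimination_trace = trace
            return fit
        fit = fit_cox(current)
        groups = _group_columns(current)
        worst, worst_p = None, -1.0
        cols = list(fit.beta.index)
        for parent, members in groups.items():
            idx = [cols.index(c) for c in members]
            b = fit.beta.to_numpy()[idx]
            V = fit.cov[np.ix_(idx, idx)]
            try:
                wald = float(b @ np.linalg.solve(V, b))
            except np.linalg.LinAlgError:
                continue
            pval = float(stats.chi2.sf(wald, df=len(idx)))
            if pval > worst_p:
                worst, worst_p, worst_wald = parent, pval, wald
        if worst is None or worst_p <= alpha_stay:
            fit.elimination_trace = trace
            return fit
        trace.append({"dropped": worst, "p_value": worst_p, "wald": worst_wald})
        current = current.drop_covariates(_group_columns(current)[worst])
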