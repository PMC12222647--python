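"""Survival-statistics core.

Implements Cox proportional-hazards fitting by Newton-Raphson with Efron or
Breslow tie handling, the Kaplan-Meier-based cumulative/dynamic
time-dependent ROC AUC at a fixed horizon (the non-nearest-neighbor
Heagerty-Lumley-Pepe estimator), Kaplan-Meier curves with log-rank tests,
and likelihood-ratio model comparison.

The td-ROC conventions used throughout: cumulative cases (event by the
horizon) versus dynamic controls (still at risk beyond it); sensitivity and
specificity built from Kaplan-Meier survival within the marker strata with
the overall Kaplan-Meier in the denominators; trapezoidal integration over
all unique marker cutpoints, so tied marker comparisons contribute 1/2. In
the absence of censoring with the horizon past all observed times this
reduces exactly to the empirical concordance of the marker against the
event indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

MAX_ABS_COEF = 15.0  # |beta| beyond this is treated as separation
NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 50


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood maximization."""

    coef: pd.Series
    se: pd.Series
    loglik: float
    loglik_null: float
    n_events: int
    n_samples: int
    converged: bool
    ties: str

    @property
    def names(self) -> list[str]:
        return list(self.coef.index)

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef).rename("HR")

    def wald_p(self) -> pd.Series:
        z = self.coef / self.se
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.coef.index)

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_matrix(X, self.names)[0]
        return X @ self.coef.to_numpy()


def _as_matrix(X, names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if names is not None:
            X = X[names]
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = names if names is not None else [f"x{i}" for i in range(X.shape[1])]
    return X, list(cols)


def _cox_loglik_grad_hess(beta, X, order, event_s, tie_first, tie_count, ties):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    ``order`` sorts samples by ascending time; ``tie_first``/``tie_count``
    delimit runs of tied event times among the sorted samples.
    """
    n, p = X.shape
    Xs = X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # stabilizes exp; PL is invariant to the shift
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # risk-set suffix sums
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1], axis=0)[::-1]
    cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for start, cnt in zip(tie_first, tie_count):
        sl = slice(start, start + cnt)
        ev = event_s[sl]
        d = int(ev.sum())
        if d == 0:
            continue
        ll += float(eta[sl][ev].sum())
        grad += Xs[sl][ev].sum(axis=0)
        S0 = cw[start]
        S1 = cwx[start]
        S2 = cwxx[start]
        if ties == "efron" and d > 1:
            D0 = float(w[sl][ev].sum())
            D1 = wx[sl][ev].sum(axis=0)
            D2 = wxx[sl][ev].sum(axis=0)
            for k in range(d):
                f = k / d
                s0 = S0 - f * D0
                s1 = S1 - f * D1
                s2 = S2 - f * D2
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        else:
            ll -= d * np.log(S0)
            grad -= d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
    return ll, grad, hess


def cox_fit(X, time, event, ties: str = "efron") -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Convergence is declared when the maximum absolute score falls below
    1e-9 (at most 50 iterations); step-halving guards against overshooting.
    Monotone-likelihood separation (any ``|beta| > 15``) is flagged as
    non-converged rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie correction {ties!r}")
    Xm, names = _as_matrix(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n, p = Xm.shape
    if len(time) != n or len(event) != n:
        raise ValidationError("covariates and survival data have different lengths")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValidationError("cannot fit a Cox model with zero events")
    const = np.ptp(Xm, axis=0) == 0
    if const.any():
        raise ValidationError(
            f"constant covariates are non-identifiable: "
            f"{[names[i] for i in np.flatnonzero(const)]}"
        )
    order = np.lexsort((-event.astype(int), time))
    time_s = time[order]
    event_s = event[order]
    # runs of equal times
    boundaries = np.flatnonzero(np.r_[True, np.diff(time_s) != 0])
    tie_first = boundaries
    tie_count = np.diff(np.r_[boundaries, len(time_s)])

    beta = np.zeros(p)
    ll_null, _, _ = _cox_loglik_grad_hess(
        beta, Xm, order, event_s, tie_first, tie_count, ties
    )
    ll = ll_null
    converged = False
    for _ in range(NEWTON_MAX_ITER):
        ll, grad, hess = _cox_loglik_grad_hess(
            beta, Xm, order, event_s, tie_first, tie_count, ties
        )
        if np.max(np.abs(grad)) < NEWTON_TOL:
            converged = True
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        factor = 1.0
        for _ in range(20):
            cand = beta + factor * step
            ll_new, _, _ = _cox_loglik_grad_hess(
                cand, Xm, order, event_s, tie_first, tie_count, ties
            )
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.max(np.abs(beta)) > MAX_ABS_COEF:
            converged = False
            break
    ll, grad, hess = _cox_loglik_grad_hess(
        beta, Xm, order, event_s, tie_first, tie_count, ties
    )
    if np.max(np.abs(grad)) < NEWTON_TOL and np.max(np.abs(beta)) <= MAX_ABS_COEF:
        converged = True
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_events=n_events,
        n_samples=n,
        converged=bool(converged),
        ties=ties,
    )


def cox_score_gradient(score, time, event) -> np.ndarray:
    """Gradient of the Cox log partial likelihood with respect to the
    per-sample linear score (Breslow tie handling).

    ``g_i = event_i - exp(s_i) * H0(t_i)`` with ``H0`` the Breslow baseline
    cumulative hazard evaluated at the current score.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.lexsort((-event.astype(int), time))
    s = score[order]
    t = time[order]
    e = event[order]
    w = np.exp(s - s.max())
    atrisk = np.cumsum(w[::-1])[::-1]
    # Breslow: ties share the denominator at their common time
    boundaries = np.flatnonzero(np.r_[True, np.diff(t) != 0])
    denom = np.repeat(atrisk[boundaries], np.diff(np.r_[boundaries, len(t)]))
    increments = np.where(e, 1.0 / denom, 0.0)
    H0 = np.cumsum(increments)
    # all tied samples see the full hazard mass at their time
    last_of_run = np.r_[boundaries[1:] - 1, len(t) - 1]
    H0 = np.repeat(H0[last_of_run], np.diff(np.r_[boundaries, len(t)]))
    g_sorted = e.astype(float) - w * H0
    g = np.empty_like(g_sorted)
    g[order] = g_sorted
    return g


# --------------------------------------------------------------------------
# Kaplan-Meier and time-dependent ROC
# --------------------------------------------------------------------------

def km_survival_at(time, event, horizon: float) -> float:
    """Product-limit survival estimate at ``horizon`` (events precede
    censorings at tied times)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = len(time)
    if n == 0:
        return np.nan
    order = np.lexsort((-event.astype(int), time))
    t = time[order]
    e = event[order]
    atrisk = n - np.arange(n)
    use = (t <= horizon) & e
    factors = (atrisk[use] - 1) / atrisk[use]
    if (factors == 0).any():
        return 0.0
    return float(np.prod(factors))


@dataclass
class TdRocResult:
    """Time-dependent ROC AUC at a fixed horizon."""

    horizon: float
    auc: float
    n_cases: int
    n_controls: int
    defined: bool
    estimator: str = "km-cumulative-dynamic"


def td_auc(marker, time, event, horizon: float = 5.0) -> TdRocResult:
    """Cumulative/dynamic time-dependent ROC AUC at ``horizon``.

    Cases are samples with an observed event by the horizon; controls are
    samples observed beyond it. When either class is empty the result is
    flagged undefined (AUC NaN) rather than raising.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n_cases = int(np.count_nonzero(event & (time <= horizon)))
    n_controls = int(np.count_nonzero(time > horizon))
    if n_cases == 0 or n_controls == 0:
        return TdRocResult(horizon, np.nan, n_cases, n_controls, False)
    S = km_survival_at(time, event, horizon)
    if S <= 0.0 or S >= 1.0:
        return TdRocResult(horizon, np.nan, n_cases, n_controls, False)
    n = len(marker)
    cuts = np.unique(marker)
    # path from (1,1) (cutpoint below the minimum: everyone positive)
    # down to (0,0) (cutpoint at the maximum)
    tps = [1.0]
    fps = [1.0]
    for c in cuts:
        pos = marker > c
        npos = int(pos.sum())
        if npos == 0:
            tp, fp = 0.0, 0.0
        else:
            p = npos / n
            S1 = km_survival_at(time[pos], event[pos], horizon)
            S0 = km_survival_at(time[~pos], event[~pos], horizon)
            tp = (1.0 - S1) * p / (1.0 - S)
            fp = 1.0 - S0 * (1.0 - p) / S
        tps.append(min(max(tp, 0.0), 1.0))
        fps.append(min(max(fp, 0.0), 1.0))
    tps_arr = np.array(tps)
    fps_arr = np.array(fps)
    auc = float(
        np.sum((fps_arr[:-1] - fps_arr[1:]) * (tps_arr[:-1] + tps_arr[1:]) / 2.0)
    )
    return TdRocResult(horizon, auc, n_cases, n_controls, True)


def binary_td_auc_matrix(markers, time, event, horizon: float = 5.0) -> np.ndarray:
    """Vectorized td-ROC AUC for a stack of binary markers.

    ``markers`` is a boolean (m, n) array; the return is a length-m vector
    of AUCs with NaN wherever a marker class is empty. Agrees with
    :func:`td_auc` on each row (binary markers have a single interior ROC
    point, so the trapezoid closed form applies).
    """
    M = np.asarray(markers, dtype=bool)
    if M.ndim == 1:
        M = M[None, :]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = len(time)
    n_cases = int(np.count_nonzero(event & (time <= horizon)))
    n_controls = int(np.count_nonzero(time > horizon))
    out = np.full(M.shape[0], np.nan)
    if n_cases == 0 or n_controls == 0:
        return out
    S = km_survival_at(time, event, horizon)
    if S <= 0.0 or S >= 1.0:
        return out
    order = np.lexsort((-event.astype(int), time))
    e_s = event[order]
    t_s = time[order]
    Ms = M[:, order]
    ev_h = (t_s <= horizon) & e_s

    def _group_logS(G):
        # suffix counts give the within-group number at risk at each row
        R = np.cumsum(G[:, ::-1], axis=1)[:, ::-1].astype(float)
        active = G & ev_h
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(active & (R > 1), np.log((R - 1.0) / R), 0.0)
        zero = (active & (R == 1)).any(axis=1)
        logS = terms.sum(axis=1)
        logS[zero] = -np.inf
        return logS

    p = Ms.mean(axis=1)
    ok = (p > 0) & (p < 1)
    if not ok.any():
        return out
    S1 = np.exp(_group_logS(Ms[ok]))
    S0 = np.exp(_group_logS(~Ms[ok]))
    pk = p[ok]
    tp = np.clip((1.0 - S1) * pk / (1.0 - S), 0.0, 1.0)
    fp = np.clip(1.0 - S0 * (1.0 - pk) / S, 0.0, 1.0)
    out[ok] = 0.5 * fp * tp + 0.5 * (tp + 1.0) * (1.0 - fp)
    return out


# --------------------------------------------------------------------------
# Kaplan-Meier curves, log-rank, likelihood ratio
# --------------------------------------------------------------------------

@dataclass
class KmLogrankResult:
    curves: dict[str, pd.DataFrame]
    statistic: float
    df: int
    p_value: float


def km_logrank(groups, time, event) -> KmLogrankResult:
    """Kaplan-Meier curves per group with a k-sample log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank requires at least two non-empty groups")
    curves = {}
    for lab in labels:
        m = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    res = multivariate_logrank_test(time, groups, event)
    return KmLogrankResult(
        curves=curves,
        statistic=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


@dataclass
class LrTestResult:
    statistic: float
    df: int
    p_value: float


def lr_test(nested: CoxFit, full: CoxFit) -> LrTestResult:
    """Likelihood-ratio test of nested Cox models fit on the same samples."""
    if not set(nested.names) <= set(full.names):
        raise ValidationError(
            "models are not nested: nested covariates "
            f"{nested.names} not a subset of {full.names}"
        )
    if nested.n_samples != full.n_samples or nested.n_events != full.n_events:
        raise ValidationError("models were fit on different samples")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(
                f"negative LRT statistic {stat:.3g}; check convergence",
                stacklevel=2,
            )
        stat = 0.0
    df = len(full.names) - len(nested.names)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    if df > 0 and stat == 0.0:
        p = 1.0
    return LrTestResult(float(stat), df, p)
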