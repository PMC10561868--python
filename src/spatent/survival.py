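"""Cox proportional-hazards modelling and the spatial-effect likelihood-ratio test.

The hazard for subject ``i`` with clinical covariates ``U_i`` and
functional principal component scores ``xi_i`` is

    log h_i(t) = log h_0(t) + U_i' gamma + xi_i' beta,

fitted by maximizing the partial likelihood (Newton-Raphson with step
halving; Breslow handling of tied event times by default, Efron
optional).  Covariates are mean-centered and unit-scaled internally; the
standardization is stored on the fit so linear predictors are
reproducible, and reported coefficients are on the original covariate
scale.  The baseline cumulative hazard is the Breslow estimator at the
fitted coefficients.

Whether spatial heterogeneity carries survival signal is tested by the
likelihood-ratio test of ``H0: beta_1 = ... = beta_L = 0`` against the
model that also includes the ``L`` score covariates; the statistic
``2 (l_full - l_restricted)`` is referred to a chi-square with ``L``
degrees of freedom.  ``L`` is fixed upstream by the FPCA
fraction-of-variance rule, never re-selected inside the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .exceptions import ConsistencyError, ConvergenceError, ValidationError

__all__ = ["CoxFit", "LRTResult", "fit_cox", "lrt_spatial_effect", "linear_predictor", "partial_log_likelihood"]


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _risk_structure(time: np.ndarray, event: np.ndarray):
    """Sort descending by time and locate event-time groups.

    Returns (order, group_slices) where each slice covers the subjects
    whose time equals one distinct event time, within the descending sort
    (so the risk set of that event time is everything up to the slice end).
    """
    order = np.lexsort((1 - event, -time))  # events after censored at equal times is irrelevant; keep stable
    t_sorted = time[order]
    e_sorted = event[order]
    groups = []
    i = 0
    n = time.size
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = int(e_sorted[i:j].sum())
        if d > 0:
            groups.append((i, j, d))
        i = j
    return order, groups


def partial_log_likelihood(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray, ties: str = "breslow"
) -> float:
    """Cox partial log-likelihood at ``beta`` (no standardization applied)."""
    ll, _, _ = _cox_derivatives(np.atleast_2d(np.asarray(X, float)), np.asarray(time, float),
                                np.asarray(event, float), np.asarray(beta, float), ties, want_derivs=False)
    return ll


def _cox_derivatives(X, time, event, beta, ties, want_derivs=True):
    """Log-likelihood, gradient and Hessian of the Cox partial likelihood."""
    n, p = X.shape
    order, groups = _risk_structure(time, event)
    Xs = X[order]
    es = event[order]
    eta = Xs @ beta if p else np.zeros(n)
    w = np.exp(eta)
    wx = w[:, None] * Xs if p else np.zeros((n, 0))
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0) if p else None
    if want_derivs and p:
        wxx = wx[:, :, None] * Xs[:, None, :]
        cwxx = np.cumsum(wxx, axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for i, j, d in groups:
        ev = es[i:j] > 0
        S0 = cw[j - 1]
        S1 = cwx[j - 1] if p else None
        S2 = cwxx[j - 1] if want_derivs and p else None
        ll += float(eta[i:j][ev].sum()) if p else 0.0
        if ties == "efron" and d > 1:
            wd = w[i:j][ev]
            Wd = wd.sum()
            S1d = wx[i:j][ev].sum(axis=0) if p else None
            S2d = wxx[i:j][ev].sum(axis=0) if want_derivs and p else None
            for r in range(d):
                f = r / d
                s0 = S0 - f * Wd
                ll -= np.log(s0)
                if p:
                    s1 = S1 - f * S1d
                    grad -= s1 / s0
                    if want_derivs:
                        s2 = S2 - f * S2d
                        hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        else:  # breslow (exact when d == 1)
            ll -= d * np.log(S0)
            if p:
                grad -= d * S1 / S0
                if want_derivs:
                    hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        if p:
            grad += Xs[i:j][ev].sum(axis=0)
    return ll, grad, hess


def _newton_cox(X, time, event, ties="breslow", tol=1e-9, max_iter=60):
    n, p = X.shape
    beta = np.zeros(p)
    trace = []
    ll, grad, hess = _cox_derivatives(X, time, event, beta, ties)
    for it in range(max_iter):
        trace.append((it, ll, float(np.max(np.abs(grad))) if p else 0.0))
        if p == 0 or np.max(np.abs(grad)) < tol:
            return beta, ll, -hess, it, trace
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}", trace) from err
        # step halving
        new_beta, new = beta + step, None
        for _ in range(30):
            new = _cox_derivatives(X, time, event, new_beta, ties)
            if np.isfinite(new[0]) and new[0] >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2
        else:
            raise ConvergenceError("step halving failed to improve the partial likelihood", trace)
        if abs(new[0] - ll) < tol * (abs(ll) + 1) and np.max(np.abs(new[1])) < np.sqrt(tol):
            beta, (ll, grad, hess) = new_beta, new
            trace.append((it + 1, ll, float(np.max(np.abs(grad)))))
            return beta, ll, -hess, it + 1, trace
        beta, (ll, grad, hess) = new_beta, new
    if np.max(np.abs(grad)) < 1e-6:
        return beta, ll, -hess, max_iter, trace
    raise ConvergenceError(
        f"Newton-Raphson did not converge in {max_iter} iterations (|grad| = {np.max(np.abs(grad)):.3g})",
        trace,
    )


# ---------------------------------------------------------------------------
# public API


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``params`` are on the original covariate scale; ``params_standardized``
    on the internal mean-centered / unit-scaled design, with ``means`` and
    ``scales`` recording the transformation.  ``baseline_times`` /
    ``baseline_cumhaz`` hold the Breslow baseline cumulative hazard at the
    distinct event times.
    """

    covariates: tuple
    params: pd.Series
    params_standardized: pd.Series
    means: pd.Series
    scales: pd.Series
    log_likelihood: float
    information: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n: int
    n_events: int
    n_iter: int
    ties: str
    dropped: tuple

    def summary(self) -> pd.DataFrame:
        se_std = np.sqrt(np.diag(np.linalg.inv(self.information))) if len(self.covariates) else np.array([])
        se = se_std / self.scales.to_numpy() if len(self.covariates) else se_std
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": pd.Series(se, index=list(self.covariates)),
                "z": self.params / pd.Series(se, index=list(self.covariates)),
            }
        )


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of all score coefficients jointly zero."""

    statistic: float
    df: int
    p_value: float
    fit_full: CoxFit
    fit_restricted: CoxFit


def _design(data: pd.DataFrame, duration_col, event_col, covariates):
    for col in (duration_col, event_col, *covariates):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from survival data")
    sub = data[[duration_col, event_col, *covariates]]
    if sub.isna().any().any():
        raise ValidationError("missing values in survival design; drop or impute before fitting")
    t = sub[duration_col].to_numpy(dtype=float)
    e = sub[event_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValidationError("survival times must be positive")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValidationError("event indicator must be binary")
    if e.sum() == 0:
        raise ValidationError("no events observed; the partial likelihood is undefined")
    X = sub[list(covariates)].to_numpy(dtype=float)
    return t, e, X


def fit_cox(
    data: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxFit:
    """Maximize the Cox partial likelihood.

    Constant covariates are dropped with a warning (their coefficient is
    not identifiable); exactly collinear designs raise an error naming the
    offending columns.  Raises ``ConvergenceError`` with the iteration
    trace if Newton-Raphson fails.
    """
    if ties not in ("breslow", "efron"):
        raise ValidationError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    covariates = list(covariates)
    t, e, X = _design(data, duration_col, event_col, covariates)

    scales_all = X.std(axis=0)
    dropped = tuple(c for c, s in zip(covariates, scales_all) if s == 0)
    if dropped:
        warnings.warn(f"constant covariate(s) dropped from Cox fit: {dropped}", stacklevel=2)
    keep = [c for c in covariates if c not in dropped]
    X = X[:, [covariates.index(c) for c in keep]]
    means = X.mean(axis=0) if keep else np.array([])
    scales = X.std(axis=0) if keep else np.array([])
    Xs = (X - means) / scales if keep else X

    if keep:
        R = np.linalg.qr(Xs, mode="r")
        diag = np.abs(np.diag(R))
        bad = diag < 1e-10 * max(diag.max(), 1e-300)
        if np.any(bad):
            collinear = [keep[i] for i in np.nonzero(bad)[0]]
            raise ValidationError(f"design matrix is rank deficient; collinear column(s): {collinear}")

    beta_std, ll, info, n_iter, _ = _newton_cox(Xs, t, e, ties=ties)

    # Breslow baseline cumulative hazard at the fitted coefficients
    order, groups = _risk_structure(t, e)
    eta = Xs[order] @ beta_std if keep else np.zeros(t.size)
    cw = np.cumsum(np.exp(eta))
    times, increments = [], []
    t_sorted = t[order]
    for i, j, d in groups:
        times.append(t_sorted[i])
        increments.append(d / cw[j - 1])
    times = np.array(times)[::-1]  # ascending
    cumhaz = np.cumsum(np.array(increments)[::-1])

    params_std = pd.Series(beta_std, index=keep)
    params = pd.Series(beta_std / scales, index=keep) if keep else pd.Series(dtype=float)
    return CoxFit(
        covariates=tuple(keep),
        params=params,
        params_standardized=params_std,
        means=pd.Series(means, index=keep),
        scales=pd.Series(scales, index=keep),
        log_likelihood=float(ll),
        information=info,
        baseline_times=times,
        baseline_cumhaz=cumhaz,
        n=int(t.size),
        n_events=int(e.sum()),
        n_iter=n_iter,
        ties=ties,
        dropped=dropped,
    )


def linear_predictor(fit: CoxFit, data: pd.DataFrame) -> np.ndarray:
    """``eta_i = sum_j beta_j (x_ij - mean_j)`` using the fit's standardization."""
    missing = [c for c in fit.covariates if c not in data.columns]
    if missing:
        raise ValidationError(f"missing covariate column(s) for prediction: {missing}")
    if not fit.covariates:
        return np.zeros(len(data))
    X = data[list(fit.covariates)].to_numpy(dtype=float)
    Xs = (X - fit.means.to_numpy()) / fit.scales.to_numpy()
    return Xs @ fit.params_standardized.to_numpy()


def lrt_spatial_effect(
    data: pd.DataFrame,
    clinical_covariates: Sequence[str],
    score_columns: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> LRTResult:
    """LRT of a non-zero spatial-heterogeneity effect on the hazard.

    Fits the full model (clinical covariates plus ``L`` FPC scores) and
    the restricted model (clinical only) on the same records; the
    statistic ``2 (l_full - l_restricted)`` is chi-square with ``L``
    degrees of freedom under the null.  Scores that are constant in the
    data are dropped from the full fit but still counted in ``L`` (they
    carry no information either way).
    """
    score_columns = list(score_columns)
    clinical_covariates = list(clinical_covariates)
    if not score_columns:
        raise ValidationError("no score columns supplied to test")
    full = fit_cox(data, clinical_covariates + score_columns, duration_col, event_col, ties)
    restricted = fit_cox(data, clinical_covariates, duration_col, event_col, ties)
    stat = 2.0 * (full.log_likelihood - restricted.log_likelihood)
    if stat < -1e-8:
        raise ConsistencyError(
            f"full-model likelihood below restricted ({full.log_likelihood} < {restricted.log_likelihood})"
        )
    stat = max(stat, 0.0)
    df = len(score_columns)
    return LRTResult(
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
        fit_full=full,
        fit_restricted=restricted,
    )
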