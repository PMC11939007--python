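"""Weighted Cox proportional-hazards fitting by Newton-Raphson.

Breslow handling of ties throughout.  Case weights enter the partial
likelihood multiplicatively (as in IPTW-weighted outcome models); the
robust (sandwich) variance is then the appropriate uncertainty estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "cox_fit", "breslow_cumhaz", "cox_partial_loglik"]


class ConvergenceError(RuntimeError):
    pass


def cox_partial_loglik(beta, X, time, event, weights=None):
    """Weighted Breslow partial log-likelihood (sum, not averaged)."""
    w = np.ones(len(time)) if weights is None else np.asarray(weights, float)
    eta = X @ beta
    return _plik_from_eta(eta, time, event, w)


def _plik_from_eta(eta, time, event, w):
    order = np.argsort(-time, kind="stable")
    eta_s, e_s, w_s, t_s = eta[order], event[order], w[order], time[order]
    r = np.cumsum(w_s * np.exp(eta_s))
    # at tied times the full tied block is at risk: use the last cumsum index
    # within each tied block
    ll = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        s0 = r[j]  # risk set for this time includes whole tied block
        blk = slice(i, j + 1)
        d = (w_s[blk] * e_s[blk]).sum()
        if d > 0:
            ll += (w_s[blk] * e_s[blk] * eta_s[blk]).sum() - d * np.log(s0)
        i = j + 1
    return ll


@dataclass
class CoxFit:
    """Result of a (possibly weighted) Cox fit."""

    beta: np.ndarray
    cov: np.ndarray            # model-based (inverse information)
    robust_cov: np.ndarray | None
    loglik: float
    n_iter: int
    names: list[str] | None = None

    def hazard_ratio(self, j: int = 0, level: float = 0.95, robust: bool = False):
        """(HR, lower, upper) for coefficient ``j``."""
        cov = self.robust_cov if (robust and self.robust_cov is not None) else self.cov
        se = np.sqrt(cov[j, j])
        z = stats.norm.ppf(0.5 + level / 2)
        b = self.beta[j]
        return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))


def _cox_derivatives(beta, X, time, event, w):
    """Negative log-lik, gradient and Hessian plus score residuals."""
    n, p = X.shape
    eta = X @ beta
    exp_eta = np.exp(eta)
    order = np.argsort(-time, kind="stable")
    Xs, ts, es, ws, ee = X[order], time[order], event[order], w[order], exp_eta[order]

    s0 = np.cumsum(ws * ee)
    s1 = np.cumsum((ws * ee)[:, None] * Xs, axis=0)
    s2 = np.cumsum((ws * ee)[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    # event-time aggregates for score residuals
    ev_t, ev_s0, ev_xbar, ev_dw = [], [], [], []
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        blk = slice(i, j + 1)
        d = (ws[blk] * es[blk]).sum()
        if d > 0:
            S0, S1, S2 = s0[j], s1[j], s2[j]
            xbar = S1 / S0
            ll += (ws[blk] * es[blk] * (Xs[blk] @ beta)).sum() - d * np.log(S0)
            grad += (ws[blk] * es[blk]) @ Xs[blk] - d * xbar
            hess -= d * (S2 / S0 - np.outer(xbar, xbar))
            ev_t.append(ts[i]); ev_s0.append(S0); ev_xbar.append(xbar); ev_dw.append(d)
        i = j + 1
    grad = np.asarray(grad).ravel()
    resid_info = (np.array(ev_t), np.array(ev_s0),
                  np.array(ev_xbar) if ev_xbar else np.zeros((0, p)), np.array(ev_dw))
    return -ll, -grad, -hess, resid_info


def _score_residuals(beta, X, time, event, w, resid_info):
    ev_t, ev_s0, ev_xbar, ev_dw = resid_info
    n, p = X.shape
    exp_eta = np.exp(X @ beta)
    U = np.zeros((n, p))
    # sort event aggregates ascending in time
    idx = np.argsort(ev_t)
    ev_t, ev_s0, ev_xbar, ev_dw = ev_t[idx], ev_s0[idx], ev_xbar[idx], ev_dw[idx]
    # cumulative sums over event times s <= t of dw/s0 and dw*xbar/s0
    c0 = np.cumsum(ev_dw / ev_s0)
    c1 = np.cumsum((ev_dw / ev_s0)[:, None] * ev_xbar, axis=0)
    pos = np.searchsorted(ev_t, time, side="right") - 1
    has = pos >= 0
    for i in range(n):
        u = np.zeros(p)
        if event[i]:
            k = np.searchsorted(ev_t, time[i])
            u += X[i] - ev_xbar[k]
        if has[i]:
            u -= exp_eta[i] * (c0[pos[i]] * X[i] - c1[pos[i]])
        U[i] = w[i] * u
    return U


def cox_fit(X, time, event, weights=None, names=None, max_iter=100, tol=1e-10,
            robust=None, ridge=0.0) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step-halving.

    ``robust`` defaults to True whenever non-unit weights are supplied.
    Raises :class:`ConvergenceError` on non-convergence or separation
    (diverging coefficients), naming the offending covariate.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if robust is None:
        robust = weights is not None
    if event.sum() == 0:
        raise ValueError("no events: Cox model is not identifiable")
    sd = X.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        nm = names[j] if names else f"column {j}"
        raise ValueError(f"covariate {nm} is constant; drop it before fitting")

    beta = np.zeros(p)
    nll, g, H, info = _cox_derivatives(beta, X, time, event, w)
    for it in range(1, max_iter + 1):
        if np.abs(g).max() < 1e-9:
            break
        Hr = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(Hr, g)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving line search on the negative log-likelihood
        lam = 1.0
        for _ in range(30):
            beta_new = beta - lam * step
            nll_new, g_new, H_new, info_new = _cox_derivatives(beta_new, X, time, event, w)
            if nll_new <= nll + 1e-12:
                break
            lam /= 2
        else:
            if np.abs(g).max() < 1e-5 * max(1.0, abs(nll)):
                break  # numerically flat at the optimum
            raise ConvergenceError("line search failed to reduce the objective")
        delta = np.abs(beta_new - beta).max()
        beta, nll, g, H, info = beta_new, nll_new, g_new, H_new, info_new
        # a coefficient driving the linear predictor spread beyond ~20 on
        # the data scale signals (quasi-)separation
        eta_spread = np.abs(beta) * sd
        if eta_spread.max() > 20:
            j = int(np.argmax(eta_spread))
            nm = names[j] if names else f"column {j}"
            raise ConvergenceError(
                f"coefficient for {nm} is diverging: likely separation"
            )
        if delta < tol and np.abs(g).max() < 1e-6:
            break
    else:
        if np.abs(g).max() > 1e-4:
            raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")
        it = max_iter
    cov = np.linalg.inv(H + ridge * np.eye(p))
    rcov = None
    if robust:
        U = _score_residuals(beta, X, time, event, w, info)
        B = U.T @ U
        rcov = cov @ B @ cov
    return CoxFit(beta=beta, cov=cov, robust_cov=rcov, loglik=-nll, n_iter=it,
                  names=list(names) if names else None)


def breslow_cumhaz(eta, time, event, weights=None):
    """Breslow cumulative baseline hazard on the unique event times.

    Returns ``(times, cumhaz)`` with ``cumhaz`` nondecreasing and 0 before
    the first event; subjects enter risk sets with weight ``w * exp(eta)``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = np.asarray(eta, float)
    w = np.ones(len(time)) if weights is None else np.asarray(weights, float)
    if event.sum() == 0:
        warnings.warn("no events: baseline hazard is identically zero")
        return np.array([]), np.array([])
    order = np.argsort(-time, kind="stable")
    ts, es, ws, ees = time[order], event[order], w[order], (w * np.exp(eta))[order]
    r = np.cumsum(ees)
    uniq_t, dh = [], []
    i, n = 0, len(ts)
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        blk = slice(i, j + 1)
        d = (ws[blk] * es[blk]).sum()
        if d > 0:
            uniq_t.append(ts[i])
            dh.append(d / r[j])
        i = j + 1
    uniq_t = np.array(uniq_t)[::-1]
    dh = np.array(dh)[::-1]
    return uniq_t, np.cumsum(dh)
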