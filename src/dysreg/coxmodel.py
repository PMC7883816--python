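"""Proportional-hazards machinery shared by the screen and signature stages.

A small Newton-Raphson maximizer of the Cox partial likelihood with Efron
tie handling.  The screening and greedy-selection stages fit tens of
thousands of small models, so the fitter works directly on numpy arrays;
covariates are standardized internally for numerical stability and the
coefficients mapped back.  Harrell's concordance index is computed by pair
enumeration with the usual conventions (usable pairs: the shorter time is
an observed event; risk ties count one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CoxFit:
    covariates: list[str]
    coef: np.ndarray
    cov: np.ndarray                       # inverse observed information
    converged: bool
    n: int
    n_events: int
    c_index: float | None = None
    loglik: float = float("nan")
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov), 0.0))

    def linear_predictor(self, Z: np.ndarray) -> np.ndarray:
        """Risk score centered at the training covariate means."""
        return (np.asarray(Z, dtype=float) - self.center) @ self.coef

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


def _loglik_grad_hess_distinct(beta, Zo, eo):
    """Partial-likelihood pieces when all times are distinct (rows already
    sorted by time ascending); Efron and Breslow coincide."""
    n, p = Zo.shape
    eta = np.clip(Zo @ beta, -200, 200)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Zo)[::-1], axis=0)[::-1]
    ev = eo == 1
    U = S1[ev] / S0[ev, None]
    ll = float(eta[ev].sum() - np.log(S0[ev]).sum())
    grad = Zo[ev].sum(axis=0) - U.sum(axis=0)
    # hess = -sum_ev [ S2/S0 - U U^T ]; S2/S0 accumulated via reverse cumsum
    ZZw = w[:, None, None] * (Zo[:, :, None] * Zo[:, None, :])
    S2 = np.cumsum(ZZw[::-1], axis=0)[::-1]
    hess = -(S2[ev] / S0[ev, None, None]).sum(axis=0) + np.einsum("ij,ik->jk", U, U)
    return ll, grad, hess


def _efron_loglik_grad_hess(beta, Z, times, events):
    """Negative partial log-likelihood pieces under Efron tie handling."""
    n, p = Z.shape
    eta = Z @ beta
    # guard against overflow during line search
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    order = np.argsort(times, kind="stable")
    Zo, to, eo, wo = Z[order], times[order], events[order], w[order]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # suffix sums over risk sets
    S0 = np.concatenate([np.cumsum(wo[::-1])[::-1], [0.0]])
    S1 = np.concatenate([np.cumsum((wo[:, None] * Zo)[::-1], axis=0)[::-1],
                         np.zeros((1, p))])
    ZZw = wo[:, None, None] * (Zo[:, :, None] * Zo[:, None, :])
    S2 = np.concatenate([np.cumsum(ZZw[::-1], axis=0)[::-1], np.zeros((1, p, p))])
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        dead = [k for k in range(i, j) if eo[k] == 1]
        D = len(dead)
        if D > 0:
            wd = wo[dead]
            Zd = Zo[dead]
            sw = wd.sum()
            sz = (wd[:, None] * Zd).sum(axis=0)
            szz = (wd[:, None, None] * (Zd[:, :, None] * Zd[:, None, :])).sum(axis=0)
            ll += (eta[order][dead]).sum()
            for r in range(D):
                f = r / D
                d0 = S0[i] - f * sw
                d1 = S1[i] - f * sz
                d2 = S2[i] - f * szz
                ll -= np.log(d0)
                grad_term = d1 / d0
                grad -= grad_term
                hess -= d2 / d0 - np.outer(grad_term, grad_term)
            grad += Zd.sum(axis=0)
        i = j
    return ll, grad, hess


def fit_cox(Z: np.ndarray, times: np.ndarray, events: np.ndarray,
            covariates: list[str] | None = None, max_iter: int = 50,
            tol: float = 1e-9, compute_c: bool = True) -> CoxFit:
    """Maximize the Efron partial likelihood by Newton-Raphson.

    Requires >= 10 events and no constant covariate.  A fit that fails to
    converge (or separates) is returned flagged, with c_index None, so
    callers can exclude it from rank tests.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(times):
        Z = Z.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = Z.shape
    if covariates is None:
        covariates = [f"z{j}" for j in range(p)]
    n_events = int(events.sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; fit may be unstable")
    sd = Z.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant covariate column")
    mu = Z.mean(axis=0)
    Zs = (Z - mu) / sd
    if len(np.unique(times)) == n:
        order = np.argsort(times, kind="stable")
        Zo, eo = Zs[order], events[order]
        objective = lambda b: _loglik_grad_hess_distinct(b, Zo, eo)
    else:
        objective = lambda b: _efron_loglik_grad_hess(b, Zs, times, events)
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = objective(beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # hess is the negative information accumulated above; Newton ascent
        new = beta - step
        ll_new, *_ = objective(new)
        halvings = 0
        while ll_new < ll and halvings < 20:
            new = (beta + new) / 2
            ll_new, *_ = objective(new)
            halvings += 1
        if not np.isfinite(ll_new):
            break
        beta = new
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    if np.abs(beta).max() > 50:
        converged = False                  # effective separation
    _, _, hess = objective(beta)
    try:
        cov_s = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov_s = np.full((p, p), np.nan)
        converged = False
    coef = beta / sd
    cov = cov_s / np.outer(sd, sd)
    fit = CoxFit(covariates=list(covariates), coef=coef, cov=cov,
                 converged=converged, n=n, n_events=n_events,
                 loglik=float(ll_old), center=mu)
    # the C-index is well defined from the ranking of the linear predictor
    # even under separation (monotone likelihood); callers exclude flagged
    # fits from rank tests via `converged`
    if compute_c and np.all(np.isfinite(beta)):
        try:
            fit.c_index = concordance_index(fit.linear_predictor(Z), times, events)
        except ValueError:
            fit.c_index = None
    return fit


def concordance_index(risk_scores, times, events) -> float:
    """Harrell's C: fraction of usable pairs ranked concordantly.

    A pair is usable when the member with the strictly shorter time had an
    observed event; concordant when that member also has the higher risk
    score; risk ties contribute one half.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    # usable[i, j]: t_i < t_j and event_i
    shorter = t[:, None] < t[None, :]
    usable = shorter & (e[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    conc = (usable & higher).sum() + 0.5 * (usable & tied).sum()
    return float(conc / n_usable)
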