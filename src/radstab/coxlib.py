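"""Cox partial-likelihood and logrank primitives.

These are written in-package (rather than delegating to a survival
library) because the bootstrap model-development loop performs thousands
of univariate fits per second: the univariate Newton iteration is
vectorized across features sharing one risk-set structure, and the
two-group logrank statistic is vectorized across candidate groupings.
Correctness is cross-checked in the test suite against lifelines and
against brute-force partial-likelihood maximization.

Ties: Breslow by default (adequate for continuous risk scores); Efron
available for the single-model fitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

BETA_CAP = 15.0  # monotone-likelihood guard on any coefficient


def _sort_by_time(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t = time[order]
    # first index of each tied-time block (Breslow risk sets)
    first_idx = np.searchsorted(t, t, side="left")
    return order, t, event[order], first_idx


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit."""

    beta: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    loglik: float
    converged: bool
    flagged: bool  # monotone likelihood / capped coefficient

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se


def cox_fit(X, time, event, ties: str = "breslow", max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) covariate matrix (p >= 1); columns should be non-constant.
    time, event : survival time and event indicator (1 = event).
    ties : "breslow" or "efron".
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(time)) == X.shape[1]:
        X = X.T
    n, p = X.shape
    order, t, d, first_idx = _sort_by_time(time, event)
    Xs = X[order]
    ev = d.astype(bool)
    if ev.sum() < 1:
        raise ValueError("no events")
    efron = ties == "efron"

    # Efron bookkeeping: events grouped by tied time
    if efron:
        ev_idx = np.flatnonzero(ev)
        ev_first = first_idx[ev_idx]
        # position of each event within its tied-event block and block sizes
        uniq, inv, counts = np.unique(ev_first, return_inverse=True, return_counts=True)
        pos_in_block = np.zeros(len(ev_idx), dtype=int)
        for b in range(len(uniq)):
            sel = inv == b
            pos_in_block[sel] = np.arange(sel.sum())
        block_size = counts[inv]

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    flagged = False
    info = np.eye(p)
    for _ in range(max_iter):
        eta = Xs @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wx = w[:, None] * Xs
        wxx = wx[:, :, None] * Xs[:, None, :]
        S0 = _suffix_cumsum(w)
        S1 = _suffix_cumsum(wx)
        S2 = _suffix_cumsum(wxx)
        s0 = S0[first_idx][ev]
        s1 = S1[first_idx][ev]
        s2 = S2[first_idx][ev]
        if efron:
            # subtract the tied-event average progressively
            dw = np.zeros_like(s0)
            dwx = np.zeros_like(s1)
            dwxx = np.zeros_like(s2)
            # sums of w over tied events at each event's time
            for b, u in enumerate(uniq):
                sel = inv == b
                rows = ev_idx[sel]
                dw[sel] = w[rows].sum()
                dwx[sel] = wx[rows].sum(axis=0)
                dwxx[sel] = wxx[rows].sum(axis=0)
            frac = pos_in_block / block_size
            s0 = s0 - frac * dw
            s1 = s1 - frac[:, None] * dwx
            s2 = s2 - frac[:, None, None] * dwxx
        ll = float(np.sum(eta[ev]) - np.sum(np.log(s0)))
        mean1 = s1 / s0[:, None]
        U = Xs[ev].sum(axis=0) - mean1.sum(axis=0)
        info = (s2 / s0[:, None, None]).sum(axis=0) - (mean1[:, :, None] * mean1[:, None, :]).sum(axis=0)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            flagged = True
            break
        # step-halving if the likelihood worsens
        shrink = 1.0
        while shrink > 1e-4:
            cand = beta + shrink * step
            if np.all(np.abs(cand) <= BETA_CAP):
                break
            shrink /= 2.0
        beta = np.clip(beta + shrink * step, -BETA_CAP, BETA_CAP)
        if np.any(np.abs(beta) >= 0.9 * BETA_CAP):
            flagged = True  # monotone likelihood / separation guard
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1):
            converged = True
            break
        ll_prev = ll
    with np.errstate(invalid="ignore"):
        try:
            var = np.diag(np.linalg.inv(info))
        except np.linalg.LinAlgError:
            var = np.full(p, np.nan)
    se = np.sqrt(np.maximum(var, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pv = 2.0 * stats.norm.sf(np.abs(z))
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    S0 = _suffix_cumsum(w)
    ll = float(np.sum(eta[ev]) - np.sum(np.log(S0[first_idx][ev])))
    return CoxFit(beta, se, pv, ll, converged, flagged)


def univariate_cox(x, time, event, ties: str = "breslow") -> CoxFit:
    """Single-covariate Cox fit (thin wrapper over :func:`cox_fit`)."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    return cox_fit(x, time, event, ties=ties)


def univariate_cox_matrix(X, time, event, max_iter: int = 30, tol: float = 1e-8):
    """Univariate Breslow Cox fits for every column of X, vectorized.

    All features share the same risk-set structure, so the Newton
    iteration runs simultaneously across columns.

    Returns
    -------
    beta, se, p_value : (m,) arrays; constant columns get NaN.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    order, t, d, first_idx = _sort_by_time(time, event)
    Xs = X[order]
    ev = d.astype(bool)
    const = np.ptp(X, axis=0) == 0
    beta = np.zeros(m)
    active = ~const
    info = np.ones(m)
    for _ in range(max_iter):
        eta = np.clip(Xs * beta, -500, 500)
        w = np.exp(eta)
        S0 = _suffix_cumsum(w)[first_idx][ev]
        S1 = _suffix_cumsum(w * Xs)[first_idx][ev]
        S2 = _suffix_cumsum(w * Xs**2)[first_idx][ev]
        mean1 = S1 / S0
        U = Xs[ev].sum(axis=0) - mean1.sum(axis=0)
        info = (S2 / S0 - mean1**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, U / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)  # damped; avoids overshoot on separation
        new = np.clip(beta + np.where(active, step, 0.0), -BETA_CAP, BETA_CAP)
        moved = np.abs(new - beta)
        beta = new
        active = active & (moved > tol)
        if not active.any():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
        z = beta / se
    pv = 2.0 * stats.norm.sf(np.abs(z))
    beta = np.where(const, np.nan, beta)
    se = np.where(const, np.nan, se)
    pv = np.where(const, np.nan, pv)
    return beta, se, pv


def logrank_chi2(group, time, event) -> float:
    """Two-group logrank chi-square, 1 df: (sum(O-E))^2 / sum(V).

    ``group`` is a boolean array (True = group 1).  Returns NaN when a
    group is empty or the variance is zero.
    """
    g = np.asarray(group, dtype=bool)
    if g.all() or not g.any():
        return float("nan")
    return float(logrank_chi2_matrix(g[:, None], time, event)[0])


def logrank_chi2_matrix(groups, time, event) -> np.ndarray:
    """Logrank chi-square per column of a boolean (n, m) group matrix."""
    G = np.asarray(groups, dtype=bool)
    n, m = G.shape
    order, t, d, first_idx = _sort_by_time(time, event)
    Gs = G[order]
    ev = d.astype(bool)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])  # unique-time block starts
    n_at_risk = n - starts
    n1_at_risk = _suffix_cumsum(Gs.astype(np.int64))[starts]  # (blocks, m)
    d_total = np.add.reduceat(d, starts)
    d1 = np.add.reduceat(Gs & ev[:, None], starts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1_at_risk / n_at_risk[:, None]
        E = d_total[:, None] * frac
        denom = np.maximum(n_at_risk - 1, 1)
        V = (
            d_total[:, None]
            * frac
            * (1 - frac)
            * ((n_at_risk - d_total) / denom)[:, None]
        )
    OmE = (d1 - E).sum(axis=0)
    Vsum = V.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(Vsum > 0, OmE**2 / np.maximum(Vsum, 1e-300), np.nan)
    empty = (~G).all(axis=0) | G.all(axis=0)
    chi2 = np.where(empty, np.nan, chi2)
    return chi2


def logrank_p(group, time, event) -> float:
    """P-value of the two-group logrank test (chi2, 1 df)."""
    c = logrank_chi2(group, time, event)
    if np.isnan(c):
        return float("nan")
    return float(stats.chi2.sf(c, df=1))
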