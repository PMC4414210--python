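"""Cox proportional-hazards regression by Newton-Raphson.

Implements the partial likelihood with Efron (default) or Breslow handling
of tied event times, exact gradient/observed-information, Wald inference,
and helpers used by the penalized path (per-observation derivatives of the
partial likelihood with respect to the linear predictor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _risk_structure(time: np.ndarray, event: np.ndarray):
    """Sort ascending by time and group tied event times.

    Returns sorted times/events plus, per distinct event time, the index
    where its risk set starts (everybody with time >= t is at risk;
    censoring at t stays at risk at t) and the tied-event count.
    """
    order = np.lexsort((1 - event, time))
    t = time[order]
    e = event[order]
    event_times, d = np.unique(t[e == 1], return_counts=True)
    risk_starts = np.searchsorted(t, event_times, side="left")
    return order, t, e, event_times, risk_starts, d


def cox_loglik_grad_info(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    ties: str = "efron",
    want_info: bool = True,
):
    """Partial log-likelihood, score vector and observed information."""
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    n, p = X.shape
    order, t, e, event_times, risk_starts, d = _risk_structure(time, event)
    Xs = X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; pl is invariant to a shift
    r = np.exp(eta)
    rx = r[:, None] * Xs
    # suffix sums: S0[i] = sum_{j >= i} r_j etc.
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    if want_info:
        rxx = rx[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum(rxx[::-1], axis=0)[::-1]
    ev = e == 1
    ll = float(eta[ev].sum())
    grad = Xs[ev].sum(axis=0)
    info = np.zeros((p, p))
    no_ties = bool((d == 1).all())
    if no_ties or ties == "breslow":
        # fully vectorized: denominator S0 repeated d times per group
        s0 = S0[risk_starts]
        ll -= float((d * np.log(s0)).sum())
        m1 = S1[risk_starts] / s0[:, None]
        grad -= (d[:, None] * m1).sum(axis=0)
        if want_info:
            info += np.einsum("k,kjl->jl", d / s0, S2[risk_starts])
            info -= np.einsum("k,kj,kl->jl", d.astype(float), m1, m1)
    else:
        # Efron with ties: loop over tied event-time groups
        for g, (rs, et, dk) in enumerate(zip(risk_starts, event_times, d)):
            idx = np.nonzero((t == et) & ev)[0]
            s0 = S0[rs]
            s1 = S1[rs]
            rd = r[idx].sum()
            s1d = rx[idx].sum(axis=0)
            frac = np.arange(dk) / dk
            denom = s0 - frac * rd
            num1 = s1[None, :] - frac[:, None] * s1d[None, :]
            ll -= float(np.log(denom).sum())
            mean1 = num1 / denom[:, None]
            grad -= mean1.sum(axis=0)
            if want_info:
                s2 = S2[rs]
                s2d = (rx[idx][:, :, None] * Xs[idx][:, None, :]).sum(axis=0)
                num2 = s2[None, :, :] - frac[:, None, None] * s2d[None, :, :]
                info += (num2 / denom[:, None, None]).sum(axis=0)
                info -= np.einsum("lj,lk->jk", mean1, mean1)
    return ll, grad, (info if want_info else None)


def cox_partial_loglik(X, time, event, beta, ties: str = "efron") -> float:
    """Partial log-likelihood at ``beta`` (no derivatives)."""
    Xa, _ = _as_matrix(X)
    ll, _, _ = cox_loglik_grad_info(
        Xa, np.asarray(time, float), np.asarray(event, int), np.asarray(beta, float), ties,
        want_info=False,
    )
    return ll


@dataclass
class CoxFitResult:
    """Fitted Cox model: estimates, uncertainties and diagnostics."""

    params: pd.Series
    se: pd.Series
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    converged: bool
    separation_flag: bool = False
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def conf_int(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        lo = np.exp(self.params - z * self.se)
        hi = np.exp(self.params + z * self.se)
        return pd.DataFrame({"hr_lower_95": lo, "hr_upper_95": hi})

    @property
    def wald_p(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.Series(np.clip(p, np.finfo(float).tiny, 1.0), index=self.params.index, name="p")

    def summary(self) -> pd.DataFrame:
        """Per-covariate coefficient table in the usual reporting layout."""
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "HR": self.hr,
            }
        )
        tab = tab.join(self.conf_int)
        tab["p"] = self.wald_p
        return tab

    def to_dict(self) -> dict:
        return {
            "coef": self.params.to_dict(),
            "se": self.se.to_dict(),
            "hr": self.hr.to_dict(),
            "p": self.wald_p.to_dict(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "converged": self.converged,
        }


def cox_fit(
    X,
    time,
    event,
    ties: str = "efron",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> CoxFitResult:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Convergence: max |score| < ``score_tol`` or relative log-likelihood
    change < ``ll_tol``.  SEs come from the inverse observed information.
    Constant columns are rejected; monotone likelihood (runaway
    coefficients, as with perfect separation) sets ``separation_flag``.
    """
    Xa, names = _as_matrix(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = Xa.shape
    if n != len(time) or n != len(event):
        raise ValueError("X, time, event length mismatch")
    if not np.isfinite(Xa).all():
        raise ValueError("non-finite values in X")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if (Xa.std(axis=0) == 0).any():
        bad = [names[j] for j in np.nonzero(Xa.std(axis=0) == 0)[0]]
        raise ValueError(f"constant columns: {bad}")
    beta = np.zeros(p)
    ll_null, _, _ = cox_loglik_grad_info(Xa, time, event, beta, ties, want_info=False)
    ll = ll_null
    separation = False
    for it in range(1, max_iter + 1):
        ll, grad, info = cox_loglik_grad_info(Xa, time, event, beta, ties)
        if np.abs(grad).max() < score_tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new, _, _ = cox_loglik_grad_info(Xa, time, event, candidate, ties, want_info=False)
            if ll_new >= ll - 1e-14:
                break
            factor *= 0.5
        beta = beta + factor * step
        if np.abs(beta).max() > 15:  # log-HR beyond any plausible effect
            separation = True
            break
        if abs(ll_new - ll) < ll_tol * (abs(ll) + 1e-12):
            ll = ll_new
            break
        ll = ll_new
    else:
        raise ConvergenceError(
            "Cox Newton-Raphson did not converge",
            {"n_iter": max_iter, "max_score": float(np.abs(grad).max()), "beta": beta.tolist()},
        )
    ll, grad, info = cox_loglik_grad_info(Xa, time, event, beta, ties)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFitResult(
        params=pd.Series(beta, index=names, name="coef"),
        se=pd.Series(se, index=names, name="se"),
        loglik=ll,
        loglik_null=ll_null,
        n=n,
        n_events=int(event.sum()),
        ties=ties,
        n_iter=it,
        converged=True,
        separation_flag=separation,
        cov=cov,
    )
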