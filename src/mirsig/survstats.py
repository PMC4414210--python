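"""Nonparametric survival statistics and discrimination measures.

Kaplan-Meier product-limit curves, the k-group log-rank test, Harrell's
concordance, the Royston-Sauerbrei D-index (rank-based scaled hazard
ratio), the cumulative-case/dynamic-control time-dependent ROC AUC with
Kaplan-Meier redistribution of censored subjects, and Benjamini-Hochberg
FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coxph import cox_fit


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times; ``survival`` the estimate just
    after each; ``at_risk``/``n_events`` the risk-set size and event count
    at each time.  Censoring at an event time is counted at risk at that
    time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
    )


def logrank_test(times, events, group_labels) -> tuple[float, int, float]:
    """k-sample log-rank test.

    Returns ``(chi2, df, p)`` with the usual observed-minus-expected
    statistic and hypergeometric variance; df = k - 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 non-empty groups")
    member = np.array([labels == g for g in groups])  # k x n
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = times >= et
        n = at_risk.sum()
        d = int(((times == et) & (events == 1)).sum())
        n_g = member[:, at_risk].sum(axis=1).astype(float)
        d_g = member[:, (times == et) & (events == 1)].sum(axis=1).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            # multivariate hypergeometric covariance
            factor = d * (n - d) / (n - 1)
            p_g = n_g / n
            V += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def concordance(scores, times, events) -> float:
    """Harrell's C over usable pairs.

    A pair is usable when the earlier time is an event; higher score
    predicting earlier failure counts as concordant, score ties count 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(scores)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    conc = 0.0
    usable = 0
    for i in range(n):
        if events[i] != 1:
            continue
        later = times > times[i]
        # pairs where i fails strictly first
        usable += int(later.sum())
        conc += (scores[i] > scores[later]).sum() + 0.5 * (scores[i] == scores[later]).sum()
        # tied times where the other is censored: i failed first
        tied_cens = (times == times[i]) & (events == 0)
        usable += int(tied_cens.sum())
        conc += (scores[i] > scores[tied_cens]).sum() + 0.5 * (
            scores[i] == scores[tied_cens]
        ).sum()
    if usable == 0:
        raise ValueError("no usable pairs")
    return float(conc / usable)


def d_index(scores, times, events) -> tuple[float, float, float]:
    """Royston-Sauerbrei D: rank-based scaled hazard ratio.

    Scores are ranked, mapped to Blom normal order statistics
    z = Phi^-1((r - 3/8)/(n + 1/4)), scaled by kappa = sqrt(8/pi), and a
    Cox model is fitted on the transformed score.  Returns
    (exp(coef), SE of coef, Wald p); exp(coef) is the hazard ratio between
    the prognostic "halves" of the score distribution.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if np.all(scores == scores[0]):
        raise ValueError("all scores tied; D-index undefined")
    ranks = stats.rankdata(scores, method="average")
    z = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    kappa = np.sqrt(8.0 / np.pi)
    fit = cox_fit(z[:, None] / kappa, times, events)
    coef = float(fit.params.iloc[0])
    se = float(fit.se.iloc[0])
    p = float(fit.wald_p.iloc[0])
    return float(np.exp(coef)), se, p


@dataclass
class TimeROC:
    """Time-dependent AUCs: AUC(t) for cumulative cases / dynamic controls."""

    eval_times: np.ndarray
    auc: np.ndarray
    method: str = "km"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.eval_times, "auc": self.auc})


def _roc_at_time(scores, times, events, t) -> float:
    """AUC(t) by the Kaplan-Meier redistribution estimator.

    Cases are subjects with T <= t (cumulative), controls those with T > t
    (dynamic); censoring before t is redistributed via subgroup KM curves:
    for each cutpoint c, sens(c) = [1 - S_{>c}(t)] P(X > c) / [1 - S(t)]
    and 1 - spec(c) = S_{>c}(t) P(X > c) / S(t).
    """
    scores = np.asarray(scores, dtype=float)
    overall = km_estimate(times, events)
    s_t = overall.survival_at(t)
    if s_t >= 1.0 or s_t <= 0.0:
        return np.nan
    order = np.argsort(scores, kind="stable")[::-1]  # descending score
    cutpoints = np.unique(scores)[::-1]
    sens = [0.0]
    fpr = [0.0]
    for c in cutpoints:
        above = scores >= c
        p_above = above.mean()
        s_above = km_estimate(times[above], events[above]).survival_at(t)
        sens.append((1.0 - s_above) * p_above / (1.0 - s_t))
        fpr.append(s_above * p_above / s_t)
    sens = np.clip(np.asarray(sens), 0.0, 1.0)
    fpr = np.clip(np.asarray(fpr), 0.0, 1.0)
    # enforce monotone ROC path before integrating
    sens = np.maximum.accumulate(sens)
    fpr = np.maximum.accumulate(fpr)
    if fpr[-1] < 1.0 or sens[-1] < 1.0:
        sens = np.append(sens, 1.0)
        fpr = np.append(fpr, 1.0)
    return float(np.trapezoid(sens, fpr))


def time_dependent_roc(scores, times, events, eval_times) -> TimeROC:
    """Cumulative/dynamic AUC(t) at each evaluation time.

    Times before the first event yield NaN (no cases yet; flagged rather
    than erroring).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    eval_times = np.asarray(eval_times, dtype=float)
    if events.sum() > 0:
        first_event = times[events == 1].min()
    else:
        first_event = np.inf
    aucs = []
    for t in eval_times:
        if t < first_event:
            aucs.append(np.nan)
        else:
            aucs.append(_roc_at_time(scores, times, events, t))
    return TimeROC(eval_times=eval_times, auc=np.asarray(aucs))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
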