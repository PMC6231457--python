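"""Expression-dichotomized survival analysis.

Samples are split into high/low expression groups (median split by
default, the cutpoint always recorded), then compared with the
Kaplan-Meier product-limit estimator, the two-group log-rank test, and a
univariate Cox proportional-hazards fit whose exponentiated coefficient is
the hazard ratio of the high-expression group.

The Cox partial likelihood is maximized by Newton iteration with Breslow
tie handling; the score test at beta = 0 coincides with the log-rank
statistic on untied data, which serves as an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import DegenerateSplitError, InsufficientDataError, ValidationError

MAX_NEWTON_ITER = 50
SCORE_TOL = 1e-8


@dataclass
class DichotomizedGroups:
    groups: pd.Series  # "high" / "low" per sample
    cutpoint: float
    method: str

    @property
    def high(self) -> list[str]:
        return list(self.groups.index[self.groups == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.groups.index[self.groups == "low"])


@dataclass
class KMEstimate:
    """Product-limit survival curve: S(0) = 1, steps at event times only."""

    times: np.ndarray       # unique observed times, ascending
    survival: np.ndarray    # S(t) at each time (right-continuous)
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t) for arbitrary t >= 0."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    beta: float
    hr: float
    se: float
    z: float
    p: float
    converged: bool
    iterations: int
    n: int
    n_events: int
    score_test_chi2: float  # score test of beta = 0 (log-rank equivalent)


def dichotomize_expression(values: pd.Series, method: str = "median") -> DichotomizedGroups:
    """Split samples into high (> cutpoint) and low (<= cutpoint) groups."""
    if method != "median":
        raise ValidationError(f"unknown dichotomization method {method!r}")
    vals = values.astype(float)
    if len(vals) < 4:
        raise InsufficientDataError("need at least 4 samples to dichotomize")
    if not np.isfinite(vals).all():
        raise ValidationError("expression values must be finite")
    cut = float(vals.median())
    groups = pd.Series(np.where(vals > cut, "high", "low"), index=vals.index)
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise DegenerateSplitError(
            f"median split at {cut} leaves one group empty")
    return DichotomizedGroups(groups=groups, cutpoint=cut, method=method)


def _check_survival_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValidationError("time and event must align")
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValidationError("times must be finite and non-negative")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event must be 0 (censored) or 1")
    return time, event


def km_estimate(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimate for one group."""
    time, event = _check_survival_arrays(time, event)
    if time.size == 0:
        raise InsufficientDataError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    # survival_function_ includes t=0; keep observed times only
    sf = kmf.survival_function_["KM_estimate"]
    times = np.unique(time)
    surv = np.array([float(sf.loc[:t].iloc[-1]) for t in times])
    tbl = kmf.event_table.loc[times]
    return KMEstimate(times=times, survival=surv,
                      n_at_risk=tbl["at_risk"].to_numpy(),
                      n_events=tbl["observed"].to_numpy())


def logrank_test(time, event, group):
    """Two-group log-rank test; returns (chi-square with 1 df, p)."""
    time, event = _check_survival_arrays(time, event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    m0, m1 = group == levels[0], group == levels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValidationError("one group is empty")
    if event.sum() == 0:
        raise InsufficientDataError("no events observed")
    res = _ll_logrank(time[m0], time[m1], event_observed_A=event[m0],
                      event_observed_B=event[m1])
    return float(res.test_statistic), float(res.p_value)


def _cox_score_info(beta: float, time, event, x):
    """Breslow partial-likelihood score and observed information.

    Works on data sorted by time ascending; risk set at an event time t is
    {i : time_i >= t}, with tied events sharing one risk-set denominator.
    """
    order = np.argsort(time, kind="mergesort")
    t, d, xv = time[order], event[order], x[order]
    n = t.size
    eta = np.exp(beta * xv)
    # suffix sums over the risk set (time >= t_i)
    s0 = np.cumsum(eta[::-1])[::-1]
    s1 = np.cumsum((eta * xv)[::-1])[::-1]
    s2 = np.cumsum((eta * xv * xv)[::-1])[::-1]
    # risk-set start index for each position: first index with same time
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    ev = np.flatnonzero(d == 1)
    f = first[ev]
    xbar = s1[f] / s0[f]
    score = float(np.sum(xv[ev] - xbar))
    info = float(np.sum(s2[f] / s0[f] - xbar ** 2))
    loglik = float(np.sum(beta * xv[ev] - np.log(s0[f])))
    return score, info, loglik


def cox_univariate(time, event, covariate) -> CoxFit:
    """Univariate Cox proportional-hazards fit by Newton iteration.

    Breslow tie handling; convergence when |score| < 1e-8 or after 50
    iterations.  On monotone likelihoods (beta diverging) the fit is
    flagged non-converged and no finite HR is reported.
    """
    time, event = _check_survival_arrays(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != time.shape:
        raise ValidationError("covariate must align with time")
    if np.unique(x).size < 2:
        raise ValidationError("covariate is constant")
    if event.sum() < 2:
        raise InsufficientDataError("need at least 2 events")

    score0, info0, _ = _cox_score_info(0.0, time, event, x)
    score_chi2 = score0 ** 2 / info0 if info0 > 0 else np.nan

    beta, converged, it = 0.0, False, 0
    for it in range(1, MAX_NEWTON_ITER + 1):
        score, info, _ = _cox_score_info(beta, time, event, x)
        if abs(score) < SCORE_TOL:
            converged = True
            break
        if info <= 0 or not np.isfinite(score):
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)  # damped to survive bad starts
        if abs(beta) > 20:  # monotone likelihood: diverging coefficient
            break
    if converged:
        _, info, _ = _cox_score_info(beta, time, event, x)
        se = float(np.sqrt(1.0 / info))
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        return CoxFit(beta=float(beta), hr=float(np.exp(beta)), se=se, z=float(z),
                      p=p, converged=True, iterations=it, n=time.size,
                      n_events=int(event.sum()), score_test_chi2=score_chi2)
    return CoxFit(beta=np.nan, hr=np.nan, se=np.nan, z=np.nan, p=np.nan,
                  converged=False, iterations=it, n=time.size,
                  n_events=int(event.sum()), score_test_chi2=score_chi2)


def km_frame(est: KMEstimate, group: str) -> pd.DataFrame:
    return pd.DataFrame({"group": group, "time": est.times,
                         "survival": est.survival, "n_at_risk": est.n_at_risk,
                         "n_events": est.n_events})
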