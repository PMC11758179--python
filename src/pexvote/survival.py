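"""Survival analysis: Kaplan-Meier curves, the two-group log-rank test,
and Cox proportional-hazards regression for one binary covariate.

These are implemented in-package (rather than delegated) because the
pipeline pins conventions that matter for reproducibility and that are
cross-checked against independent references in the test suite:

* censored-at-event-time subjects count as at risk at that time
  (censoring ordered after events at ties);
* Greenwood variance for the product-limit estimate;
* Efron tie handling by default with Breslow selectable;
* the Cox score statistic at beta = 0 is exposed, which coincides with
  the log-rank chi-square on tie-free data.

Times are in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

EFRON = "efron"
BRESLOW = "breslow"


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_total: int


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxResult:
    log_hr: float
    se: float
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    ties_method: str
    score_chi2: float
    converged: bool
    n_iter: int


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape or len(t) == 0:
        raise ValidationError("times and events must be equal-length non-empty vectors")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("times must be finite and non-negative")
    if not np.isin(e, (0, 1, True, False)).all():
        raise ValidationError("events must be binary")
    return t, e.astype(bool)


def km_estimator(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors."""
    t, e = _check_times_events(times, events)
    n = len(t)
    event_times = np.unique(t[e])
    n_at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    surv = np.empty(len(event_times))
    gw_terms = np.empty(len(event_times))
    s = 1.0
    gw = 0.0
    for j, tau in enumerate(event_times):
        at_risk = int((t >= tau).sum())  # censored at tau still at risk
        d = int(((t == tau) & e).sum())
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        else:
            gw = np.inf  # S hits 0; variance term degenerates
        n_at_risk[j] = at_risk
        n_events[j] = d
        surv[j] = s
        gw_terms[j] = gw
    se = np.where(np.isfinite(gw_terms), surv * np.sqrt(np.where(np.isfinite(gw_terms), gw_terms, 0.0)), 0.0)
    return KMCurve(event_times=event_times, n_at_risk=n_at_risk,
                   n_events=n_events, survival=surv, greenwood_se=se, n_total=n)


def survival_at(curve: KMCurve, t_months: float) -> float:
    """Right-continuous step-function value S(t)."""
    if t_months < 0:
        raise ValidationError("t_months must be >= 0")
    idx = np.searchsorted(curve.event_times, t_months, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test (df = 1).

    O-E statistic for group 1 with the hypergeometric variance at each
    distinct event time.
    """
    t, e = _check_times_events(times, events)
    g = np.asarray(groups).astype(bool)
    if g.shape != t.shape:
        raise ValidationError("groups must align with times")
    if g.all() or (~g).all():
        raise ValidationError("both groups must be non-empty")
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & g).sum())
        d_j = int(((t == tau) & e).sum())
        d1_j = int(((t == tau) & e & g).sum())
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var <= 0:
        return LogRankResult(chi2=0.0, df=1, p=1.0)
    chi2 = o_minus_e ** 2 / var
    return LogRankResult(chi2=float(chi2), df=1, p=float(stats.chi2.sf(chi2, 1)))


def cox_binary(times, events, group, ties: str = EFRON) -> CoxResult:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton-Raphson on the partial likelihood; Wald CI
    ``exp(log_hr +/- 1.96 se)``. Monotone likelihoods (complete
    separation in the risk sets) are flagged via ``converged=False``.
    """
    if ties not in (EFRON, BRESLOW):
        raise ValidationError(f"ties must be {EFRON!r} or {BRESLOW!r}")
    t, e = _check_times_events(times, events)
    x = np.asarray(group).astype(float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValidationError("group must be binary")
    if x.sum() == 0 or x.sum() == len(x):
        raise ValidationError("both groups must be non-empty")
    if not e.any():
        raise ValidationError("no events observed")

    u0, i0 = _cox_score_info(0.0, t, e, x, ties)
    score_chi2 = float(u0 ** 2 / i0) if i0 > 0 else 0.0

    beta = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, 51):
        u, info = _cox_score_info(beta, t, e, x, ties)
        if info <= 1e-12:
            break
        step = u / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 30:
            break  # monotone likelihood
        if abs(u) < 1e-10 or abs(step) < 1e-12:
            converged = True
            break
    if abs(beta) > 15:
        converged = False  # monotone likelihood / complete separation
    _, info = _cox_score_info(beta, t, e, x, ties)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    zq = 1.959963984540054

    def _safe_exp(v: float) -> float:
        return float(np.exp(np.clip(v, -700, 700)))

    return CoxResult(
        log_hr=float(beta),
        se=se,
        hr=_safe_exp(beta),
        ci95=(_safe_exp(beta - zq * se), _safe_exp(beta + zq * se)),
        wald_p=float(2 * stats.norm.sf(abs(z))),
        ties_method=ties,
        score_chi2=score_chi2,
        converged=converged,
        n_iter=n_iter,
    )


def _cox_score_info(beta: float, t, e, x, ties: str) -> tuple[float, float]:
    """Clean score/information computation (used by :func:`cox_binary`)."""
    u = 0.0
    info = 0.0
    w = np.exp(beta * x)
    wx = w * x
    for tau in np.unique(t[e]):
        risk = t >= tau
        dead = (t == tau) & e
        d = int(dead.sum())
        s0_r = w[risk].sum()
        s1_r = wx[risk].sum()
        s0_d = w[dead].sum()
        s1_d = wx[dead].sum()
        u += x[dead].sum()
        for ell in range(d):
            frac = ell / d if ties == EFRON else 0.0
            s0 = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            mu = s1 / s0
            u -= mu
            info += mu - mu * mu  # E[x^2] = E[x] for binary x
    return u, info
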