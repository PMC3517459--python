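"""Right-censored survival machinery.

Kaplan-Meier product-limit estimation with Greenwood standard errors,
the k-group log-rank test, and Cox proportional-hazards regression fitted
by Newton-Raphson maximization of the partial likelihood (Breslow tie
handling by default, Efron available). All three are written directly
against their defining formulas so they can be verified against
brute-force oracles on tiny instances.

Conventions: time is in months (non-negative reals; integers are not
assumed), events are booleans (True = death observed), and when a death
and a censoring share the same time the death is processed first, i.e.
the censored subject is still in the risk set at that time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` holds the distinct times with at least one death
    (survival only jumps there); ``survival``, ``at_risk``, ``events`` and
    ``greenwood_se`` are aligned with it. ``max_follow_up`` is the largest
    observed time, death or censoring.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_se: np.ndarray
    n_total: int
    max_follow_up: float

    def __post_init__(self):
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct death times t_i,
    with d_i deaths among the n_i subjects still at risk (subjects censored
    strictly before t_i have left; subjects censored exactly at t_i are
    still counted at risk). Greenwood's formula gives the variance:
    Var S(t) = S(t)^2 * sum d_i / (n_i (n_i - d_i)).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival time")

    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = t.size

    death_times = np.unique(t[e])
    surv, se2_sum = 1.0, 0.0
    survival, at_risk, d_counts, se = [], [], [], []
    for dt in death_times:
        n_i = int(np.sum(t >= dt))
        d_i = int(np.sum((t == dt) & e))
        surv *= 1.0 - d_i / n_i
        if n_i > d_i:
            se2_sum += d_i / (n_i * (n_i - d_i))
            se_i = surv * np.sqrt(se2_sum)
        else:
            se_i = 0.0  # S hit zero; Greenwood term degenerates
        survival.append(surv)
        at_risk.append(n_i)
        d_counts.append(d_i)
        se.append(se_i)
    return KMCurve(
        event_times=np.array(death_times, dtype=float),
        survival=np.array(survival, dtype=float),
        at_risk=np.array(at_risk, dtype=int),
        events=np.array(d_counts, dtype=int),
        greenwood_se=np.array(se, dtype=float),
        n_total=n,
        max_follow_up=float(t.max()),
    )


def km_survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t).

    At an event time the post-jump value is returned. Beyond the last
    observed follow-up the last value is returned with a warning (the
    estimate is not defined there).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > curve.max_follow_up:
        warnings.warn(
            f"t={t} exceeds the last follow-up ({curve.max_follow_up}); "
            "returning the last estimate",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def km_median(curve: KMCurve) -> float | None:
    """Smallest death time with S <= 0.5, or ``None`` when never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.event_times[below[0]]) if below.size else None


def km_to_frame(curve: KMCurve) -> pd.DataFrame:
    """Tabular export (time, at_risk, events, survival, se) for plotting."""
    return pd.DataFrame({
        "time": curve.event_times,
        "at_risk": curve.at_risk,
        "events": curve.events,
        "survival": curve.survival,
        "se": curve.greenwood_se,
    })


def logrank_test(groups) -> LogRankResult:
    """k-group log-rank test.

    At every pooled death time, compares the observed deaths in each group
    with the expectation under a common survival distribution and
    accumulates the hypergeometric covariance; the statistic is the
    quadratic form over k-1 groups, chi-square distributed with k-1 df.
    """
    if len(groups) < 2:
        raise ValueError("logrank_test needs at least two groups")
    ts, es, gs = [], [], []
    for g, (t_g, e_g) in enumerate(groups):
        t_g = np.asarray(t_g, dtype=float)
        e_g = np.asarray(e_g, dtype=bool)
        if t_g.size == 0:
            raise ValueError(f"group {g} is empty")
        ts.append(t_g)
        es.append(e_g)
        gs.append(np.full(t_g.size, g))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    k = len(groups)
    df = k - 1

    death_times = np.unique(t[e])
    if death_times.size == 0:
        return LogRankResult(chi2=0.0, df=df, p=1.0)

    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for dt in death_times:
        at_risk = t >= dt
        n = at_risk.sum()
        n_g = np.bincount(g[at_risk], minlength=k).astype(float)
        dead = at_risk & (t == dt) & e
        d = dead.sum()
        d_g = np.bincount(g[dead], minlength=k).astype(float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            p_g = n_g / n
            V += d * (n - d) / (n - 1) * (np.diag(p_g) - np.outer(p_g, p_g))

    diff = (observed - expected)[:df]
    Vsub = V[:df, :df]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox regression fit with Wald inference.

    Arrays are aligned with ``names``; ``risk_ratio`` = exp(coefficient),
    ``ci95`` the Wald interval exp(coef +/- 1.96 se). Covariates without
    contrast (constant columns) are dropped before fitting and listed in
    ``dropped``.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    risk_ratio: np.ndarray
    ci95: np.ndarray  # shape (p, 2)
    p_wald: np.ndarray
    converged: bool
    n_iterations: int
    log_partial_likelihood: float
    n: int
    n_events: int
    dropped: list[str] = field(default_factory=list)
    separation_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.names,
            "coef": self.coef,
            "se": self.se,
            "risk_ratio": self.risk_ratio,
            "ci95_low": self.ci95[:, 0],
            "ci95_high": self.ci95[:, 1],
            "p": self.p_wald,
        })


def _breslow_parts(beta, X, t, e, first_idx, event_idx):
    """Log partial likelihood, gradient and information under Breslow ties.

    Inputs are pre-sorted ascending in time; ``first_idx[i]`` is the index
    of the first subject whose time equals t[i] (start of the risk set for
    an event at that time, since the risk set is {j : t_j >= t_i}).
    """
    lp = X @ beta
    lp -= lp.max()  # guard exp overflow; cancels in all ratios and in llf shift
    w = np.exp(lp)
    # suffix sums over the ascending order: S*(i) = sum_{j >= i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    k = first_idx[event_idx]
    s0 = S0[k]
    s1 = S1[k] / s0[:, None]
    s2 = S2[k] / s0[:, None, None]

    llf = float(np.sum(lp[event_idx] - np.log(s0)))
    grad = (X[event_idx] - s1).sum(axis=0)
    info = (s2 - s1[:, :, None] * s1[:, None, :]).sum(axis=0)
    return llf, grad, info


def _efron_parts(beta, X, t, e, first_idx, event_idx):
    """Efron tie-corrected log partial likelihood, gradient and information."""
    lp = X @ beta
    lp -= lp.max()
    w = np.exp(lp)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    p = X.shape[1]
    llf, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    for dt in np.unique(t[event_idx]):
        tied = event_idx[t[event_idx] == dt]
        d = tied.size
        k = first_idx[tied[0]]
        wd = w[tied].sum()
        s1d = (w[tied, None] * X[tied]).sum(axis=0)
        s2d = (w[tied, None, None] * (X[tied, :, None] * X[tied, None, :])).sum(axis=0)
        llf += float(lp[tied].sum())
        grad += X[tied].sum(axis=0)
        for l in range(d):
            f = l / d
            a0 = S0[k] - f * wd
            a1 = S1[k] - f * s1d
            a2 = S2[k] - f * s2d
            llf -= np.log(a0)
            grad -= a1 / a0
            info += a2 / a0 - np.outer(a1, a1) / a0**2
    return llf, grad, info


def cox_fit(
    covariates,
    times,
    events,
    names=None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is an (n, p) matrix, conventionally 0/1 indicators with
    1 the unfavorable level so fitted risk ratios are >= 1-directed.
    Starts at beta = 0, halves the step when the partial likelihood would
    decrease, and declares convergence when max |gradient| < ``tol``.
    Constant columns carry no contrast and are dropped with a warning; a
    coefficient walking beyond |beta| > 10 flags likely monotone likelihood
    (complete separation).
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == 1 and np.asarray(times).size != 1:
        X = X.T
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n, p = X.shape
    if t.size != n or e.size != n:
        raise ValueError("covariates, times and events must align")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)

    keep = [j for j in range(p) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(p) if j not in keep]
    if dropped:
        warnings.warn(f"dropping covariates without contrast: {dropped}", stacklevel=2)
    X = X[:, keep]
    names = [names[j] for j in keep]
    p = len(keep)
    if p == 0:
        raise ValueError("no covariate with contrast remains")
    if not e.any():
        raise ValueError("no events observed; partial likelihood is undefined")

    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    first_idx = np.searchsorted(t, t, side="left")
    event_idx = np.nonzero(e)[0]

    parts = {"breslow": _breslow_parts, "efron": _efron_parts}[ties]

    beta = np.zeros(p)
    llf, grad, info = parts(beta, X, t, e, first_idx, event_idx)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_llf, new_grad, new_info = parts(new_beta, X, t, e, first_idx, event_idx)
        halvings = 0
        while new_llf < llf - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_llf, new_grad, new_info = parts(new_beta, X, t, e, first_idx, event_idx)
            halvings += 1
        beta, llf, grad, info = new_beta, new_llf, new_grad, new_info
    else:
        it = max_iter
    if converged is False and np.max(np.abs(grad)) < tol:
        converged = True

    separation = bool(np.any(np.abs(beta) > 10))
    if separation:
        warnings.warn("coefficient magnitude > 10: possible monotone likelihood "
                      "(complete separation)", stacklevel=2)

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    with np.errstate(over="ignore"):  # separated fits: CI bound may be inf
        rr = np.exp(beta)
        ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    p_wald = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        names=names, coef=beta, se=se, risk_ratio=rr, ci95=ci,
        p_wald=p_wald, converged=converged, n_iterations=it,
        log_partial_likelihood=llf, n=n, n_events=int(e.sum()),
        dropped=dropped, separation_warning=separation,
    )


def cox_score_test(covariate, times, events) -> LogRankResult:
    """Score test of beta = 0 for a single covariate: U(0)^2 / I(0).

    On tie-free binary-covariate data this equals the two-group log-rank
    chi-square exactly (the classical identity).
    """
    X = np.asarray(covariate, dtype=float).reshape(-1, 1)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    first_idx = np.searchsorted(t, t, side="left")
    event_idx = np.nonzero(e)[0]
    _, grad, info = _breslow_parts(np.zeros(1), X, t, e, first_idx, event_idx)
    if info[0, 0] <= 0:
        # every risk set is homogeneous in x: no information, statistic 0
        # (matches the log-rank convention when its variance degenerates)
        chi2 = 0.0
    else:
        chi2 = float(grad[0] ** 2 / info[0, 0])
    return LogRankResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))
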