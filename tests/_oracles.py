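"""Brute-force reference computations for tiny survival instances.

Deliberately naive (explicit loops over risk sets, no shared code with the
package) so they can serve as independent oracles.
"""

import math


def km_curve_brute(times, events):
    """Product-limit estimate by explicit risk-set counting.

    Returns (death_times, survival). Censored subjects at a death time are
    still at risk for that death (deaths processed first).
    """
    pairs = sorted(zip(times, events))
    death_times = sorted({t for t, e in pairs if e})
    s = 1.0
    out = []
    for dt in death_times:
        n = sum(1 for t, _ in pairs if t >= dt)
        d = sum(1 for t, e in pairs if t == dt and e)
        s *= 1.0 - d / n
        out.append(s)
    return death_times, out


def km_at_brute(times, events, t):
    dts, surv = km_curve_brute(times, events)
    s = 1.0
    for dt, sv in zip(dts, surv):
        if dt <= t:
            s = sv
    return s


def logrank_2group_brute(t1, e1, t2, e2):
    """Two-group log-rank chi-square: sum of O-E with hypergeometric variance."""
    pooled = sorted({t for t, e in list(zip(t1, e1)) + list(zip(t2, e2)) if e})
    o_minus_e = 0.0
    var = 0.0
    for dt in pooled:
        n1 = sum(1 for t in t1 if t >= dt)
        n2 = sum(1 for t in t2 if t >= dt)
        d1 = sum(1 for t, e in zip(t1, e1) if t == dt and e)
        d2 = sum(1 for t, e in zip(t2, e2) if t == dt and e)
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_loglik_breslow_brute(beta, x, times, events):
    """Breslow log partial likelihood for a single covariate, explicit risk sets."""
    ll = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if not ei:
            continue
        risk = [j for j, tj in enumerate(times) if tj >= ti]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def cox_loglik_breslow_brute_multi(beta, X, times, events):
    """Breslow log partial likelihood, p covariates, explicit risk sets."""

    def lp(j):
        return sum(b * xv for b, xv in zip(beta, X[j]))

    ll = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if not ei:
            continue
        risk = [j for j, tj in enumerate(times) if tj >= ti]
        ll += lp(i) - math.log(sum(math.exp(lp(j)) for j in risk))
    return ll


def cox_loglik_efron_brute(beta, x, times, events):
    """Efron-corrected log partial likelihood for a single covariate."""
    death_times = sorted({t for t, e in zip(times, events) if e})
    ll = 0.0
    for dt in death_times:
        tied = [j for j, (t, e) in enumerate(zip(times, events)) if t == dt and e]
        risk = [j for j, t in enumerate(times) if t >= dt]
        d = len(tied)
        sum_risk = sum(math.exp(beta * x[j]) for j in risk)
        sum_tied = sum(math.exp(beta * x[j]) for j in tied)
        ll += sum(beta * x[j] for j in tied)
        for k in range(d):
            ll -= math.log(sum_risk - (k / d) * sum_tied)
    return ll
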