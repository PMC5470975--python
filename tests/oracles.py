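"""Independent oracles used by the test suite.

Deliberately naive implementations (loops, enumeration, quadrature) that
share no code with the package paths they verify.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.stats import norm


def naive_cox_loglik(beta: float, x, times, events, ties: str) -> float:
    """Written-out Cox partial log-likelihood for a single covariate."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ll = 0.0
    for tt in sorted({t for t, e in zip(times, events) if e == 1}):
        D = [i for i in range(len(times)) if times[i] == tt and events[i] == 1]
        R = [i for i in range(len(times)) if times[i] >= tt]
        d = len(D)
        ll += sum(beta * x[i] for i in D)
        if ties == "breslow":
            ll -= d * math.log(sum(math.exp(beta * x[i]) for i in R))
        elif ties == "efron":
            sR = sum(math.exp(beta * x[i]) for i in R)
            sD = sum(math.exp(beta * x[i]) for i in D)
            for el in range(d):
                ll -= math.log(sR - (el / d) * sD)
        else:
            raise ValueError(ties)
    return ll


def brute_force_cox_coef(x, times, events, ties: str, bound: float = 10.0) -> float:
    """Maximise the naive partial likelihood on a bounded interval."""
    res = minimize_scalar(
        lambda b: -naive_cox_loglik(b, x, times, events, ties),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def exhaustive_hypergeom_upper(N: int, K: int, n_q: int, k: int) -> float:
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n_q)
    hit = sum(
        math.comb(K, j) * math.comb(N - K, n_q - j)
        for j in range(k, min(K, n_q) + 1)
        if n_q - j <= N - K
    )
    return hit / total


def quadrature_fisher_pvalue(r: float, n: int) -> float:
    """Two-sided normal tail of atanh(r)·sqrt(n−3) by numeric quadrature."""
    stat = abs(math.atanh(r)) * math.sqrt(n - 3)
    tail, _ = quad(norm.pdf, stat, stat + 40.0, epsabs=0, epsrel=1e-13, limit=200)
    return 2.0 * tail


def hand_product_limit(times, events):
    """Kaplan–Meier by the textbook product formula, loops only."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for tt in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = int((times >= tt).sum())
        d = int(((times == tt) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out.append((tt, at_risk, d, s))
    return out


def bh_step_up(pvals):
    """Hand BH: sort, multiply by m/rank, enforce step-up monotonicity."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
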