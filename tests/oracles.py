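"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, avoiding the code paths (and
libraries) the package itself uses: product-limit by explicit products,
concordance by pair enumeration, Cox by scalar grid/golden-section search over
the Efron partial likelihood, matching by a literal greedy re-trace, quantiles
by the sorted-order interpolation formula.
"""

from __future__ import annotations

import math
from fractions import Fraction


def bross_multiplier(pc1: float, pc0: float, rr: float) -> float:
    """Bias multiplier via exact rational arithmetic."""
    p1, p0, r = Fraction(pc1).limit_denominator(10**9), Fraction(pc0).limit_denominator(10**9), Fraction(rr).limit_denominator(10**9)
    return float((p1 * (r - 1) + 1) / (p0 * (r - 1) + 1))


def concordance(scores, exposure) -> float:
    """c-statistic by explicit pair enumeration."""
    s1 = [s for s, e in zip(scores, exposure) if e]
    s0 = [s for s, e in zip(scores, exposure) if not e]
    total = 0.0
    for a in s1:
        for b in s0:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(s1) * len(s0))


def product_limit_incidence(times, events, horizon) -> float:
    """1 - S(horizon) by the literal product over distinct event times."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    s = 1.0
    i = 0
    n = len(times)
    at_risk = n
    while i < n:
        t = times[order[i]]
        if t > horizon:
            break
        d = 0
        c = 0
        j = i
        while j < n and times[order[j]] == t:
            if events[order[j]]:
                d += 1
            else:
                c += 1
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
        at_risk -= d + c
        i = j
    return 1.0 - s


def greedy_match(ps, exposure, caliper_width, logit=True) -> list[tuple[int, int]]:
    """Literal greedy nearest-neighbor re-trace on the logit scale."""
    def lg(p):
        return math.log(p / (1 - p)) if logit else p

    exp_idx = [i for i, e in enumerate(exposure) if e]
    une_idx = [i for i, e in enumerate(exposure) if not e]
    exp_idx.sort(key=lambda i: (-ps[i], i))
    used = set()
    pairs = []
    for i in exp_idx:
        best = None
        best_d = None
        for j in une_idx:
            if j in used:
                continue
            d = abs(lg(ps[i]) - lg(ps[j]))
            if d <= caliper_width and (best_d is None or d < best_d or (d == best_d and j < best)):
                best, best_d = j, d
        if best is not None:
            pairs.append((i, best))
            used.add(best)
    return pairs


def percentile_linear(values, q) -> float:
    """q-th percentile (0-100) with linear interpolation, from the definition."""
    v = sorted(values)
    if len(v) == 1:
        return float(v[0])
    h = (len(v) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def rubin_pool(estimates):
    """Rubin's rules by hand: (qbar, W, B, T)."""
    m = len(estimates)
    qs = [q for q, _ in estimates]
    us = [u for _, u in estimates]
    qbar = sum(qs) / m
    w = sum(us) / m
    b = sum((q - qbar) ** 2 for q in qs) / (m - 1) if m > 1 else 0.0
    t = w + (1 + 1 / m) * b
    return qbar, w, b, t


# ---------------------------------------------------------------------------
# Efron partial likelihood + scalar maximization for a single binary covariate
# ---------------------------------------------------------------------------

def efron_log_partial_likelihood(beta, times, events, x) -> float:
    n = len(times)
    distinct = sorted({times[i] for i in range(n) if events[i]})
    theta = [math.exp(beta * xi) for xi in x]
    ll = 0.0
    for t in distinct:
        tied = [i for i in range(n) if events[i] and times[i] == t]
        risk = [i for i in range(n) if times[i] >= t]
        d = len(tied)
        sum_risk = sum(theta[i] for i in risk)
        sum_tied = sum(theta[i] for i in tied)
        ll += sum(beta * x[i] for i in tied)
        for ell in range(d):
            ll -= math.log(sum_risk - ell / d * sum_tied)
    return ll


def cox_grid_search(times, events, x, lo=-10.0, hi=10.0, tol=1e-8) -> float:
    """Golden-section maximization of the Efron partial likelihood in beta."""
    gr = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = efron_log_partial_likelihood(c, times, events, x)
    fd = efron_log_partial_likelihood(d, times, events, x)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = efron_log_partial_likelihood(c, times, events, x)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = efron_log_partial_likelihood(d, times, events, x)
    return (a + b) / 2


# ---------------------------------------------------------------------------
# logistic regression by straight Newton iterations (for tiny designs)
# ---------------------------------------------------------------------------

def logistic_newton(X, y, iters=200):
    """MLE of logistic regression with intercept, plain Newton-Raphson.

    X: list of rows (without intercept); y: 0/1 list. Returns [b0, b1, ...].
    """
    import numpy as np

    Xm = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    beta = np.zeros(Xm.shape[1])
    for _ in range(iters):
        p = 1 / (1 + np.exp(-Xm @ beta))
        g = Xm.T @ (np.asarray(y) - p)
        W = p * (1 - p)
        H = (Xm * W[:, None]).T @ Xm
        step = np.linalg.solve(H + 1e-12 * np.eye(len(beta)), g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta
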