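"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (loops, enumeration, quadrature) and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def mean_loop(values) -> float:
    total = 0.0
    for v in values:
        total += v
    return total / len(values)


def product_limit(times, events):
    """Naive Kaplan-Meier: returns (event_times, S just after each).

    times/events are parallel sequences; events truthy = death.
    """
    times = list(times)
    events = list(events)
    event_times = sorted({t for t, e in zip(times, events) if e})
    s = 1.0
    out = []
    for et in event_times:
        at_risk = sum(1 for t in times if t >= et)
        deaths = sum(1 for t, e in zip(times, events) if e and t == et)
        s *= 1.0 - deaths / at_risk
        out.append((et, s))
    return out


def km_median(times, events):
    """Smallest event time with S(t) <= 0.5, else None."""
    for t, s in product_limit(times, events):
        if s <= 0.5 + 1e-12:
            return t
    return None


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Hand-tabulated log-rank chi-square with hypergeometric variance."""
    all_times = sorted(
        {t for t, e in zip(list(times_a) + list(times_b), list(events_a) + list(events_b)) if e}
    )
    o_minus_e = 0.0
    var = 0.0
    for et in all_times:
        n1 = sum(1 for t in times_a if t >= et)
        n2 = sum(1 for t in times_b if t >= et)
        d1 = sum(1 for t, e in zip(times_a, events_a) if e and t == et)
        d2 = sum(1 for t, e in zip(times_b, events_b) if e and t == et)
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0 or n2 == 0:
            o_minus_e += d1 - (d * n1 / n if n else 0.0)
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def logrank_permutation_p(times_a, events_a, times_b, events_b) -> float:
    """Exact permutation p: fraction of group-label reassignments whose
    log-rank chi-square is >= the observed one."""
    obs = logrank_chi2(times_a, events_a, times_b, events_b)
    pooled = list(zip(list(times_a) + list(times_b), list(events_a) + list(events_b)))
    n_a = len(times_a)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = set(idx)
        ta = [pooled[i][0] for i in sel]
        ea = [pooled[i][1] for i in sel]
        tb = [pooled[i][0] for i in range(len(pooled)) if i not in sel]
        eb = [pooled[i][1] for i in range(len(pooled)) if i not in sel]
        stat = logrank_chi2(ta, ea, tb, eb)
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total


def mwu_enumeration_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of label
    assignments (no ties assumed): returns (U_x, p)."""
    x = list(x)
    y = list(y)
    nx, ny = len(x), len(y)

    def u_of(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    u_obs = u_of(x, y)
    pooled = x + y
    us = []
    for idx in itertools.combinations(range(nx + ny), nx):
        sel = set(idx)
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in range(nx + ny) if i not in sel]
        us.append(u_of(xs, ys))
    us = np.array(us)
    p_le = float(np.mean(us <= u_obs + 1e-12))
    p_ge = float(np.mean(us >= u_obs - 1e-12))
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def bky_brute_force(p_values, q=0.05):
    """Direct transcription of the two-stage adaptive step-up definition."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q1 = q / (1 + q)

    def step_up(level):
        k = 0
        for rank, i in enumerate(order, start=1):
            if p[i] <= level * rank / m:
                k = rank
        return k

    r1 = step_up(q1)
    if r1 == 0 or r1 == m:
        k = r1
    else:
        k = step_up(q1 * m / (m - r1))
    rejected = [False] * m
    for i in order[:k]:
        rejected[i] = True
    return rejected, r1


def bh_rejections(p_values, q=0.05):
    """Plain Benjamini-Hochberg step-up rejection flags."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= q * rank / m:
            k = rank
    rejected = [False] * m
    for i in order[:k]:
        rejected[i] = True
    return rejected


def tiac_quadrature(a0, plateau, t_half_bio_h, t_half_phys_h) -> float:
    """Adaptive quadrature of the decay-weighted activity concentration."""
    lam_b = math.log(2) / t_half_bio_h
    lam_p = math.log(2) / t_half_phys_h

    def integrand(t):
        return ((a0 - plateau) * math.exp(-lam_b * t) + plateau) * math.exp(-lam_p * t) / 100.0

    val, _ = quad(integrand, 0, np.inf, epsabs=1e-12, epsrel=1e-10, limit=400)
    return val


def grid_search_one_phase(t, y, a0_range, p_range, th_range, n=40):
    """Dense grid search minimising SSE of the one-phase decay model."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = (np.inf, None)
    for a0 in np.linspace(*a0_range, n):
        for p in np.linspace(*p_range, n):
            if p > a0:
                continue
            for th in np.linspace(*th_range, n):
                pred = (a0 - p) * np.exp(-math.log(2) / th * t) + p
                sse = float(np.sum((y - pred) ** 2))
                if sse < best[0]:
                    best = (sse, (a0, p, th))
    return best
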