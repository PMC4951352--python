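"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive — enumeration, per-sample loops,
grid searches — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumeration over fixed-margin tables.

    Sums the probabilities of every table (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(first cell == x) under fixed margins
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def hypergeom_upper(m, n_universe, n_marked, n_drawn) -> float:
    """P(at least m marked among n_drawn drawn from n_universe) by summation."""
    total = 0.0
    for i in range(m, min(n_marked, n_drawn) + 1):
        total += (
            comb(n_marked, i)
            * comb(n_universe - n_marked, n_drawn - i)
            / comb(n_universe, n_drawn)
        )
    return min(total, 1.0)


def overlap_pvalue_by_enumeration(set_a, universe, k_drawn, min_overlap) -> float:
    """P(|draw ∩ A| >= min_overlap) over every possible draw of k items."""
    universe = list(universe)
    hits = 0
    total = 0
    for drawn in itertools.combinations(universe, k_drawn):
        total += 1
        if len(set(drawn) & set(set_a)) >= min_overlap:
            hits += 1
    return hits / total


def km_product_limit(times, events):
    """Kaplan-Meier by an explicit per-event loop; returns {time: S(t)}."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    surv = 1.0
    out = {}
    for t in sorted(set(times)):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        if deaths:
            surv *= 1.0 - deaths / at_risk
        out[t] = surv
    return out


def logrank_chi2(times, events, group):
    """Two-group log-rank statistic computed with the textbook O-E/V sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def harrell_c(risk, times, events) -> float:
    """Harrell's C by exhaustive enumeration over sample pairs."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    num = 0.0
    den = 0
    for i in range(len(times)):
        for j in range(len(times)):
            if i == j:
                continue
            # usable: i fails first (observed event before j's observed time)
            if events[i] == 1 and (times[i] < times[j] or (times[i] == times[j] and events[j] == 0)):
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def cox_loglik_1d(beta, times, events, x):
    """Breslow partial log-likelihood for one covariate (no tied event times)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll
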