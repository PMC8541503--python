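"""Independent brute-force oracles used by the test suite.

Everything here is written in plain loops from the defining formulas, kept
deliberately separate from the package's vectorized implementations.
"""

import numpy as np


def nelson_aalen_at(times, events, t):
    """H(t) = sum over event times u <= t of d_u / n_u."""
    h = 0.0
    for u in sorted(set(times[events == 1])):
        if u <= t:
            n_u = sum(1 for ti in times if ti >= u)
            d_u = sum(1 for ti, ei in zip(times, events) if ti == u and ei == 1)
            h += d_u / n_u
    return h


def logrank_scores_oracle(times, events):
    return np.array(
        [e - nelson_aalen_at(times, events, t) for t, e in zip(times, events)]
    )


def brute_maxstat(x, times, events, minprop=0.1, maxprop=0.9):
    """Exhaustive enumeration of admissible cutpoints; returns (M, cutpoint)."""
    a = logrank_scores_oracle(times, events)
    n = len(x)
    abar = float(np.mean(a))
    ssq = float(sum((ai - abar) ** 2 for ai in a))
    best = None
    for mu in sorted(set(x)):
        low = x <= mu
        m = int(low.sum())
        if m == n:
            continue
        frac = m / n
        if frac < minprop or frac > maxprop:
            continue
        s = float(a[low].sum())
        e = m * abar
        v = m * (n - m) / (n * (n - 1)) * ssq
        z = abs(s - e) / np.sqrt(v)
        if best is None or z > best[0] + 1e-12:
            best = (z, mu)
    return best  # None if no admissible cutpoint


def brute_logrank(times, events, group):
    """Per-event-time 2x2 hypergeometric arithmetic; returns the chi-square."""
    obs = exp = var = 0.0
    for u in sorted(set(times[events == 1])):
        at_risk = times >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((times == u) & (events == 1)).sum())
        d1 = int(((times == u) & (events == 1) & (group == 1)).sum())
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


def brute_km(times, events):
    """Hand product-limit computation; returns dict time -> S(time)."""
    s = 1.0
    out = {}
    for u in sorted(set(times[events == 1])):
        n = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1 - d / n
        out[u] = s
    return out
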