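"""Independent brute-force oracles shared by the test suite.

These deliberately use naive double loops and stay independent of the
package's implementations.
"""

from __future__ import annotations

import numpy as np


def brute_cindex(risk, t, s) -> float:
    """Pair-enumeration Harrell's C: event-anchored pairs, 0.5 tie credit."""
    risk = np.asarray(risk, float)
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    numer = 0.0
    denom = 0
    n = len(t)
    for i in range(n):
        if s[i] != 1:
            continue
        for j in range(n):
            if t[i] < t[j]:
                denom += 1
                if risk[i] > risk[j]:
                    numer += 1.0
                elif risk[i] == risk[j]:
                    numer += 0.5
    if denom == 0:
        raise ValueError("no comparable pairs")
    return numer / denom


def brute_cox_loss(p, t, s, normalize=True) -> float:
    """Explicit double-loop negative log partial likelihood (Breslow)."""
    p = np.asarray(p, float)
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    total = 0.0
    n_events = 0
    for i in range(len(t)):
        if s[i] != 1:
            continue
        n_events += 1
        denom = 0.0
        for j in range(len(t)):
            if t[j] >= t[i]:
                denom += np.exp(p[j])
        total += p[i] - np.log(denom)
    loss = -total
    if normalize:
        loss /= n_events
    return loss


def brute_km(t, s):
    """Hand product-limit estimate: (event_times, survival)."""
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    taus = sorted(set(t[s == 1]))
    surv = []
    prod = 1.0
    for tau in taus:
        n_at_risk = int((t >= tau).sum())
        d = int(((t == tau) & (s == 1)).sum())
        prod *= 1.0 - d / n_at_risk
        surv.append(prod)
    return np.asarray(taus), np.asarray(surv)


def random_survival_instance(rng, n_max=50, with_ties=True):
    """A small random censored sample with at least one comparable pair."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        if with_ties:
            t = rng.integers(1, max(3, n // 2) + 1, size=n).astype(float)
            risk = rng.integers(-3, 4, size=n).astype(float)
        else:
            t = rng.uniform(0.5, 10.0, size=n)
            risk = rng.normal(size=n)
        s = (rng.uniform(size=n) < 0.7).astype(float)
        events = t[s == 1]
        if events.size and (t > events.min()).any():
            return risk, t, s
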