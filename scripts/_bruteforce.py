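"""Literal brute-force cylinder enumeration used by the acceptance script
to cross-check the scan implementation (independent of the package's scan
code)."""

from __future__ import annotations

import numpy as np


def brute_force_candidates(t, x, y, max_radius, max_span, min_observed):
    """member frozenset -> (c, n_s, n_t, mu, glr, radius, center_idx)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    times = np.unique(t)
    best = {}
    for i in range(n):
        d = np.hypot(x - x[i], y - y[i])
        for r in sorted(set(d[d <= max_radius])):
            smask = d <= r
            n_s = int(smask.sum())
            for ai in range(len(times)):
                for bi in range(ai, len(times)):
                    if times[bi] - times[ai] > max_span:
                        break
                    tmask = (t >= times[ai]) & (t <= times[bi])
                    members = frozenset(np.flatnonzero(smask & tmask).tolist())
                    c = len(members)
                    if c < min_observed:
                        continue
                    n_t = int(tmask.sum())
                    mu = n_s * n_t / n
                    prev = best.get(members)
                    if prev is not None and (prev[3], prev[5], prev[6]) <= (mu, r, i):
                        continue
                    best[members] = (c, n_s, n_t, mu, _glr(c, mu, n), r, i)
    return best


def _glr(c, mu, n):
    if c <= mu:
        return 1.0
    val = (c / mu) ** c
    if n - c > 0:
        val *= ((n - c) / (n - mu)) ** (n - c)
    return val
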